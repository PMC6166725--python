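"""Kinematic ω-torsion scans and hydrogen-bond geometry tracking.

Peptidyl–prolyl cis/trans isomerization is a rotation of the peptide-bond
torsion ω = Cα(i−1)–C(i−1)–N(i)–Cα(i) from ~180° (trans) through a twisted
"syn" transition-state-like geometry near ±90° to ~0° (cis). A PPIase can
stabilize the transition state through a hydrogen bond from its catalytic
backbone amide to the carbonyl oxygen of the residue preceding the proline.

This module re-implements the restrained rotation scan kinematically: a
schedule of ω restraint centers advancing by a fixed step per dwell time, a
rigid-body rotation of the segment N-terminal to the prolyl bond about the
C–N axis, and per-frame hydrogen-bond geometry (H···O distance, N–H···O
angle) with a strong/none classification. No force field is involved: each
frame sits exactly at its scheduled ω.

Structures are gemmi objects (multi-model PDB); atoms are addressed as
``"chain:resnum:atom"`` strings, residues are 1-based, ω is reported in
(−180°, 180°].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import gemmi
import numpy as np

#: Strong hydrogen bond: H···O below this distance (Å) ...
HBOND_DMAX = 2.5
#: ... and N–H···O at least this linear (degrees). Distance criterion is
#: the established one; the angle default is a conventional linearity
#: cutoff and is configurable.
HBOND_ANGLE_MIN = 130.0


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    wrapped = float(np.mod(deg, 360.0))
    if wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


@dataclass
class TorsionSchedule:
    """An ω-restraint-center schedule.

    The restraint center advances by ``step`` degrees per ``dwell`` ps from
    ``start_omega`` to ``end_omega``. ``clockwise`` traverses the arc of
    increasing ω (for the −174° → 0° endpoints this is the shorter arc,
    through −90°); ``counterclockwise`` the complementary arc through ±180°.
    ``restraint_k`` (kcal·mol⁻¹·rad⁻²) is carried as metadata only.
    """

    start_omega: float
    end_omega: float
    step: float = 0.2
    dwell: float = 2.0
    direction: str = "clockwise"
    restraint_k: float = 50.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValueError("direction must be clockwise or counterclockwise")
        for name in ("start_omega", "end_omega"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} must lie in (-180, 180], got {v}")

    @property
    def arc_length(self) -> float:
        """Traversed arc in degrees (0 for start == end)."""
        diff = (self.end_omega - self.start_omega) % 360.0
        return diff if self.direction == "clockwise" else (-diff) % 360.0

    @property
    def n_windows(self) -> int:
        """Number of steps; arc must be an integer multiple of step."""
        ratio = self.arc_length / self.step
        n = round(ratio)
        if abs(ratio - n) > 1e-9 * max(1.0, ratio):
            raise ValueError(
                f"arc of {self.arc_length} deg is not divisible by step {self.step}"
            )
        return n

    @property
    def total_time_ns(self) -> float:
        return self.n_windows * self.dwell * 1e-3


def build_schedule(schedule: TorsionSchedule) -> list[tuple[float, float]]:
    """Expand a schedule into (time_ns, restraint_center_deg) windows.

    The first entry is the starting geometry at t = 0; each subsequent
    window advances the center by one step and the clock by one dwell, so
    the list has ``n_windows + 1`` entries and the last entry's time equals
    ``total_time_ns``.
    """
    sign = 1.0 if schedule.direction == "clockwise" else -1.0
    out = []
    for k in range(schedule.n_windows + 1):
        center = wrap_angle(schedule.start_omega + sign * k * schedule.step)
        out.append((k * schedule.dwell * 1e-3, center))
    return out


# ---------------------------------------------------------------------------
# coordinate access and primitive geometry

def parse_selection(sel: str) -> tuple[str, int, str]:
    """Parse a ``"chain:resnum:atom"`` selection string."""
    parts = sel.split(":")
    if len(parts) != 3:
        raise ValueError(f"selection must be chain:resnum:atom, got {sel!r}")
    return parts[0], int(parts[1]), parts[2]


def get_atom_pos(model: gemmi.Model, chain: str, resnum: int, atom: str) -> np.ndarray:
    """Coordinates (Å) of one atom in a gemmi model."""
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num != resnum:
                continue
            for at in res:
                if at.name == atom:
                    return np.array([at.pos.x, at.pos.y, at.pos.z])
    raise KeyError(f"atom {chain}:{resnum}:{atom} not found")


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees, IUPAC convention) over four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def measure_omega(model: gemmi.Model, residue_index: int, chain: str = "A") -> float:
    """Peptide-bond torsion Cα(i−1)–C(i−1)–N(i)–Cα(i), in (−180, 180]."""
    if residue_index < 2:
        raise ValueError("omega is undefined at the N-terminal residue")
    ca_prev = get_atom_pos(model, chain, residue_index - 1, "CA")
    c_prev = get_atom_pos(model, chain, residue_index - 1, "C")
    n = get_atom_pos(model, chain, residue_index, "N")
    ca = get_atom_pos(model, chain, residue_index, "CA")
    return wrap_angle(dihedral(ca_prev, c_prev, n, ca))


def _rotation_matrix(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    t = np.radians(deg)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def rotate_segment(
    model: gemmi.Model,
    proline_index: int,
    delta_deg: float,
    chain: str = "A",
) -> gemmi.Model:
    """Rigidly rotate the N-terminal segment about the prolyl C–N bond.

    All atoms of residues 1 … proline_index−1 (including the preceding
    carbonyl oxygen) rotate about the C(i−1)–N(i) axis so that the measured
    ω increases by exactly ``delta_deg`` (mod 360); the proline and all
    C-terminal atoms stay fixed, emulating a substrate held by the catalyst
    while the upstream segment swings. Returns a new model.

    The handedness of the rotation matrix relative to the ω sign is
    resolved by measurement, so the post-condition ω_new = ω_old + delta
    holds exactly regardless of axis orientation.
    """
    c_prev = get_atom_pos(model, chain, proline_index - 1, "C")
    n_pro = get_atom_pos(model, chain, proline_index, "N")
    axis = n_pro - c_prev
    if np.linalg.norm(axis) < 1e-9:
        raise ValueError("C and N bond atoms are coincident")

    omega_before = measure_omega(model, proline_index, chain)

    def rotated(sign: float) -> gemmi.Model:
        R = _rotation_matrix(axis, sign * delta_deg)
        out = copy.deepcopy(model)
        for ch in out:
            if ch.name != chain:
                continue
            for res in ch:
                if res.seqid.num >= proline_index:
                    continue
                for at in res:
                    p = np.array([at.pos.x, at.pos.y, at.pos.z])
                    q = R @ (p - c_prev) + c_prev
                    at.pos = gemmi.Position(*q)
        return out

    for sign in (1.0, -1.0):
        cand = rotated(sign)
        achieved = measure_omega(cand, proline_index, chain)
        if abs(wrap_angle(achieved - (omega_before + delta_deg))) < 1e-6:
            return cand
    # delta ≡ 0 or 180 (both signs equivalent): either candidate is exact
    return cand


def set_omega(
    model: gemmi.Model, proline_index: int, target_deg: float, chain: str = "A"
) -> gemmi.Model:
    """Rotate the N-terminal segment so ω equals ``target_deg`` exactly."""
    current = measure_omega(model, proline_index, chain)
    return rotate_segment(model, proline_index, wrap_angle(target_deg - current), chain)


def hbond_geometry(donor_N, donor_H, acceptor_O) -> tuple[float, float]:
    """H···O distance (Å) and N–H···O angle (degrees) at the H vertex."""
    n, h, o = (np.asarray(p, dtype=float) for p in (donor_N, donor_H, acceptor_O))
    ho = o - h
    hn = n - h
    d = float(np.linalg.norm(ho))
    if d < 1e-9 or np.linalg.norm(hn) < 1e-9:
        raise ValueError("coincident atoms in hydrogen-bond geometry")
    cos_t = np.clip(np.dot(hn, ho) / (np.linalg.norm(hn) * d), -1.0, 1.0)
    return d, float(np.degrees(np.arccos(cos_t)))


def classify_hbond(
    d_HO: float,
    theta_NHO: float,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> str:
    """``strong`` iff the H···O distance is < d_max AND the angle ≥ angle_min."""
    return "strong" if (d_HO < d_max and theta_NHO >= angle_min) else "none"


@dataclass
class FrameGeometry:
    """Per-frame scan record."""

    time: float  # ns
    omega: float  # degrees, (−180, 180]
    d_HO: float  # Å
    theta_NHO: float  # degrees
    hbond_class: str


def track_scan(
    ensemble: gemmi.Structure,
    donor_spec: str,
    acceptor_spec: str,
    proline_index: int,
    schedule: TorsionSchedule | list[tuple[float, float]],
    peptide_chain: str = "A",
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
    on_mismatch: str = "error",
) -> tuple[list[FrameGeometry], dict]:
    """Measure ω and hydrogen-bond geometry across a scan ensemble.

    ``donor_spec`` names the probe amide H (its N is found by replacing the
    atom field with ``N``); ``acceptor_spec`` names the carbonyl oxygen.
    The ensemble must have one model per schedule window; on a length
    mismatch ``on_mismatch`` selects ``"error"`` or ``"truncate"`` (warn
    and use the common prefix).

    Returns the frame list and a summary dict including the first time at
    which the hydrogen bond classifies strong (None if never) and the time
    and geometry of closest approach.
    """
    windows = build_schedule(schedule) if isinstance(schedule, TorsionSchedule) else schedule
    n_models = len(ensemble)
    if n_models != len(windows):
        if on_mismatch == "truncate":
            import warnings

            warnings.warn(
                f"{n_models} models vs {len(windows)} schedule windows; truncating",
                stacklevel=2,
            )
            windows = windows[: min(n_models, len(windows))]
        else:
            raise ValueError(
                f"ensemble has {n_models} models but schedule has {len(windows)} windows"
            )

    d_chain, d_res, d_atom = parse_selection(donor_spec)
    a_chain, a_res, a_atom = parse_selection(acceptor_spec)

    frames: list[FrameGeometry] = []
    for (t_ns, _center), model in zip(windows, ensemble):
        h = get_atom_pos(model, d_chain, d_res, d_atom)
        n = get_atom_pos(model, d_chain, d_res, "N")
        o = get_atom_pos(model, a_chain, a_res, a_atom)
        d, theta = hbond_geometry(n, h, o)
        frames.append(
            FrameGeometry(
                time=t_ns,
                omega=measure_omega(model, proline_index, peptide_chain),
                d_HO=d,
                theta_NHO=theta,
                hbond_class=classify_hbond(d, theta, d_max, angle_min),
            )
        )

    strong = [f for f in frames if f.hbond_class == "strong"]
    closest = min(frames, key=lambda f: f.d_HO) if frames else None
    summary = {
        "n_frames": len(frames),
        "first_strong_ns": strong[0].time if strong else None,
        "first_strong_omega": strong[0].omega if strong else None,
        "n_strong": len(strong),
        "closest_approach_ns": closest.time if closest else None,
        "closest_approach_A": closest.d_HO if closest else None,
        "closest_approach_omega": closest.omega if closest else None,
    }
    return frames, summary
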