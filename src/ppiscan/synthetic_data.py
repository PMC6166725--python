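"""Synthetic inputs with the statistical structure the analyses assume.

Three generators stand in for the study's raw data so the whole pipeline is
testable without downloads:

* titration peak tables with planted binding sites, broadened under a
  fast-exchange model (bound fraction from single-site binding at a
  configurable K_d);
* CPMG dispersion curves from the fast-exchange two-state forward model
  with Gaussian noise;
* idealized-backbone conformer ensembles of a short proline-containing
  peptide driven through an ω-rotation schedule, with a fixed catalytic
  amide probe for hydrogen-bond tracking.

Each generator consumes one seeded NumPy generator; with ``noise_sd = 0``
output is bit-reproducible for a fixed spec and seed. Ground truth (planted
sites, generating parameters, schedule centers) is returned alongside the
data, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .titration_mapping import TitrationSeries
from .cpmg_dispersion import DispersionCurve
from .torsion_hbond import TorsionSchedule, build_schedule, set_omega, measure_omega

# ---------------------------------------------------------------------------
# titration


@dataclass
class TitrationSpec:
    """Recipe for a synthetic titration with planted binding sites.

    ``sites`` are 1-based inclusive ``(start, end, depth)`` regions; depth
    in (0, 1] scales the extra exchange broadening inside the site.
    ``ratios`` are chaperone:substrate molar ratios, strictly increasing.
    ``csp_max`` is the saturating (¹H, ¹⁵N) shift change in ppm for in-site
    residues. Binding strength and sample conditions are explicit so the
    generated kinetics stay physically anchored: ``kd`` molar,
    ``substrate_conc`` molar, free-state ``r2_free`` and maximal extra
    broadening ``delta_r2_max`` in s⁻¹.
    """

    sequence: str
    sites: list[tuple[int, int, float]] = field(default_factory=list)
    ratios: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0)
    noise_sd: float = 0.02
    csp_max: tuple[float, float] = (0.05, 0.25)
    seed: int = 0
    kd: float = 47e-6
    substrate_conc: float = 100e-6
    r2_free: float = 20.0
    delta_r2_max: float = 200.0

    def __post_init__(self):
        n = len(self.sequence)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(b <= a for a, b in zip(self.ratios, self.ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        spans = sorted((s, e) for s, e, _ in self.sites)
        for (s, e, depth) in self.sites:
            if not (1 <= s <= e <= n):
                raise ValueError(f"site ({s},{e}) outside sequence of length {n}")
            if not (0 < depth <= 1):
                raise ValueError(f"site depth must be in (0,1], got {depth}")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted sites must not overlap")


def bound_fraction(ratio: float, kd: float, substrate_conc: float) -> float:
    """Fraction of substrate bound at a chaperone:substrate molar ratio.

    Single-site binding: with total substrate P₀ and total chaperone
    L₀ = ratio·P₀, the complex concentration solves the usual quadratic.
    """
    p0 = substrate_conc
    l0 = ratio * p0
    s = p0 + l0 + kd
    return (s - np.sqrt(s * s - 4.0 * p0 * l0)) / (2.0 * p0)


def generate_titration(spec: TitrationSpec) -> TitrationSeries:
    """Simulate per-residue peak tables across a titration.

    Residues inside a planted site acquire extra transverse relaxation
    ΔR₂ = depth·delta_r2_max scaled by the bound fraction, so their peak
    intensity ratio is I/I₀ = R₂free/(R₂free + f_b·ΔR₂); residues outside
    sites keep ratio 1. Chemical shifts move by f_b·csp_max inside sites.
    Multiplicative Gaussian noise of sd ``noise_sd`` is applied to bound
    intensities. Prolines carry no amide observables (``assigned=False``).

    The planted site list rides along as ``ground_truth_sites``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    residues = np.arange(1, n + 1)

    # free-state baseline: random but seed-reproducible amide positions
    d1h0 = rng.uniform(7.8, 8.6, size=n)
    d15n0 = rng.uniform(105.0, 130.0, size=n)
    i0 = np.full(n, 1e6)

    depth_of = np.zeros(n)
    for s, e, depth in spec.sites:
        depth_of[s - 1 : e] = depth

    is_pro = np.array([aa == "P" for aa in spec.sequence.upper()])

    def table(d1h, d15n, inten):
        return pd.DataFrame({
            "residue": residues,
            "aa": list(spec.sequence.upper()),
            "d1H": np.where(is_pro, np.nan, d1h),
            "d15N": np.where(is_pro, np.nan, d15n),
            "intensity": np.where(is_pro, 0.0, inten),
            "assigned": ~is_pro,
        })

    reference = table(d1h0, d15n0, i0)

    points: dict[float, pd.DataFrame] = {}
    for ratio in spec.ratios:
        fb = bound_fraction(ratio, spec.kd, spec.substrate_conc)
        model_ratio = spec.r2_free / (spec.r2_free + fb * depth_of * spec.delta_r2_max)
        noise = (
            1.0 + spec.noise_sd * rng.standard_normal(n)
            if spec.noise_sd > 0 else 1.0
        )
        inten = i0 * model_ratio * noise
        in_site = depth_of > 0
        d1h = d1h0 + np.where(in_site, fb * spec.csp_max[0], 0.0)
        d15n = d15n0 + np.where(in_site, fb * spec.csp_max[1], 0.0)
        points[ratio] = table(d1h, d15n, np.clip(inten, 0.0, None))

    return TitrationSeries(
        reference=reference, points=points, ground_truth_sites=list(spec.sites)
    )


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionSpec:
    """Forward-model parameters for a synthetic dispersion curve."""

    r2_0: float = 15.0
    kex: float = 740.0
    phi: float = 2000.0
    nu_grid: tuple[float, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    temperature: float = 35.0
    field: float = 800.0

    def __post_init__(self):
        if not self.nu_grid:
            # 16 log-spaced refocusing frequencies, a realistic CPMG grid
            self.nu_grid = tuple(np.logspace(np.log10(25.0), np.log10(1000.0), 16))
        if self.r2_0 <= 0 or self.kex <= 0 or self.phi < 0:
            raise ValueError("require r2_0 > 0, kex > 0, phi >= 0")
        if any(nu <= 0 for nu in self.nu_grid):
            raise ValueError("all nu_CPMG must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_dispersion(spec: DispersionSpec) -> DispersionCurve:
    """R2eff over the ν grid from the fast-exchange forward model + noise.

    The model expression here is an independent algebraic transcription of
    the two-state fast-exchange dispersion (expanded form), deliberately
    not calling the fitting module's evaluator, so the two can cross-check
    each other.
    """
    nu = np.asarray(spec.nu_grid, dtype=float)
    # expanded form: R2_0 + phi/kex − (4 ν phi / kex²) · tanh(kex / 4ν)
    r2eff = (
        spec.r2_0
        + spec.phi / spec.kex
        - (4.0 * nu * spec.phi / spec.kex**2) * np.tanh(spec.kex / (4.0 * nu))
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        r2eff = r2eff + spec.noise_sd * rng.standard_normal(nu.shape)
    sd = np.full(nu.shape, spec.noise_sd) if spec.noise_sd > 0 else None
    return DispersionCurve(
        nu=nu, r2eff=r2eff, sd=sd,
        temperature=spec.temperature, field=spec.field,
    )


# ---------------------------------------------------------------------------
# peptide ω scan

# idealized backbone internal coordinates (Å, degrees); any internally
# consistent set works since only relative geometry is analysed downstream
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
BOND_N_H = 1.01
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.0
ANGLE_C_N_CA = 122.0
ANGLE_CA_C_O = 121.0
ANGLE_C_N_H = 119.0
PHI_EXTENDED = -135.0
PSI_EXTENDED = 135.0


@dataclass
class PeptideScanSpec:
    """Recipe for an idealized-peptide ω-rotation scan ensemble.

    The scanned peptidyl–prolyl bond precedes residue ``proline_index``
    (1-based; must have a preceding residue). ``acceptor_site`` optionally
    fixes the catalytic backbone-amide probe explicitly as
    ``{"N": (x,y,z), "H": (x,y,z)}``; by default the probe is placed along
    the preceding residue's carbonyl direction at the ω where the study
    expects the hydrogen bond (``probe_omega``), ``probe_d_ho`` Å from the
    oxygen, so the closest approach occurs at that window by construction.
    """

    n_residues: int = 5
    proline_index: int = 3
    start_omega: float = -174.0
    end_omega: float = 0.0
    step: float = 0.2
    dwell: float = 2.0
    direction: str = "clockwise"
    acceptor_site: dict | None = None
    probe_omega: float = -90.0
    probe_d_ho: float = 2.1

    def schedule(self) -> TorsionSchedule:
        return TorsionSchedule(
            start_omega=self.start_omega, end_omega=self.end_omega,
            step=self.step, dwell=self.dwell, direction=self.direction,
        )

    def __post_init__(self):
        if not (2 <= self.proline_index <= self.n_residues):
            raise ValueError(
                "proline_index needs a preceding residue inside the chain"
            )
        self.schedule()  # validates angles/step/dwell


def _place(a, b, c, length, angle_deg, torsion_deg):
    """Internal-coordinate atom placement (NeRF)."""
    theta = np.radians(angle_deg)
    chi = np.radians(-torsion_deg)  # sign fixed so dihedral(a,b,c,new)=torsion
    d = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(chi),
        length * np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    return c + np.column_stack([bc, m, n]) @ d


def _build_backbone(n_residues: int, proline_index: int, omega_scan: float):
    """Idealized extended backbone; returns {(resnum, atom): xyz}.

    All peptide bonds are trans (ω=180) except the scanned bond, set to
    ``omega_scan``. Residues are glycine except the proline, which carries
    no amide H.
    """
    atoms: dict[tuple[int, str], np.ndarray] = {}
    atoms[(1, "N")] = np.array([0.0, 0.0, 0.0])
    atoms[(1, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    t = np.radians(ANGLE_N_CA_C)
    atoms[(1, "C")] = atoms[(1, "CA")] + BOND_CA_C * np.array([-np.cos(t), np.sin(t), 0.0])

    for i in range(2, n_residues + 1):
        omega = omega_scan if i == proline_index else 180.0
        n_prev, ca_prev, c_prev = (atoms[(i - 1, x)] for x in ("N", "CA", "C"))
        n_i = _place(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, PSI_EXTENDED)
        atoms[(i, "N")] = n_i
        ca_i = _place(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        atoms[(i, "CA")] = ca_i
        atoms[(i, "C")] = _place(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, PHI_EXTENDED)
        # carbonyl O of the preceding residue, anti to this N across C
        atoms[(i - 1, "O")] = _place(n_prev, ca_prev, c_prev, BOND_C_O,
                                     ANGLE_CA_C_O, PSI_EXTENDED + 180.0)
        if i != proline_index:  # proline has no amide H
            atoms[(i, "H")] = _place(ca_prev, c_prev, n_i, BOND_N_H,
                                     ANGLE_C_N_H, omega + 180.0)
    # C-terminal carbonyl O (placed with the default psi continuation)
    i = n_residues
    atoms[(i, "O")] = _place(atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")],
                             BOND_C_O, ANGLE_CA_C_O, PSI_EXTENDED + 180.0)
    return atoms


def _peptide_model(atoms, n_residues, proline_index, model_name="1") -> gemmi.Model:
    model = gemmi.Model(model_name)
    chain = gemmi.Chain("A")
    element = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H"}
    for i in range(1, n_residues + 1):
        res = gemmi.Residue()
        res.name = "PRO" if i == proline_index else "GLY"
        res.seqid = gemmi.SeqId(i, " ")
        for name in ("N", "CA", "C", "O", "H"):
            if (i, name) not in atoms:
                continue
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element[name])
            at.pos = gemmi.Position(*atoms[(i, name)])
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    return model


def _probe_chain(n_xyz, h_xyz) -> gemmi.Chain:
    chain = gemmi.Chain("B")
    res = gemmi.Residue()
    res.name = "PRB"
    res.seqid = gemmi.SeqId(1, " ")
    for name, xyz, elem in (("N", n_xyz, "N"), ("H", h_xyz, "H")):
        at = gemmi.Atom()
        at.name = name
        at.element = gemmi.Element(elem)
        at.pos = gemmi.Position(*xyz)
        res.add_atom(at)
    chain.add_residue(res)
    return chain


def default_probe_site(spec: PeptideScanSpec) -> dict:
    """Probe amide (N, H) placed to meet the moving carbonyl O at
    ``spec.probe_omega``: H sits ``probe_d_ho`` Å from the oxygen along the
    carbonyl direction there, N behind H, so the N–H···O geometry is linear
    and the approach is closest exactly at that window."""
    from .torsion_hbond import get_atom_pos

    at_target = set_omega(_canonical_model(spec), spec.proline_index,
                          spec.probe_omega)
    o = get_atom_pos(at_target, "A", spec.proline_index - 1, "O")
    c = get_atom_pos(at_target, "A", spec.proline_index - 1, "C")
    u = (o - c) / np.linalg.norm(o - c)
    h = o + spec.probe_d_ho * u
    n = h + BOND_N_H * u
    return {"N": tuple(n), "H": tuple(h)}


def _canonical_model(spec: PeptideScanSpec) -> gemmi.Model:
    """Backbone built at a canonical ω (180°, trans).

    Every scan model is derived from this one frame by rigid rotation, so
    the non-rotating atoms occupy the same lab coordinates whatever the
    schedule endpoints or direction — per-ω geometry is schedule-invariant.
    """
    atoms = _build_backbone(spec.n_residues, spec.proline_index, 180.0)
    return _peptide_model(atoms, spec.n_residues, spec.proline_index)


def generate_peptide_scan(spec: PeptideScanSpec) -> gemmi.Structure:
    """Conformer ensemble of the peptide driven through the ω schedule.

    One model per schedule window (including the starting geometry), each
    with the scanned ω set exactly to that window's restraint center, plus
    the fixed probe amide as chain B. Returns a gemmi Structure suitable
    for multi-model PDB output.
    """
    schedule = spec.schedule()
    windows = build_schedule(schedule)
    probe = spec.acceptor_site or default_probe_site(spec)

    base = _canonical_model(spec)

    st = gemmi.Structure()
    st.name = "omega-scan"
    for k, (_t, center) in enumerate(windows):
        model = set_omega(base, spec.proline_index, center)
        model.num = k + 1
        model.add_chain(_probe_chain(np.asarray(probe["N"]), np.asarray(probe["H"])))
        st.add_model(model)
    return st


def omega_of_models(st: gemmi.Structure, proline_index: int) -> list[float]:
    """Measured ω of the scanned bond in every model (degrees)."""
    return [measure_omega(m, proline_index) for m in st]
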