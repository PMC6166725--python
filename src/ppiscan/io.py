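"""Table and structure I/O: TSV dialects, FASTA, multi-model PDB.

All residue coordinates in files are 1-based and inclusive. Tables are
tab-separated with a header line; ``#``-prefixed lines carry metadata
(seed, acquisition parameters, planted ground truth) as ``key = value``
pairs and are round-tripped where meaningful.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .cpmg_dispersion import DispersionCurve
from .titration_mapping import PEAK_COLUMNS, BindingSite, TitrationSeries
from .torsion_hbond import FrameGeometry


def _read_tsv(path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    """Read a TSV with '#' metadata lines; enforce required columns."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, newline="") as fh:  # newline='' keeps CRLF handling to pandas
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    return df, meta


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# peak tables and titrations

def write_peak_table(table: pd.DataFrame, path, meta: dict | None = None):
    _write_tsv(table[PEAK_COLUMNS], path, meta)


def read_peak_table(path) -> pd.DataFrame:
    df, _ = _read_tsv(path, PEAK_COLUMNS)
    df["assigned"] = df["assigned"].astype(bool)
    return df


TITRATION_COLUMNS = ["residue", "aa", "ratio_point", "d1H_ppm", "d15N_ppm",
                     "intensity_ratio"]


def write_titration(series: TitrationSeries, path, seed: int | None = None):
    """One row per residue per titration point; ratio_point 0 = free state.

    ``intensity_ratio`` is I/I₀ against the free reference (1.0 in the
    reference rows); planted ground-truth sites, if known, go into the
    metadata header as ``site_k = start-end:depth``.
    """
    ref = series.reference.set_index("residue")
    rows = []

    def emit(ratio, table):
        for _, rec in table.iterrows():
            res = int(rec["residue"])
            if rec["assigned"] and ref.at[res, "assigned"]:
                ratio_i = float(rec["intensity"]) / float(ref.at[res, "intensity"])
            else:
                ratio_i = np.nan
            rows.append({
                "residue": res, "aa": rec["aa"], "ratio_point": ratio,
                "d1H_ppm": rec["d1H"], "d15N_ppm": rec["d15N"],
                "intensity_ratio": ratio_i,
            })

    emit(0.0, series.reference)
    for ratio, table in series.points.items():
        emit(ratio, table)

    meta: dict = {}
    if seed is not None:
        meta["seed"] = seed
    for k, (s, e, depth) in enumerate(series.ground_truth_sites or []):
        meta[f"site_{k}"] = f"{s}-{e}:{depth}"
    _write_tsv(pd.DataFrame(rows, columns=TITRATION_COLUMNS), path, meta)


def read_titration(path) -> TitrationSeries:
    """Rebuild a TitrationSeries from the titration TSV dialect.

    Reference intensities are normalised to 1, so bound intensities equal
    the stored intensity ratios (the analysis only ever uses ratios).
    """
    df, meta = _read_tsv(path, TITRATION_COLUMNS)

    def to_table(sub: pd.DataFrame) -> pd.DataFrame:
        assigned = sub["intensity_ratio"].notna()
        return pd.DataFrame({
            "residue": sub["residue"].astype(int),
            "aa": sub["aa"],
            "d1H": sub["d1H_ppm"],
            "d15N": sub["d15N_ppm"],
            "intensity": sub["intensity_ratio"].fillna(0.0),
            "assigned": assigned,
        }).reset_index(drop=True)

    points = {}
    reference = None
    for ratio, sub in df.groupby("ratio_point", sort=True):
        if ratio == 0.0:
            reference = to_table(sub)
            reference["intensity"] = np.where(reference["assigned"], 1.0, 0.0)
        else:
            points[float(ratio)] = to_table(sub)
    if reference is None:
        raise ValueError(f"{path}: no reference rows (ratio_point = 0)")

    sites = []
    for key in sorted(k for k in meta if k.startswith("site_")):
        span, _, depth = meta[key].partition(":")
        s, _, e = span.partition("-")
        sites.append((int(s), int(e), float(depth)))
    return TitrationSeries(reference=reference, points=points,
                           ground_truth_sites=sites or None)


def read_sparky_peaks(path) -> pd.DataFrame:
    """Import a simple Sparky-style peak list.

    Whitespace-separated lines ``assignment  w1(15N)  w2(1H)  [height]``
    with assignments like ``G254N-H``. Returns a peak table; rows whose
    assignment cannot be parsed raise with their line number.
    """
    import re

    rows = []
    pat = re.compile(r"^([A-Z])(\d+)")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "Assignment")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields, got {line!r}")
            m = pat.match(fields[0])
            if not m:
                raise ValueError(f"{path}:{lineno}: cannot parse assignment {fields[0]!r}")
            try:
                w1, w2 = float(fields[1]), float(fields[2])
                height = float(fields[3]) if len(fields) > 3 else 1.0
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            rows.append({
                "residue": int(m.group(2)), "aa": m.group(1),
                "d1H": w2, "d15N": w1, "intensity": height, "assigned": True,
            })
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# dispersion

DISPERSION_COLUMNS = ["nu_cpmg_hz", "r2eff"]


def write_dispersion(curve: DispersionCurve, path, meta: dict | None = None):
    df = pd.DataFrame({"nu_cpmg_hz": curve.nu, "r2eff": curve.r2eff})
    if curve.sd is not None:
        df["sd"] = curve.sd
    full_meta = dict(meta or {})
    for key, val in (("temperature_C", curve.temperature),
                     ("field_MHz", curve.field), ("t_relax_s", curve.t_relax)):
        if val is not None:
            full_meta.setdefault(key, val)
    _write_tsv(df, path, full_meta)


def read_dispersion(path) -> DispersionCurve:
    df, meta = _read_tsv(path, DISPERSION_COLUMNS)
    return DispersionCurve(
        nu=df["nu_cpmg_hz"].to_numpy(),
        r2eff=df["r2eff"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df.columns else None,
        temperature=float(meta["temperature_C"]) if "temperature_C" in meta else None,
        field=float(meta["field_MHz"]) if "field_MHz" in meta else None,
        t_relax=float(meta.get("t_relax_s", 0.050)),
    )


def read_intensity_dispersion(path, i_ref: float, t_relax: float = 0.050) -> DispersionCurve:
    """Dispersion from a raw intensity TSV (nu_cpmg_hz, intensity)."""
    from .cpmg_dispersion import r2eff_from_intensities

    df, _ = _read_tsv(path, ["nu_cpmg_hz", "intensity"])
    r2 = r2eff_from_intensities(df["intensity"].to_numpy(), i_ref, t_relax)
    return DispersionCurve(nu=df["nu_cpmg_hz"].to_numpy(), r2eff=r2, t_relax=t_relax)


# ---------------------------------------------------------------------------
# sites, profiles, frames

def write_sites(sites: list[BindingSite], path, meta: dict | None = None):
    """Called binding sites as BED-like TSV (1-based, inclusive)."""
    df = pd.DataFrame(
        [{"start": s.start, "end": s.end,
          "mean_reduction": s.mean_reduction, "n_scored": s.n_scored}
         for s in sites],
        columns=["start", "end", "mean_reduction", "n_scored"],
    )
    _write_tsv(df, path, meta)


def write_frames(frames: list[FrameGeometry], path, meta: dict | None = None):
    df = pd.DataFrame(
        [{"time_ns": f.time, "omega_deg": f.omega, "d_ho_A": f.d_HO,
          "theta_deg": f.theta_NHO, "hbond": f.hbond_class}
         for f in frames],
        columns=["time_ns", "omega_deg", "d_ho_A", "theta_deg", "hbond"],
    )
    _write_tsv(df, path, meta)


# ---------------------------------------------------------------------------
# sequences and structures

def read_fasta(path) -> dict[str, str]:
    """All sequences from a FASTA file, id → uppercase string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_pdb(structure: gemmi.Structure, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    structure.write_pdb(str(path))


def read_pdb(path) -> gemmi.Structure:
    return gemmi.read_structure(str(path))
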