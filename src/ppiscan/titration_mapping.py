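"""Chemical-shift-perturbation and line-broadening analysis of titrations.

Adding a chaperone domain to an ¹⁵N-labelled unfolded substrate perturbs the
amide resonances of residues at the interaction surface: their positions
shift (chemical shift perturbation, CSP) and, for a large or kinetically
broadened complex, their intensities drop (differential line broadening).
The combined amide CSP is

    Δδ = sqrt( Δδ(¹H)² + (Δδ(¹⁵N)/5)² )

and a binding site is called as a continuous stretch of more than four
residues with significant intensity reduction, with invisible residues
(prolines have no amide; unassigned peaks) bridged rather than breaking
the run.

Peak tables are pandas DataFrames with columns ``residue`` (1-based int),
``aa`` (one-letter code), ``d1H``/``d15N`` (ppm), ``intensity`` (a.u.) and
``assigned`` (bool; prolines always False for amide observables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["residue", "aa", "d1H", "d15N", "intensity", "assigned"]

#: CSP classification thresholds (ppm): ≤ first → below, ≤ second →
#: moderate, above → strong. Typical interface-mapping cutoffs.
CSP_THRESHOLDS = (0.015, 0.025)

#: ¹⁵N shift scaling in the combined-CSP formula (amide ¹⁵N shifts span a
#: range ~5× wider than ¹H).
N15_SCALE = 5.0


@dataclass
class TitrationSeries:
    """A free-state reference peak table plus tables at increasing ratios.

    ``points`` maps chaperone:substrate molar ratio → peak table; ratios
    must be strictly increasing and every table must cover the same
    residue set as the reference.
    """

    reference: pd.DataFrame
    points: dict[float, pd.DataFrame]
    ground_truth_sites: list[tuple[int, int, float]] | None = None

    def __post_init__(self):
        ratios = list(self.points)
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("titration ratios must be strictly increasing")
        ref_res = set(self.reference["residue"])
        for r, table in self.points.items():
            if set(table["residue"]) != ref_res:
                raise ValueError(f"residue set at ratio {r} differs from reference")

    @property
    def ratios(self) -> list[float]:
        return list(self.points)


@dataclass
class BindingSite:
    """A called binding site: inclusive 1-based residue range."""

    start: int
    end: int
    mean_reduction: float
    n_scored: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_scored < 5:
            raise ValueError("a binding site requires >= 5 scored residues")


def csp(d1H_free: float, d15N_free: float, d1H_bound: float, d15N_bound: float) -> float:
    """Combined amide chemical shift perturbation in ppm (non-negative)."""
    for v in (d1H_free, d15N_free, d1H_bound, d15N_bound):
        if not math.isfinite(v):
            raise ValueError("chemical shifts must be finite")
    dh = d1H_bound - d1H_free
    dn = (d15N_bound - d15N_free) / N15_SCALE
    return math.sqrt(dh * dh + dn * dn)


def classify_csp(value: float, thresholds: tuple[float, float] = CSP_THRESHOLDS) -> str:
    """Bin a CSP value into ``below`` / ``moderate`` / ``strong``."""
    if value < 0:
        raise ValueError("CSP is non-negative by construction")
    lo, hi = thresholds
    if value <= lo:
        return "below"
    if value <= hi:
        return "moderate"
    return "strong"


def csp_profile(series: TitrationSeries, point: float) -> pd.DataFrame:
    """Per-residue CSP between the reference and one titration point."""
    bound = _get_point(series, point)
    ref = series.reference.set_index("residue")
    bnd = bound.set_index("residue")
    rows = []
    for res in ref.index:
        ok = bool(ref.at[res, "assigned"]) and bool(bnd.at[res, "assigned"])
        value = (
            csp(ref.at[res, "d1H"], ref.at[res, "d15N"],
                bnd.at[res, "d1H"], bnd.at[res, "d15N"])
            if ok else np.nan
        )
        rows.append({
            "residue": res, "aa": ref.at[res, "aa"], "csp_ppm": value,
            "class": classify_csp(value) if ok else "missing",
        })
    return pd.DataFrame(rows)


def intensity_ratios(series: TitrationSeries, point: float) -> pd.DataFrame:
    """Per-residue I/I0 at one titration point.

    Unassigned residues (including prolines) get NaN with ``missing=True``.
    A zero reference intensity on an assigned residue is an error.
    """
    bound = _get_point(series, point)
    ref = series.reference.set_index("residue")
    bnd = bound.set_index("residue")
    rows = []
    for res in ref.index:
        assigned = bool(ref.at[res, "assigned"]) and bool(bnd.at[res, "assigned"])
        if assigned:
            i0 = float(ref.at[res, "intensity"])
            if i0 == 0:
                raise ValueError(f"zero reference intensity for assigned residue {res}")
            ratio = float(bnd.at[res, "intensity"]) / i0
        else:
            ratio = np.nan
        rows.append({
            "residue": res, "aa": ref.at[res, "aa"],
            "intensity_ratio": ratio, "missing": not assigned,
        })
    return pd.DataFrame(rows)


def _get_point(series: TitrationSeries, point: float) -> pd.DataFrame:
    if point not in series.points:
        raise KeyError(f"no titration point at ratio {point}; have {series.ratios}")
    return series.points[point]


def significance_mask(
    ratios: pd.DataFrame,
    method: str = "mad",
    k: float = 2.0,
    cutoff: float = 0.7,
) -> pd.Series:
    """Flag residues with significant intensity reduction.

    ``method="mad"``: significant iff I/I0 < median − k·MAD, with the MAD
    scaled to be consistent with a normal σ. Robust to overall broadening
    from complex size, which shifts the whole profile. ``method="cutoff"``:
    significant iff I/I0 < cutoff. Missing residues are never significant.
    """
    vals = ratios["intensity_ratio"]
    if method == "mad":
        med = vals.median(skipna=True)
        mad = 1.4826 * (vals - med).abs().median(skipna=True)
        thresh = med - k * mad
    elif method == "cutoff":
        thresh = cutoff
    else:
        raise ValueError("method must be 'mad' or 'cutoff'")
    return (vals < thresh) & ~ratios["missing"]


def call_binding_sites(
    ratios: pd.DataFrame,
    significance: pd.Series | None = None,
    min_run: int = 5,
    bridge_missing: bool = True,
    **sig_kwargs,
) -> list[BindingSite]:
    """Call binding sites by the run-length rule.

    A site is a maximal run of consecutive significant residues containing
    at least ``min_run`` scored significant residues ("more than four").
    With ``bridge_missing``, invisible residues (prolines, unassigned)
    flanked by significant residues are absorbed into the run — a proline
    inside a binding site does not split it; they count toward the span
    but not toward ``n_scored``.
    """
    df = ratios.sort_values("residue").reset_index(drop=True)
    sig = (significance if significance is not None
           else significance_mask(df, **sig_kwargs)).reset_index(drop=True)

    sites: list[BindingSite] = []
    run: list[int] = []  # indices of significant rows in the current run

    def flush(run_idx: list[int]):
        if len(run_idx) >= min_run:
            rows = df.iloc[run_idx]
            sites.append(BindingSite(
                start=int(rows["residue"].min()),
                end=int(rows["residue"].max()),
                mean_reduction=float(1.0 - rows["intensity_ratio"].mean()),
                n_scored=len(run_idx),
            ))

    prev_res = None
    for i in range(len(df)):
        res = int(df.at[i, "residue"])
        missing = bool(df.at[i, "missing"])
        contiguous = prev_res is not None and res == prev_res + 1
        if sig.iloc[i]:
            if not (run and contiguous):
                flush(run)
                run = []
            run.append(i)
        elif missing and run and contiguous and bridge_missing:
            pass  # bridge: keep the run open across an invisible residue
        else:
            flush(run)
            run = []
        prev_res = res
    flush(run)
    return sites


def compare_preference(
    ratios_A: pd.DataFrame,
    ratios_B: pd.DataFrame,
    sites: list[BindingSite],
    label_A: str = "A",
    label_B: str = "B",
) -> pd.DataFrame:
    """Per-site mean intensity reduction under two conditions, ranked.

    The stronger the broadening (larger reduction 1 − I/I0) within a site,
    the stronger the binding preference of that condition for the site.
    Result is sorted by the reduction difference (A − B), descending, so
    sites preferred by condition A rank first.
    """
    a = ratios_A.set_index("residue")
    b = ratios_B.set_index("residue")
    if set(a.index).isdisjoint(b.index):
        raise ValueError("ratio profiles share no residues")
    rows = []
    for site in sites:
        span = range(site.start, site.end + 1)
        red_a = 1.0 - np.nanmean([a.at[r, "intensity_ratio"] for r in span if r in a.index])
        red_b = 1.0 - np.nanmean([b.at[r, "intensity_ratio"] for r in span if r in b.index])
        rows.append({
            "start": site.start, "end": site.end,
            f"reduction_{label_A}": red_a, f"reduction_{label_B}": red_b,
            "difference": red_a - red_b,
            "preferred_by": label_A if red_a > red_b else (label_B if red_b > red_a else "tie"),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("difference", ascending=False).reset_index(drop=True)
    return out
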