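"""Thermodynamic consistency arithmetic for calorimetric binding parameters.

Binding of an unfolded substrate peptide to a chaperone domain is summarised
by the dissociation constant K_d and the decomposition ΔG = ΔH + (−TΔS).
Raw isotherm fitting is out of scope here; these routines link the printed
parameters through the standard relations and check a reported set for
internal consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Gas constant in kcal·mol⁻¹·K⁻¹, matching calorimetric reporting units.
R_KCAL = 1.987e-3

#: Standard-state concentration (molar) defining ΔG = RT·ln(K_d / C0).
STANDARD_STATE_M = 1.0


@dataclass
class BindingThermo:
    """A binding-thermodynamics record at a stated temperature.

    Fields are in the units calorimetry papers print: ``kd`` molar,
    energies kcal/mol, ``temperature`` kelvin. Any field other than
    ``temperature`` may be None (partially reported datasets).
    """

    temperature: float
    kd: float | None = None
    dG: float | None = None
    dH: float | None = None
    minus_TdS: float | None = None


def dg_from_kd(kd: float, temperature: float) -> float:
    """Standard binding free energy RT·ln(K_d/1 M) in kcal/mol.

    Parameters
    ----------
    kd : dissociation constant in molar; must be positive.
    temperature : absolute temperature in kelvin; must be positive.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature * math.log(kd / STANDARD_STATE_M)


def kd_from_dg(dG: float, temperature: float) -> float:
    """Inverse of :func:`dg_from_kd` (molar)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return STANDARD_STATE_M * math.exp(dG / (R_KCAL * temperature))


def entropy_term(dG: float, dH: float) -> float:
    """Entropic contribution −TΔS = ΔG − ΔH (kcal/mol).

    A positive value means entropy opposes binding (enthalpy-driven
    interaction); a negative value means entropy favours it.
    """
    if not (math.isfinite(dG) and math.isfinite(dH)):
        raise ValueError("dG and dH must be finite")
    return dG - dH


def check_consistency(
    thermo: BindingThermo,
    tol_decomposition: float = 0.1,
    tol_kd: float = 0.1,
) -> dict:
    """Verify the two identities a complete record must satisfy.

    Checks ``dG == dH + minus_TdS`` and ``dG == RT·ln(kd/1 M)`` against the
    given tolerances (kcal/mol). Missing fields yield a partial report with
    the corresponding check marked ``None`` rather than an error.

    Returns a dict with per-check residuals, verdicts, and an overall
    ``consistent`` flag (True only if every performed check passed).
    """
    report: dict = {"temperature_K": thermo.temperature}

    if thermo.dG is not None and thermo.dH is not None and thermo.minus_TdS is not None:
        resid = thermo.dG - (thermo.dH + thermo.minus_TdS)
        report["decomposition_residual_kcal_mol"] = resid
        report["decomposition_ok"] = abs(resid) <= tol_decomposition
    else:
        report["decomposition_residual_kcal_mol"] = None
        report["decomposition_ok"] = None

    if thermo.dG is not None and thermo.kd is not None:
        dg_calc = dg_from_kd(thermo.kd, thermo.temperature)
        resid = thermo.dG - dg_calc
        report["dg_from_kd_kcal_mol"] = dg_calc
        report["kd_residual_kcal_mol"] = resid
        report["kd_ok"] = abs(resid) <= tol_kd
    else:
        report["dg_from_kd_kcal_mol"] = None
        report["kd_residual_kcal_mol"] = None
        report["kd_ok"] = None

    performed = [v for v in (report["decomposition_ok"], report["kd_ok"]) if v is not None]
    report["consistent"] = all(performed) if performed else None
    return report
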