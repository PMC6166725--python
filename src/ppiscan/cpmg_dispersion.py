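"""Two-state fast-exchange CPMG relaxation-dispersion analysis.

A nucleus exchanging between two conformations (e.g. the trans and cis forms
of a peptidyl–prolyl bond on a catalyst) faster than their chemical-shift
difference shows a single population-averaged resonance whose effective
transverse relaxation rate depends on the CPMG refocusing frequency:

    R2eff(ν) = R2⁰ + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)]

with exchange rate k_ex = k_ab + k_ba and amplitude Φ = p_a·p_b·δω². In this
fast-exchange limit only R2⁰, k_ex and Φ are identifiable; the populations
and δω are not separable and are never reported individually here.

The module converts constant-time CPMG intensities to R2eff, fits the
three-parameter model by bounded multi-start least squares, performs a
flat-vs-exchange F-test so that exchange is never claimed from a flat curve,
and implements the fast-exchange regime check (comparing the expected δω
with the fitted k_ex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

#: ¹⁵N/¹H gyromagnetic ratio magnitude; converts the spectrometer ¹H
#: frequency (MHz) to the ¹⁵N frequency (MHz), hence ppm → Hz for ¹⁵N.
GAMMA_RATIO_15N = 0.10136767

#: k_ex multi-start grid (s⁻¹); the model is weakly identifiable at fast
#: exchange, so every fit is attempted from each of these.
KEX_STARTS = (50.0, 200.0, 740.0, 2000.0, 5000.0)

R2_0_MAX = 100.0
KEX_MAX = 1e5


@dataclass
class DispersionCurve:
    """R2eff versus CPMG refocusing frequency.

    ``nu`` in Hz (all positive), ``r2eff`` in s⁻¹, optional per-point
    ``sd`` in s⁻¹ used as weights. Acquisition metadata (temperature °C,
    spectrometer ¹H frequency MHz, constant relaxation delay s) travels
    with the curve.
    """

    nu: np.ndarray
    r2eff: np.ndarray
    sd: np.ndarray | None = None
    temperature: float | None = None
    field: float | None = None
    t_relax: float = 0.050

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.nu <= 0):
            raise ValueError("all nu_CPMG values must be positive")
        if not np.all(np.isfinite(self.r2eff)):
            raise ValueError("R2eff values must be finite")
        if self.nu.shape != self.r2eff.shape:
            raise ValueError("nu and r2eff must have equal length")


@dataclass
class ExchangeFit:
    """Result of fitting a dispersion curve.

    ``model`` is the F-test verdict: ``"exchange"`` if the three-parameter
    model is justified over a flat line at the chosen significance level,
    else ``"flat"``. Exchange parameters and uncertainties are reported
    either way; for a flat verdict ``flat_r2_0`` is the quantity to quote.
    """

    r2_0: float
    kex: float
    phi: float
    stderr: dict = field(default_factory=dict)
    ssr: float = np.nan
    flat_r2_0: float = np.nan
    flat_ssr: float = np.nan
    f_pvalue: float = np.nan
    model: str = "exchange"
    n_points: int = 0


def r2eff_from_intensities(I, I0, t_relax: float):
    """Effective relaxation rate from constant-time CPMG intensities.

    R2eff = −ln(I/I0)/T_relax. Intensities above the reference (possible
    at low noise floors) give negative rates, which are returned but
    flagged with a warning rather than silently clipped.
    """
    I = np.asarray(I, dtype=float)
    I0 = np.asarray(I0, dtype=float)
    if t_relax <= 0:
        raise ValueError(f"t_relax must be positive, got {t_relax}")
    if np.any(I <= 0) or np.any(I0 <= 0):
        raise ValueError("intensities must be positive")
    r2 = -np.log(I / I0) / t_relax
    if np.any(np.asarray(r2) < 0):
        warnings.warn(
            "intensity above reference gives negative R2eff (noise?)",
            stacklevel=2,
        )
    return r2


def meiboom_r2eff(r2_0: float, kex: float, phi, nu):
    """Fast-exchange (Meiboom) dispersion model, exact evaluation.

    Parameters: plateau rate ``r2_0`` (s⁻¹), exchange rate ``kex`` (s⁻¹,
    positive), amplitude ``phi`` = p_a·p_b·δω² (s⁻²), refocusing frequency
    ``nu`` (Hz, positive; scalar or array).
    """
    nu = np.asarray(nu, dtype=float)
    if kex <= 0:
        raise ValueError(f"kex must be positive, got {kex}")
    if np.any(nu <= 0):
        raise ValueError("nu must be positive")
    x = kex / (4.0 * nu)
    out = r2_0 + (phi / kex) * (1.0 - np.tanh(x) / x)
    return out if out.shape else float(out)


def _exchange_residuals(params, nu, r2eff, weights):
    model = meiboom_r2eff(
        params["r2_0"].value, params["kex"].value, params["phi"].value, nu
    )
    return (r2eff - model) * weights


def fit_dispersion(
    curve: DispersionCurve,
    alpha: float = 0.05,
    kex_starts: tuple = KEX_STARTS,
    bootstrap: int = 0,
    seed: int | None = None,
) -> ExchangeFit:
    """Fit the Meiboom model with multi-start bounded least squares.

    Also fits the nested flat model (R2eff = const) and runs an F-test
    between the two; ``model`` in the result is ``"exchange"`` only when
    the p-value is below ``alpha``, which controls the false-exchange rate
    on genuinely flat curves.

    Parameter uncertainties come from the fit covariance; pass
    ``bootstrap=N`` (with a seed) for residual-resampling errors instead.

    Raises
    ------
    ValueError : fewer than 4 distinct frequencies (under-determined).
    RuntimeError : no start converges.
    """
    nu, r2eff = curve.nu, curve.r2eff
    if len(np.unique(nu)) < 4:
        raise ValueError("exchange model needs >= 4 distinct nu_CPMG points")
    weights = 1.0 / curve.sd if curve.sd is not None else np.ones_like(nu)

    # flat (no-exchange) model: weighted mean
    flat_r2 = float(np.sum(r2eff * weights**2) / np.sum(weights**2))
    flat_ssr = float(np.sum(((r2eff - flat_r2) * weights) ** 2))

    amplitude = max(float(np.max(r2eff) - np.min(r2eff)), 1e-6)
    best = None
    for kex0 in kex_starts:
        params = Parameters()
        params.add("r2_0", value=float(np.min(r2eff)), min=1e-6, max=R2_0_MAX)
        params.add("kex", value=kex0, min=1e-3, max=KEX_MAX)
        # phi sized so phi/kex matches the observed dispersion amplitude
        params.add("phi", value=amplitude * kex0, min=0.0)
        try:
            res = minimize(
                _exchange_residuals, params, args=(nu, r2eff, weights),
                method="leastsq", nan_policy="raise",
            )
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("dispersion fit did not converge from any start")

    ssr = float(best.chisqr)
    n = len(nu)
    # F-test between nested models (1 vs 3 parameters)
    dof_extra, dof_fit = 2, n - 3
    if dof_fit > 0 and ssr > 0:
        f_stat = ((flat_ssr - ssr) / dof_extra) / (ssr / dof_fit)
        f_pvalue = float(stats.f.sf(max(f_stat, 0.0), dof_extra, dof_fit))
    elif ssr == 0 and flat_ssr > 0:
        f_pvalue = 0.0  # exchange model exact, flat is not
    else:
        f_pvalue = 1.0

    stderr = {
        name: (best.params[name].stderr if best.params[name].stderr is not None else np.nan)
        for name in ("r2_0", "kex", "phi")
    }
    if bootstrap:
        stderr = _bootstrap_stderr(curve, best, weights, bootstrap, seed)

    return ExchangeFit(
        r2_0=float(best.params["r2_0"].value),
        kex=float(best.params["kex"].value),
        phi=float(best.params["phi"].value),
        stderr=stderr,
        ssr=ssr,
        flat_r2_0=flat_r2,
        flat_ssr=flat_ssr,
        f_pvalue=f_pvalue,
        model="exchange" if f_pvalue < alpha else "flat",
        n_points=n,
    )


def _bootstrap_stderr(curve, best, weights, n_boot, seed):
    """Residual-resampling bootstrap for parameter uncertainties."""
    rng = np.random.default_rng(seed)
    fitted = meiboom_r2eff(
        best.params["r2_0"].value, best.params["kex"].value,
        best.params["phi"].value, curve.nu,
    )
    residuals = curve.r2eff - fitted
    draws = {"r2_0": [], "kex": [], "phi": []}
    for _ in range(n_boot):
        resampled = fitted + rng.choice(residuals, size=len(residuals), replace=True)
        params = Parameters()
        for name in ("r2_0", "kex", "phi"):
            p = best.params[name]
            params.add(name, value=p.value, min=p.min, max=p.max)
        try:
            res = minimize(
                _exchange_residuals, params,
                args=(curve.nu, resampled, weights), method="leastsq",
            )
        except Exception:
            continue
        for name in draws:
            draws[name].append(res.params[name].value)
    return {name: float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            for name, vals in draws.items()}


def regime_check(
    kex: float,
    delta_omega_ppm: float,
    field_mhz: float,
    nucleus_ratio: float = GAMMA_RATIO_15N,
    mode: str = "angular",
    threshold: float = 1.0,
) -> dict:
    """Judge whether an exchange process is in the fast regime.

    Fast exchange requires the shift difference between the states to be
    small against the exchange rate. ``delta_omega_ppm`` is converted to Hz
    at the nucleus frequency ``field_mhz × nucleus_ratio`` and compared
    with ``kex``:

    - ``mode="angular"``: fast iff kex / (2π·δω_Hz) ≥ threshold, treating
      kex (s⁻¹) as an angular rate against δω as angular frequency.
    - ``mode="direct"``: fast iff kex / δω_Hz ≥ threshold, the plain
      Hz-vs-s⁻¹ comparison common in the experimental literature.

    δω = 0 is trivially fast in both modes.
    """
    if kex <= 0 or field_mhz <= 0:
        raise ValueError("kex and field_mhz must be positive")
    if mode not in ("angular", "direct"):
        raise ValueError("mode must be 'angular' or 'direct'")
    dw_hz = abs(delta_omega_ppm) * field_mhz * nucleus_ratio
    if dw_hz == 0:
        ratio = np.inf
    else:
        ratio = kex / (2.0 * np.pi * dw_hz) if mode == "angular" else kex / dw_hz
    return {
        "kex_s": kex,
        "delta_omega_ppm": delta_omega_ppm,
        "delta_omega_hz": dw_hz,
        "mode": mode,
        "ratio": float(ratio),
        "regime": "fast" if ratio >= threshold else "intermediate_or_slow",
    }
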