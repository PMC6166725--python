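"""Pipeline orchestration: configuration, staging, logging, manifests.

A run executes a selection of stages — ``simulate`` → ``profile`` →
``titrate`` → ``cpmg_fit`` → ``torsion_scan`` → ``thermo`` — into one run
directory, echoing every parameter and seed into ``manifest.json`` (enough
to reproduce the run bit-exactly) and a human-readable ``summary.txt``.

Configuration is a single nested mapping (YAML on disk); unknown keys are
rejected before any stage runs, and stage failures halt the run with a
stage-tagged error.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, binding_thermo, io, sequence_profile, synthetic_data
from . import cpmg_dispersion, titration_mapping, torsion_hbond

logger = logging.getLogger("ppiscan")

#: Synthetic unfolded-substrate demo sequence (60 aa): hydrophilic flanks
#: around one hydrophobic stretch (residues 25–33, LVAGPWLIV) carrying a
#: proline-aromatic motif (P29–W30); P13 is a control proline in a
#: hydrophilic region with no aromatic neighbour.
DEMO_SEQUENCE = (
    "SNKEDQTSGS" "KDPEQNSTGD" "QSTALVAGPW" "LIVTDKEQSN" "GSDKEQTSNG" "DSKTEQNGSD"
)

STAGES = ("simulate", "profile", "titrate", "cpmg_fit", "torsion_scan", "thermo")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "runs/demo",
    "stages": list(STAGES),
    "log_level": "INFO",
    "simulate": {
        "titration": {
            "sequence": DEMO_SEQUENCE,
            "sites": [[25, 33, 0.9]],
            "ratios": [0.1, 0.2, 0.5, 1.0, 2.0],
            "noise_sd": 0.02,
            "csp_max": [0.05, 0.25],
            "kd": 47e-6,
            "substrate_conc": 100e-6,
        },
        "dispersion": {"r2_0": 15.0, "kex": 740.0, "phi": 2000.0, "noise_sd": 0.3},
        "scan": {
            "n_residues": 5,
            "proline_index": 3,
            "start_omega": -174.0,
            "end_omega": 0.0,
            "step": 0.2,
            "dwell": 2.0,
            "direction": "clockwise",
        },
    },
    "profile": {"window": 9, "threshold": 0.0, "fasta": None, "sequence": None},
    "titrate": {
        "input": None,
        "point": None,  # None = final titration point
        "min_run": 5,
        "method": "mad",
        "k": 2.0,
        "cutoff": 0.7,
        "bridge_missing": True,
        "csp_thresholds": [0.015, 0.025],
    },
    "cpmg_fit": {"input": None, "alpha": 0.05, "t_relax": 0.050,
                 "field": 800.0, "delta_omega_ppm": 0.8},
    "torsion_scan": {"input": None, "donor": "B:1:H", "acceptor": None,
                     "d_max": 2.5, "angle_min": 130.0},
    "thermo": {"kd": 47e-6, "temperature": 295.15, "dg": None,
               "dh": -5.9, "minus_tds": None},
}


class ConfigError(ValueError):
    pass


def _check_keys(given: dict, template: dict, path: str = ""):
    for key, value in given.items():
        if key not in template:
            raise ConfigError(f"unknown configuration key {path + key!r}; "
                              f"expected one of {sorted(template)}")
        if isinstance(template[key], dict) and isinstance(value, dict):
            _check_keys(value, template[key], path + key + ".")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(source: dict | str | Path | None = None) -> dict:
    """Validate a config mapping (or YAML file) against the schema and
    merge it over the defaults. Unknown keys anywhere raise ConfigError."""
    if source is None:
        given: dict = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            given = yaml.safe_load(fh) or {}
    else:
        given = source
    if not isinstance(given, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(given, DEFAULT_CONFIG)
    cfg = _merge(DEFAULT_CONFIG, given)
    unknown_stages = set(cfg["stages"]) - set(STAGES)
    if unknown_stages:
        raise ConfigError(f"unknown stage(s) {sorted(unknown_stages)}")
    return cfg


def run_pipeline(config: dict | str | Path | None = None) -> Path:
    """Execute the configured stages into the run directory.

    Returns the run directory; raises with a stage-tagged message on the
    first stage failure. Reruns with the same config and seed reproduce
    identical tables.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=getattr(logging, cfg["log_level"].upper(), logging.INFO))
    logger.info("run directory: %s", outdir)
    logger.info("parameters: %s", json.dumps(cfg, default=str))

    summary: list[str] = [f"ppiscan {__version__} pipeline run", ""]
    state: dict = {}

    for stage in cfg["stages"]:
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, outdir, state, summary)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    manifest = {"version": __version__, "config": cfg}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg, outdir, state, summary):
    seed = int(cfg["seed"])
    tcfg = cfg["simulate"]["titration"]
    tspec = synthetic_data.TitrationSpec(
        sequence=tcfg["sequence"],
        sites=[tuple(s) for s in tcfg["sites"]],
        ratios=tuple(tcfg["ratios"]),
        noise_sd=tcfg["noise_sd"],
        csp_max=tuple(tcfg["csp_max"]),
        kd=tcfg["kd"],
        substrate_conc=tcfg["substrate_conc"],
        seed=seed,
    )
    series = synthetic_data.generate_titration(tspec)
    io.write_titration(series, outdir / "titration.tsv", seed=seed)
    state["titration"] = series

    dcfg = cfg["simulate"]["dispersion"]
    dspec = synthetic_data.DispersionSpec(
        r2_0=dcfg["r2_0"], kex=dcfg["kex"], phi=dcfg["phi"],
        noise_sd=dcfg["noise_sd"], seed=seed,
    )
    curve = synthetic_data.generate_dispersion(dspec)
    io.write_dispersion(curve, outdir / "dispersion.tsv", meta={"seed": seed})
    state["dispersion"] = curve

    scfg = cfg["simulate"]["scan"]
    sspec = synthetic_data.PeptideScanSpec(**scfg)
    ensemble = synthetic_data.generate_peptide_scan(sspec)
    io.write_pdb(ensemble, outdir / "scan.pdb")
    state["scan"] = ensemble
    state["scan_spec"] = sspec
    summary.append(
        f"simulate: {len(series.points)} titration points over "
        f"{len(tspec.sequence)} residues; {len(curve.nu)}-point dispersion "
        f"curve; {len(ensemble)}-model omega scan (seed {seed})"
    )


def _stage_profile(cfg, outdir, state, summary):
    pcfg = cfg["profile"]
    if pcfg["fasta"]:
        sequence = next(iter(io.read_fasta(pcfg["fasta"]).values()))
    else:
        sequence = pcfg["sequence"] or cfg["simulate"]["titration"]["sequence"]
    profile = sequence_profile.hydrophobicity_profile(sequence, window=pcfg["window"])
    stretches = sequence_profile.hydrophobic_stretches(profile, threshold=pcfg["threshold"])
    hits = sequence_profile.scan_proline_aromatic(sequence, stretches)

    import pandas as pd

    in_stretch = np.zeros(len(sequence), dtype=bool)
    for s, e in stretches:
        in_stretch[s : e + 1] = True
    io._write_tsv(
        pd.DataFrame({
            "position": np.arange(1, len(sequence) + 1),
            "aa": list(sequence),
            "score": profile.scores,
            "in_stretch": in_stretch,
        }),
        outdir / "profile.tsv",
        {"window": pcfg["window"], "threshold": pcfg["threshold"], "scale": "roseman1988"},
    )
    io._write_tsv(
        pd.DataFrame(
            [{"proline": h.proline_position + 1, "aromatic": h.aromatic_position + 1,
              "aromatic_residue": h.aromatic_residue,
              "in_hydrophobic_stretch": h.in_hydrophobic_stretch}
             for h in hits],
            columns=["proline", "aromatic", "aromatic_residue", "in_hydrophobic_stretch"],
        ),
        outdir / "motifs.tsv",
    )
    state["stretches"] = stretches
    summary.append(
        f"profile: {len(stretches)} hydrophobic stretch(es) above "
        f"{pcfg['threshold']}; {len(hits)} proline-aromatic hit(s)"
    )


def _stage_titrate(cfg, outdir, state, summary):
    tcfg = cfg["titrate"]
    series = (io.read_titration(tcfg["input"]) if tcfg["input"]
              else state.get("titration") or io.read_titration(outdir / "titration.tsv"))
    point = tcfg["point"] if tcfg["point"] is not None else series.ratios[-1]
    ratios = titration_mapping.intensity_ratios(series, point)
    sig = titration_mapping.significance_mask(
        ratios, method=tcfg["method"], k=tcfg["k"], cutoff=tcfg["cutoff"])
    sites = titration_mapping.call_binding_sites(
        ratios, sig, min_run=tcfg["min_run"], bridge_missing=tcfg["bridge_missing"])
    csp_table = titration_mapping.csp_profile(series, point)

    merged = ratios.merge(csp_table[["residue", "csp_ppm", "class"]], on="residue")
    merged["significant"] = sig.to_numpy()
    io._write_tsv(merged, outdir / "residue_analysis.tsv",
                  {"point": point, "method": tcfg["method"], "k": tcfg["k"],
                   "min_run": tcfg["min_run"]})
    io.write_sites(sites, outdir / "sites.tsv", {"point": point})
    state["sites"] = sites
    summary.append(
        f"titrate: point 1:{point}, {int(sig.sum())} significant residues, "
        f"{len(sites)} called site(s): "
        + (", ".join(f"{s.start}-{s.end}" for s in sites) or "none")
    )


def _stage_cpmg_fit(cfg, outdir, state, summary):
    ccfg = cfg["cpmg_fit"]
    curve = (io.read_dispersion(ccfg["input"]) if ccfg["input"]
             else state.get("dispersion") or io.read_dispersion(outdir / "dispersion.tsv"))
    fit = cpmg_dispersion.fit_dispersion(curve, alpha=ccfg["alpha"])
    regime = cpmg_dispersion.regime_check(
        fit.kex if fit.model == "exchange" else max(fit.kex, 1e-3),
        ccfg["delta_omega_ppm"], ccfg["field"],
    )

    import pandas as pd

    io._write_tsv(
        pd.DataFrame([{
            "model": fit.model, "r2_0": fit.r2_0, "kex": fit.kex, "phi": fit.phi,
            "r2_0_err": fit.stderr.get("r2_0"), "kex_err": fit.stderr.get("kex"),
            "phi_err": fit.stderr.get("phi"), "ssr": fit.ssr,
            "flat_r2_0": fit.flat_r2_0, "f_pvalue": fit.f_pvalue,
            "regime": regime["regime"],
        }]),
        outdir / "dispersion_fit.tsv", {"alpha": ccfg["alpha"]},
    )
    nu_dense = np.logspace(np.log10(curve.nu.min()), np.log10(curve.nu.max()), 200)
    io._write_tsv(
        pd.DataFrame({
            "nu_cpmg_hz": nu_dense,
            "r2eff_fit": cpmg_dispersion.meiboom_r2eff(fit.r2_0, fit.kex, fit.phi, nu_dense),
        }),
        outdir / "dispersion_fitted_curve.tsv",
    )
    state["fit"] = fit
    summary.append(
        f"cpmg_fit: model={fit.model}, kex={fit.kex:.0f} s-1, "
        f"phi={fit.phi:.0f} s-2, r2_0={fit.r2_0:.2f} s-1, "
        f"regime={regime['regime']}"
    )


def _stage_torsion_scan(cfg, outdir, state, summary):
    scfg = cfg["torsion_scan"]
    if scfg["input"]:
        ensemble = io.read_pdb(scfg["input"])
    else:
        ensemble = state.get("scan") or io.read_pdb(outdir / "scan.pdb")
    spec = state.get("scan_spec") or synthetic_data.PeptideScanSpec(
        **cfg["simulate"]["scan"])
    acceptor = scfg["acceptor"] or f"A:{spec.proline_index - 1}:O"
    frames, scan_summary = torsion_hbond.track_scan(
        ensemble, scfg["donor"], acceptor, spec.proline_index, spec.schedule(),
        d_max=scfg["d_max"], angle_min=scfg["angle_min"],
    )
    io.write_frames(frames, outdir / "scan_frames.tsv",
                    {"donor": scfg["donor"], "acceptor": acceptor,
                     "d_max": scfg["d_max"], "angle_min": scfg["angle_min"]})
    (outdir / "scan_summary.json").write_text(
        json.dumps(scan_summary, indent=2) + "\n")
    state["scan_summary"] = scan_summary
    first = scan_summary["first_strong_ns"]
    summary.append(
        f"torsion_scan: {scan_summary['n_frames']} frames, closest approach "
        f"{scan_summary['closest_approach_A']:.2f} A at "
        f"{scan_summary['closest_approach_ns']:.3f} ns "
        f"(omega {scan_summary['closest_approach_omega']:.1f} deg); "
        + (f"H-bond strong from {first:.3f} ns" if first is not None
           else "no strong H-bond")
    )


def _stage_thermo(cfg, outdir, state, summary):
    tcfg = cfg["thermo"]
    dg = tcfg["dg"]
    if dg is None and tcfg["kd"] is not None:
        dg = binding_thermo.dg_from_kd(tcfg["kd"], tcfg["temperature"])
    minus_tds = tcfg["minus_tds"]
    if minus_tds is None and dg is not None and tcfg["dh"] is not None:
        minus_tds = binding_thermo.entropy_term(dg, tcfg["dh"])
    record = binding_thermo.BindingThermo(
        temperature=tcfg["temperature"], kd=tcfg["kd"], dG=dg,
        dH=tcfg["dh"], minus_TdS=minus_tds,
    )
    report = binding_thermo.check_consistency(record)
    out = {
        "kd_M": record.kd, "temperature_K": record.temperature,
        "dG_kcal_mol": record.dG, "dH_kcal_mol": record.dH,
        "minus_TdS_kcal_mol": record.minus_TdS, "consistency": report,
    }
    (outdir / "thermo.json").write_text(json.dumps(out, indent=2) + "\n")
    state["thermo"] = out
    summary.append(
        f"thermo: Kd={record.kd:.2e} M -> dG={record.dG:.2f} kcal/mol, "
        f"dH={record.dH:.2f}, -TdS={record.minus_TdS:.2f} "
        f"(consistent={report['consistent']})"
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "profile": _stage_profile,
    "titrate": _stage_titrate,
    "cpmg_fit": _stage_cpmg_fit,
    "torsion_scan": _stage_torsion_scan,
    "thermo": _stage_thermo,
}
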