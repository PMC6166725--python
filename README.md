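# ppiscan

Quantitative analyses of how a chaperone's peptidyl–prolyl cis/trans
isomerase (PPIase) domain recognizes unfolded substrate proteins and
catalyzes isomerization. The package is written for structural-biology /
biomolecular-NMR practitioners studying chaperone–substrate recognition —
e.g. trigger factor acting on an unfolded maltose-binding-protein fragment —
and bundles five analyses that are usually scattered across ad-hoc scripts:

1. **Sequence profiling** (`sequence_profile`): sliding-window Roseman
   hydrophobicity over a substrate sequence, extraction of hydrophobic
   stretches (score > 0), and a scan for the *proline-aromatic motif* — a
   proline immediately adjacent to W/F/Y/H — the recognition element the
   PPIase domain selects.
2. **Titration mapping** (`titration_mapping`): combined amide chemical
   shift perturbation Δδ = √(Δδ(¹H)² + (Δδ(¹⁵N)/5)²), differential line
   broadening (I/I₀), and binding-site calling as a continuous stretch of
   more than four residues with significant intensity reduction, bridging
   invisible residues (prolines, unassigned peaks).
3. **CPMG relaxation dispersion** (`cpmg_dispersion`): the two-state
   fast-exchange (Meiboom) model

   R₂eff(ν) = R₂⁰ + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)],  Φ = pₐ·p_b·δω²

   fitted by bounded multi-start least squares, with a nested flat-model
   F-test so exchange is never claimed from a flat curve, and a
   fast-exchange regime check (δω in Hz vs k_ex).
4. **Torsion scan** (`torsion_hbond`): a kinematic re-implementation of a
   restrained ω-rotation scan — the prolyl peptide torsion
   ω = Cα(i−1)–C(i−1)–N(i)–Cα(i) driven from trans (−174°) to cis (0°) at
   0.2° per 2 ps window — with rigid rotation of the N-terminal segment
   about the C–N bond and per-frame hydrogen-bond geometry (H···O distance,
   N–H···O angle; strong iff < 2.5 Å and ≥ 130°). No force field: each
   frame sits exactly on its scheduled ω.
5. **Binding thermodynamics** (`binding_thermo`): ΔG = RT·ln(K_d/1 M),
   −TΔS = ΔG − ΔH, and a consistency check of a reported parameter set.

A seeded synthetic-data module (`synthetic_data`) generates titration peak
tables with planted binding sites, dispersion curves from the forward model,
and idealized-backbone scan ensembles, so the entire pipeline is testable
with ground truth and no downloads. `pipeline` + the `ppiscan` CLI tie the
stages into one reproducible run with a full parameter manifest.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each writes its tables under `results/` and prints what it found:

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_profile_substrate.py
python analysis/03_map_binding_sites.py
python analysis/04_fit_dispersion.py
python analysis/05_torsion_scan.py
python analysis/06_thermodynamics.py
```

Output (seed 1):

```
1 hydrophobic stretch(es) above 0:
  residues 25-32
1 proline-aromatic motif hit(s):
  P29-W30 (in hydrophobic stretch: True)

titration point 1:2.0; 8 residues with significant intensity reduction
  called site 25-33: mean reduction 0.87 over 8 scored residues
planted ground truth: 25-33 (depth 0.9)

dispersion fit: model=exchange, kex = 766 +/- 111 /s, phi = 2130 /s^2,
  R2_0 = 14.99 /s (F-test p = 7.67e-10)
regime check: delta_omega = 64.9 Hz vs kex = 766 /s -> fast
no-exchange control: verdict = flat (R2_0 = 15.06 /s)

clockwise scan (871 frames, 1.74 ns):
  closest approach 2.10 A at 0.84 ns (omega = -90 deg)
  strong H-bond in 471 frames, first at 0.37 ns
counterclockwise scan (931 frames, 1.86 ns): closest approach 3.09 A,
  0 strong frames

Kd = 47 uM at 295.15 K
dG   = -5.84 kcal/mol
dH   = -5.90 kcal/mol
-TdS = +0.06 kcal/mol (binding is enthalpy-driven)
```

Reading the numbers: the motif scan finds the planted proline-tryptophan
pair inside the single hydrophobic stretch; site calling recovers the
planted binding site exactly (the in-site proline is bridged, so the site
spans 25–33 with 8 scored residues); the dispersion fit recovers the
generating exchange rate (740 s⁻¹) within its uncertainty from a noisy
curve and correctly classifies the exchange as fast; the flat control is
not assigned exchange. In the torsion scan the catalytic amide probe meets
the carbonyl oxygen of the residue preceding the proline exactly at the
twisted *syn* geometry (ω = −90°, 0.84 ns of the clockwise schedule) where
the hydrogen bond classifies strong, while the counterclockwise rotation
never brings the two groups within bonding distance — the directionality of
the catalytic mechanism. The thermodynamic decomposition shows binding is
enthalpy-driven with a near-zero entropic term.

The same stages are available as CLI subcommands
(`ppiscan run|simulate|profile|titrate|cpmg-fit|torsion-scan|thermo`), e.g.

```bash
ppiscan thermo --kd 47e-6 --dh -5.9
ppiscan run --outdir runs/demo --seed 1
```

## Layout

```
src/ppiscan/        library: one module per analysis stage + synthetic data,
                    I/O, pipeline, CLI
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property-based, acceptance)
scripts/            acceptance recomputation
docs/methods.md     models, assumptions, parameter choices, limitations
```
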