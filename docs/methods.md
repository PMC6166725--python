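# Methods

This note documents the models implemented in `ppiscan`, the assumptions
behind them, the parameters that matter, what the synthetic data do and do
not emulate, and the numerical choices made where the design was open.

## Sequence profiling

Per-residue hydrophobicity uses the Roseman (1988) side-chain transfer
free-energy scale (positive = hydrophobic), averaged over a centered sliding
window (default 9 residues — wide enough to suppress single-residue noise
while resolving chaperone-binding-sized stretches). Terminal positions where
the window does not fit are reported as undefined rather than computed from
shrunken windows, which would bias scores toward zero at the ends. The scale
is a plain mapping and can be swapped for any other hydropathy scale; only
the sign convention (positive = hydrophobic) is assumed by the stretch
extraction. Hydrophobic stretches are maximal runs of defined positions with
score strictly above the threshold (default 0).

The proline-aromatic motif scan reports every proline with an immediately
adjacent aromatic residue. The default aromatic alphabet is {W, F, Y, H}:
tryptophan and tyrosine/histidine neighbours are directly supported by
observed chaperone–substrate contacts; phenylalanine is included as a
conservative generalization and can be excluded by passing a smaller
alphabet. A proline flanked by two aromatics yields two hits, one per
neighbour.

## Titration mapping

Combined amide chemical shift perturbation:
Δδ = √(Δδ(¹H)² + (Δδ(¹⁵N)/5)²) ppm, the standard 5:1 nitrogen scaling.
Classification thresholds default to 0.015 ppm (moderate) and 0.025 ppm
(strong), the customary interface-mapping cutoffs; both are arguments.

Differential line broadening is analysed as per-residue intensity ratios
I/I₀ against the free-state reference. "Significant intensity reduction" is
not uniquely defined in the field; two rules are provided:

* **robust (default)**: significant iff I/I₀ < median − k·MAD with k = 2 and
  the MAD scaled by 1.4826 to be consistent with a normal σ. Using the
  profile's own median makes the rule invariant to uniform broadening from
  complex size or dilution, which shifts every residue.
* **fixed cutoff**: significant iff I/I₀ < 0.7.

A binding site is a maximal run of consecutive significant residues
containing at least `min_run = 5` scored residues ("more than four").
Residues with no amide observable — prolines and unassigned positions —
bridge a run by default (they count toward the span, not toward the scored
minimum), since a binding site containing a proline would otherwise be
artificially split; a strict no-bridge mode exists. Site calling defaults to
the final titration point, where broadening contrast is largest; the
significance rule can be applied per point.

## CPMG relaxation dispersion

The fast-exchange (Meiboom) two-state model is used throughout:

R₂eff(ν) = R₂⁰ + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)]

with exchange rate k_ex and amplitude Φ = pₐ·p_b·δω². In this regime only
R₂⁰, k_ex and Φ are identifiable; populations and δω are never reported
individually. No slow/intermediate (Carver–Richards) model is provided —
the analysis commits to the fast limit and verifies it (below). Intensities
from constant-time experiments convert as R₂eff = −ln(I/I₀)/T_relax
(default T_relax = 50 ms); intensities above reference give negative rates,
returned with a warning.

Fitting is weighted least squares (lmfit/Levenberg–Marquardt) over
(R₂⁰, k_ex, Φ) with bounds R₂⁰ ∈ (0, 100] s⁻¹, k_ex ∈ (0, 10⁵] s⁻¹, Φ ≥ 0.
Because the model is weakly identifiable at fast exchange, every fit is
multi-started from k_ex ∈ {50, 200, 740, 2000, 5000} s⁻¹ with Φ initialized
from the observed dispersion amplitude × k_ex, and the lowest-SSR solution
kept. Model selection against the nested flat model (R₂eff = const) uses an
F-test at α = 0.05; on genuinely flat data the bounded fit typically hits
Φ = 0, making the test conservative (measured false-exchange rate well
under the nominal 5%). Parameter uncertainties come from the fit covariance
by default; a seeded residual-resampling bootstrap is available.

**Identifiability under the default synthetic conditions.** With the default
16 log-spaced ν points in [25, 1000] Hz, parameters (15, 740, 2000) and
Gaussian noise σ = 0.3 s⁻¹, the Cramér–Rao bound gives a relative standard
deviation of ≈ 23% on k_ex — the dispersion amplitude is only ≈ 2.3 s⁻¹
against per-point noise of 0.3 s⁻¹. The observed median relative error of
the fit (≈ 20% over seeded replicates) is therefore close to the
information-theoretic floor, and no estimator can do materially better at
this noise level; sub-10% recovery requires σ ≲ 0.1 s⁻¹ or a denser/wider
grid. Noiseless curves refit to the generating parameters to better than
0.1%.

The regime check converts an expected δω (ppm) to Hz at the ¹⁵N frequency
(spectrometer ¹H MHz × 0.10136767) and compares with k_ex in two
conventions, neither asserted as canonical: `angular` (fast iff
k_ex/(2π·δω_Hz) ≥ 1) and `direct` (fast iff k_ex/δω_Hz ≥ 1, the plain
Hz-vs-s⁻¹ comparison common in experimental reports).

## Torsion scan and hydrogen-bond geometry

The scan is kinematic, not dynamical. A schedule advances the ω restraint
center by `step` (default 0.2°) per `dwell` (default 2 ps) from a start to
an end angle; "clockwise" traverses the arc of increasing ω (for the
−174° → 0° endpoints, the 174° arc through −90°, 870 windows, 1.74 ns) and
"counterclockwise" the complementary arc through ±180° (186°, 930 windows,
1.86 ns). The restraint force constant (50 kcal·mol⁻¹·rad⁻²) is carried as
metadata only: each frame sets ω *exactly* to the window center, so thermal
fluctuation about a restraint — a force-field phenomenon — is deliberately
absent. The schedule includes the starting geometry at t = 0, so an
ensemble has (arc/step) + 1 models and a degenerate schedule (start = end)
has one.

Each frame is produced by rigid rotation of all atoms N-terminal of the
prolyl C–N bond (including the preceding carbonyl oxygen) about that bond
axis, from a single canonical trans-built backbone; the proline and
C-terminal segment stay fixed, emulating a substrate held on the catalyst
while the upstream segment swings. The rotation is an exact isometry of
each rigid set, and its handedness is resolved at run time by measurement
so that ω changes by exactly the requested amount. Backbone geometry is
idealized (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å, C=O 1.23 Å, N–H 1.01 Å,
sp² angles, extended φ/ψ); only relative geometry is analysed, so any
internally consistent set serves.

Hydrogen bonds are scored from the donor-amide H···O(acceptor) distance and
the N–H···O angle at the hydrogen. Classification is `strong` iff
d(H···O) < 2.5 Å **and** θ(N–H···O) ≥ 130°. The 2.5 Å distance is the
established strong-H-bond criterion; the angle default is a conventional
linearity cutoff and configurable — the two reference scan geometries
(2.1 Å/152° strong; 4.3 Å/134° none) classify correctly for any angle
threshold up to 152°, the latter on distance alone.

The default probe placement in the generator puts the catalytic amide
(N, H) on the extension of the carbonyl C=O direction at the ω where the
bond is expected to form (−90°, the *syn*/transition-state-like geometry),
at 2.1 Å H···O. By construction the closest approach then falls exactly on
the −90° window (0.84 ns in the full clockwise schedule) with a linear
N–H···O arrangement. Because the oxygen moves on a circle of radius ~1 Å
about the bond axis, the distance criterion is necessarily met over a band
of tens of degrees around the minimum — a sharp single-window onset of the
strong class is geometrically impossible for any fixed probe — so the
meaningful scan observables are the closest-approach window and the
strong/none contrast between rotation directions.

## Binding thermodynamics

ΔG = RT·ln(K_d/1 M) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and a 1 M standard
state; −TΔS = ΔG − ΔH. Default temperature 295.15 K (22 °C, the
calorimetry condition). The consistency checker verifies both identities on
a reported (K_d, ΔG, ΔH, −TΔS, T) record against tolerances defaulting to
0.1 kcal/mol (typical printed error bars) and degrades gracefully on
partial records. Raw isotherm fitting is out of scope; printed parameters
are inputs.

## Synthetic data: what it emulates, what it does not

* **Titrations.** Bound fraction at each chaperone:substrate ratio comes
  from single-site binding (quadratic solution) with K_d defaulting to
  47 µM — the measured chaperone-domain affinity — and substrate
  concentration 100 µM (a typical HSQC sample). In-site residues gain extra
  transverse relaxation ΔR₂ = depth × 200 s⁻¹ scaled by bound fraction over
  a free-state R₂ of 20 s⁻¹ (realistic fast-exchange broadening toward a
  ~60 kDa complex), giving I/I₀ = R₂free/(R₂free + f_b·ΔR₂); shifts move by
  f_b·csp_max. Noise is multiplicative Gaussian (default 2%). Not emulated:
  peak overlap, incomplete assignment beyond prolines, exchange-regime
  crossover, field-dependent broadening — so perfect recovery statistics
  here bound, but do not demonstrate, performance on crowded real spectra.
* **Dispersion.** The forward model is an independently written algebraic
  form of the Meiboom expression (the generator and the fitting module
  share no code) plus Gaussian noise. Not emulated: off-resonance effects,
  pulse imperfections, B₁ inhomogeneity.
* **Scan ensembles.** Idealized backbone, exact ω placement, fixed probe.
  Not emulated: force-field energetics, solvent, thermal fluctuation —
  hence the scan validates geometry/bookkeeping, not molecular dynamics.

One seeded NumPy generator per spec; with zero noise every generator is
bit-reproducible, and seeds are echoed into output headers and run
manifests.

## Numerical choices and degenerate inputs

* Angles are wrapped to (−180°, 180°]; schedules whose arc is not an
  integer multiple of the step (tolerance 10⁻⁹ relative) are rejected.
* Dihedral measurement uses the atan2 formulation (stable near 0°/180°).
* Fits with fewer than 4 distinct frequencies are rejected as
  under-determined; total non-convergence raises, never returns silently.
* PDB output carries 0.001 Å coordinate precision, which bounds dihedrals
  re-measured from files to ~0.06°; in-memory round trips are exact to
  10⁻³ degrees and better.
* Zero reference intensity for an assigned residue is an error (not an
  infinite ratio); unassigned/proline residues propagate as missing values,
  never as zeros.
* Problem sizes in the shipped analyses (60-residue substrate, 16-point
  dispersion curves, 5-residue scan peptide at full 0.2° resolution) were
  chosen so every stage runs in seconds while exercising all code paths.

## Known limitations

* Site-calling significance is a per-profile robust rule, not a
  noise-model-based test; heavily broadened profiles (most residues in
  sites) shift the median and lower sensitivity.
* The fast-exchange model cannot separate populations from δω; fitted Φ is
  the only exchange amplitude reported, and the regime check depends on an
  externally supplied δω estimate.
* The torsion scan's hydrogen-bond onset time is construction-dependent
  (see above); only schedule arithmetic, per-window geometry, and
  direction contrasts are quantitative.
* The hydrophobicity scale ships as published values; window-9 profiles of
  very short sequences (< 9 residues) are entirely undefined by design.
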