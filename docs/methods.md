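# Methods

## Motif model

A putative intramolecular G-quadruplex motif is a chain of maximal runs of
guanines ("tracts") on a single strand. Tracts are greedy: a run of k ≥
`min_tract` guanines is one tract and is never split (so a single long
G-run is one tract, not four). Consecutive tracts are chained when the gap
between them — the loop — is within `loop_min..loop_max` nucleotides, and
every maximal chain of at least four tracts is reported as one motif;
overlapping alternative decompositions of the same region are not
enumerated. Loops may contain G-runs shorter than `min_tract`. Coordinates
are 0-based half-open; scanning covers the given strand, with
reverse-complement scanning available as a CLI flag.

Defaults: `min_tract = 3`, loops 1–7 nt. The tract minimum of three is the
threshold for a three-layer tetrad stack; the loop bounds are the common
putative-quadruplex convention (the motif analyzed here has 1–2 nt loops,
well inside any reasonable bound). The predicted tetrad-layer count is the
length of the shortest tract, and the interlayer cation-site count is one
less — the geometry by which retained NH₄⁺ ions in native MS report on the
stack height.

## Oligonucleotide masses

Masses come from a built-in elemental-composition table: each residue is a
deoxynucleoside monophosphate minus water, and the oligonucleotide mass is
the residue sum plus one water. This residue-sum convention makes mass
exactly additive over concatenation (up to one water), which the adduct
bookkeeping below relies on; it corresponds to an oligonucleotide carrying
one terminal phosphate. Average masses (IUPAC atomic weights) are the
default, matching broad ion-trap peaks; monoisotopic masses are available
by flag. Printed instrument m/z values are treated as calibrated
observations, never as exactness oracles for these theoretical masses.

## Native-MS ion arithmetic and IRₐ

For an ion retaining a ammonium and b ligand cations at negative charge
magnitude z,

    m/z = (M + a·m(NH₄) + b·M_L − (z + a + b)·m(H)) / z

— each retained cation displaces one additional proton, the only convention
consistent with ion formulas of the type [M + 2NH₄ − 6H]⁴⁻. Assignment
matches peaks and candidate species greedily by increasing |m/z error|
within a tolerance (default 1.0 Th, appropriate to an ion trap at the 4−
charge state); each peak takes at most one species and vice versa, and
numerically exact ties resolve toward smaller ligand count, then fewer
ammoniums, then lower charge. The built-in ligand table carries the
berberine cation (average 336.4 Da); other ligands are supplied by mass.

IRₐ sums assigned intensities per ligand stoichiometry b ∈ {0, 1, 2, 3},
pooling charge states and ammonium counts, and reports
complex/(free + complex), rounded to two decimals. An all-zero table is
flagged rather than divided.

## CD classification

Spectra are smoothed with a centered moving average (default 5 points,
deterministic, no fitted baselines) before extremum detection. The topology
call uses the global positive maximum: within ±6 nm of 264 nm → parallel;
of 295 nm → antiparallel; otherwise "other". The ±6 nm window is chosen so
canonical parallel spectra classify correctly while the 272 nm maximum of
the mutated non-quadruplex control does not fall in either window; the
band positions are field conventions, their tolerances are not, so the
window is configurable. Spectra with comparable positive maxima in both
windows (hybrid-like) are reported as "other" with both wavelengths as
evidence, since no hybrid rule is defined; spectra with no positive signal
are "other" with empty evidence, not an error.

## Melting thermodynamics

The model is an intramolecular two-state equilibrium: folded fraction θ,
K = θ/(1−θ) independent of strand concentration, ln K linear in 1/T with
slope −ΔH/R and intercept ΔS/R (R = 8.314 J mol⁻¹ K⁻¹), and Tm the
ln K = 0 crossing (Tm = ΔH/ΔS in kelvin). Signs follow the folding
direction (ΔH < 0); unfolding-direction values are kept in diagnostics.
Temperatures are kelvin internally, reported in °C; energies are reported
in kJ/mol at a stated reference temperature via ΔG = ΔH − TΔS.
Ligand-stabilization deltas are component-wise bound − free, with both ΔG
values evaluated at the same reference temperature before differencing.
The intramolecularity check passes when Tm is concentration-independent
within a tolerance (default 1 °C).

**Normalization.** Linear folded/unfolded baselines are fit in a
low-temperature and a high-temperature window (defaults: first 15% and
last 10% of the span) and θ = (signal − unfolded)/(folded − unfolded),
which is 1 at low temperature for either signal polarity. A two-state
transition with ΔH around −200 kJ/mol is broad enough that a few percent
of transition signal leaks into any practical window, which biases a
single-pass baseline fit (of order 1 °C in Tm and 10% in ΔH). The
baselines are therefore refined iteratively: the current θ is regressed as
ln K vs 1/T, the implied two-state θ is used to deconvolve transition
signal from the window points, and the four baseline coefficients are
re-solved by least squares. On noiseless two-state input the iteration's
fixed point is the exact generating θ. Because noise can make the
iteration wander, the iterate whose implied two-state model best
reconstructs the whole curve (lowest residual sum of squares) is kept;
`max_refine = 0` recovers the plain single-pass behavior. Degenerate input
(folded and unfolded baselines closer than 5% of the signal range, e.g. a
straight line) raises a no-transition error.

**Fitting.** Only points with θ in [0.15, 0.85] enter the regression —
outside that band ln K is baseline-dominated and numerically divergent —
and at least five in-band points are required. The regression Tm is the
reported one (a smoothed estimate on noisy curves); the raw θ = 0.5
interpolation is kept in diagnostics, as is a warning for non-monotone θ
inside the band.

## Synthetic data

Generators are pure functions of (parameters, seed) via numpy's seeded
`default_rng`; identical config gives bit-identical output, and every
generator returns a truth record of its parameters.

- **Melting**: θ(T) = K/(1+K) with ln K = −(ΔH/R)(1/T − 1/Tm);
  signal = unfolded(T) + [folded(T) − unfolded(T)]·θ with sloping linear
  baselines; optional Gaussian noise scaled to the transition amplitude.
  Presets mirror the three measured conditions — Tm 67.0 °C (100 mM KCl),
  77.0 °C (KCl + berberine 1:4), 37.0 °C (100 mM LiCl) — on 0.5 °C grids
  (20–95 °C for the KCl pair, 10–75 °C for LiCl so the lower transition is
  bracketed). The generator ΔH is fixed at −200 kJ/mol, a typical van't
  Hoff enthalpy for a sharp three-tetrad intramolecular transition; the
  much smaller ΔH magnitudes that appear in reported parameter tables for
  this system would imply transitions far broader than the published
  curves show and cannot generate a realistic sigmoid, so they are used
  only as arithmetic inputs to ΔG/ΔΔG checks, never as generator defaults.
- **MS**: Gaussian peak profiles (default FWHM 0.6 Th) at the theoretical
  m/z of each requested species, summed on an m/z grid, optionally
  degraded with Gaussian noise, then centroided back to a peak list
  normalized to % of base peak. Species closer than one FWHM trigger a
  merged-peak warning in the truth record.
- **CD**: sums of Gaussian bands on a 220–320 nm, 0.5 nm grid — parallel
  +264/−242 nm, antiparallel +295/−265 nm, and a mutant-control signature
  with a single +272 nm band.

What the generators do *not* emulate: instrument drift, shot noise,
isotopologue fine structure, overlapping charge-state envelopes, multi-state
or kinetically limited melting, and concentration-dependent (bimolecular)
folding. Passing recovery tests therefore demonstrates correctness of the
analysis pipeline under the stated statistical model, not robustness to
every artifact of real instrument data.

## Problem sizes

The test suite and the acceptance script run on the generator defaults:
131–151-point melting curves, 201-point CD spectra, three-peak MS spectra,
a 4 × 3 (Tm, ΔH) recovery grid, and 25 replicate seeds for the noisy-melt
study. Everything completes in seconds on one CPU.

## Known limitations

- The scanner reports maximal tract chains only; it does not enumerate
  alternative quadruplex decompositions, score propensity (G4Hunter-style),
  or handle RNA.
- Peak assignment assumes a single oligonucleotide species; no
  deconvolution of overlapping envelopes and no Kd estimation.
- The two-state van't Hoff analysis has no heat-capacity (ΔCp) correction
  and no multi-wavelength global fit.
- CD classification is a band-position rule; it does not deconvolve
  secondary structure or normalize to molar ellipticity.
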