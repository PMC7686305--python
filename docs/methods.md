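# Methods

`qrelax` simulates and analyses a quantitative prostate-MRI experiment: an
inversion-prepared FISP fingerprinting acquisition matched against a
simulated dictionary, the conventional gold-standard maps (IR-FSE T1, VFA
T1, MSE T2, DWI ADC), a gadolinium contrast model, and the ROI-level
statistics that ask whether contrast administration inflates T1 variation
enough to destroy lesion/normal-tissue discrimination in the transition
zone (TZ) of the prostate.

## Signal models

**Closed forms.** Inversion recovery
`S(TI) = PD·|1 − 2e^(−TI/T1) + e^(−TR/T1)|`; spoiled gradient echo
`S(α) = PD·sin α·(1 − E1)/(1 − E1·cos α)` with `E1 = e^(−TR/T1)`;
spin-echo decay `S(TE) = PD·e^(−TE/T2)`; diffusion decay
`S(b) = S0·e^(−b·ADC)`. Times are in ms throughout; ADC is carried in
10⁻³ mm²/s (the conventional prostate scale), so the diffusion exponent is
`b·ADC/1000`.

**Fingerprinting train.** The sequence is an unbalanced (FISP-type) SSFP
train with inversion preparation: 979 excitations, TR 10 ms, TE 2.5 ms,
8π intravoxel dephasing per TR, ideal instantaneous 180° inversion
followed by an 18 ms delay. Because the per-TR dephasing is a whole number
of 2π cycles, the voxel-averaged echo is exactly the F0 configuration
state, which the extended-phase-graph (EPG) engine computes in O(N·K) for
K retained configuration orders. The echo is sampled as F0 immediately
after the pulse, decayed by `e^(−TE/T2)`; relaxation is split into TE and
TR−TE segments; the gradient shift acts once per TR after the echo.

The flip-angle train is data, not code: a plain-text file (one angle per
line, `#` comments) bundled with the package and substitutable by the
user. The default is five half-sinusoid lobes (peaks 60/45/70/50/65°) on a
10° baseline with a fixed-seed 1° perturbation — a configurable stand-in
with the overall morphology of published fingerprinting lists, not a claim
to reproduce any specific scanner protocol.

**EPG numerical choices.** Default K = 40 retained orders. The truncation
error against K = 100 is < 10⁻⁶ for T2 ≲ 100 ms (4×10⁻⁸ at T2 = 69 ms) and
grows with T2/TR to ≈ 4×10⁻³ at T2 = 800 ms — still an order of magnitude
below the dictionary's T2 quantisation there; K is a keyword everywhere
for users who want more. With zero RF phase and zero off-resonance the
transverse states are purely imaginary, so the engine runs in real
arithmetic (≈4× faster); phase-cycled or off-resonant trains take the
complex path. Dictionary builds vectorise all (T1, T2) pairs through one
3×3 matrix product per excitation.

**Bloch oracle.** An independent isochromat simulator averages explicit
Bloch rotations over a uniform fan of spins spanning the per-TR dephasing.
When the dephasing is m full cycles (m = 4 here), a fan whose size shares
a factor with m aliases configuration order N/gcd(m, N) back into the
echo, so the fan size is rounded up to the next integer coprime with m
(200 → 201); the first aliased order is then the fan size itself. The EPG
and Bloch routes agree to < 0.4% relative RMS over the in vivo (T1, T2)
range at ≥ 200 isochromats, and to ~10⁻⁴ where T2 is short.

## Dictionary matching

The dictionary is the matrix of L2-normalised EPG fingerprints over a
(T1, T2) grid, excluding pairs with T2 > T1. The default grid spans
T1 ∈ 100:10:2000 ∪ 2020:20:3500 ms and T2 ∈ 10:2:100 ∪ 105:5:300 ∪
310:10:800 ms — finer where prostate tissues cluster. Matching maximises
|⟨series, atom⟩| (complex inner product; plain dot product for
magnitude-only data, recorded in the dictionary metadata). The winning
grid pair is returned unmodified (snap-to-grid, standard fingerprinting
practice), so the grid step bounds precision and is reported; proton
density is the projection divided by the winning atom's pre-normalisation
norm, and the match score |⟨s, â⟩|/‖s‖ ∈ [0, 1]. Argmax ties break toward
the lexicographically smallest (T1, T2) by construction of the pair
ordering. Cohort runs use a coarser grid (T1 step 20 ms, T2 step 10–20 ms)
because biological spread, not grid step, dominates there.

## Conventional fitting

All fitters are bounded trust-region nonlinear least squares
(T1 ∈ [10, 10⁴] ms, T2 ∈ [1, 3×10³] ms, ADC ∈ [0.01, 4]×10⁻³ mm²/s;
cost tolerance 10⁻¹⁰) initialised from deterministic closed-form
linearisations — no random restarts:

- **IR:** magnitude data lose the recovery sign; every candidate null
  position is tried (signs flipped before it), each fitted with the signed
  three-term model, lowest SSE wins. The `+e^(−TR/T1)` term is kept even
  when TR ≫ T1 so the same code serves short-TR protocols.
- **VFA:** DESPOT1 line `S/sin α = E1·(S/tan α) + c`; a slope outside
  (0, 1) is reported as non-convergence, never an exception.
- **MSE:** log-linear initialiser on all echoes including the first
  (stimulated-echo correction is out of scope and a known bias source on
  real multi-echo trains); estimates beyond 4× the longest TE carry an
  extrapolation flag.
- **ADC:** log-linear least squares over b-values.

Estimates are invariant to global signal scaling (the scale parameter
absorbs it); non-convergence sets a flag and NaN, and `fit_volume`
surfaces convergence as a companion quality map.

## Synthetic data

The generators are pure functions of (spec, seed); per-patient and
per-stage streams derive from the global seed by a splitmix-style hash so
partial re-runs reproduce full-run values.

**Phantom.** Spheres on a lattice with log-spaced T1 (100–3000 ms; a T2
layer variant spans 10–700 ms), uniform within each sphere, one mask per
sphere. Schematic: it emulates the layered calibration-phantom geometry
only as far as ROI statistics need.

**Virtual pelvis.** One labelled 48×48 slice per patient: fat and muscle
bands, an ellipsoidal prostate with inner TZ, annular peripheral zone
(PZ), and ellipsoidal lesions; 14 patients carrying 10 PZ and 9 TZ lesions
by default. ROI-level parameter means are drawn from per-class
distributions whose pre-contrast defaults equal the bundled cohort summary
table; voxels jitter at 5% CV so across-ROI variance is dominated by
between-ROI biology, matching how the reference cohort's CVs were computed
(across ROI means). T1 draws are normal (floored at 50 ms); T2 and ADC
draws are log-normal moment-matched to the published mean/SD, because
cells like fat ADC 0.08 ± 0.07 make any clipped normal bias the mean far
beyond the generator's own 5% moment tolerance.

Two deliberate dependence structures reproduce the cohort's paired-test
behaviour, which pooled marginals alone cannot (the pooled TZ lesion and
normal-TZ means differ by only 57 ms, yet the matched-pair contrast in the
reference cohort is clearly significant, because lesion-bearing patients
had systematically longer normal-TZ T1):

- normal-TZ ROI means are a two-component mixture conditioned on whether
  the patient hosts a TZ lesion — hosts come from the published
  patient-matched subset distribution, non-hosts from the complementary
  component solved so the pooled mixture reproduces the pooled
  mean ± SD exactly (components are expressed in standardised units, so
  zero-SD specs collapse to the class mean);
- each lesion's T1 correlates at ρ = 0.8 with its host patient's
  normal-tissue T1 (shared patient-level physiology: perfusion, age, BPH),
  with both marginals preserved exactly.

**Contrast model.** `1/T1_post = 1/T1_pre + r1·C` and likewise for T2 with
r2; defaults r1 = 5.0, r2 = 6.0 L·mmol⁻¹·s⁻¹ (gadobutrol-like order of
magnitude at 3 T — configuration, not a claim). Each ROI draws one
concentration from its class's log-normal uptake distribution, with 5%
per-voxel jitter; a per-voxel i.i.d. draw would average out inside the ROI
and could not inflate across-ROI CVs. The per-class uptake (mean, CV)
defaults were calibrated by `scripts/calibrate_uptake.py`: delta-method
seed values from the relaxivity equation, then iterative refinement
against the median of many seeded cohort simulations, because the sample
CV over 9–14 ROIs of a heavy-tailed distribution is biased well below the
population CV. With the frozen defaults the median simulated cohort
reproduces the published post-contrast means (within ±15%) and the CV
pattern — TZ-lesion CV inflation ≈ 4.4-fold, normal-TZ ≈ 2-fold, normal-PZ
and muscle stable — and the full headline pattern (all tissues shortened;
TZ CV ratio ≥ 3; pre-contrast lesion/normal contrasts significant in both
zones with the post-contrast TZ contrast lost) appears in roughly three
quarters of cohort seeds. Post-contrast targets are pattern-level, not
value-level: no quantitative uptake data exist to calibrate against.

**Acquisition noise.** Forward models applied voxelwise; complex Gaussian
noise with σ = (mean foreground |signal|)/SNR, magnitude detection giving
Rician statistics (zero-signal voxels average σ√(π/2)). Fingerprinting
data are kept complex for matching. Undersampling/aliasing of a real
spiral acquisition is folded into this noise level rather than modelled;
defaults are SNR 100 for the phantom study and SNR 50 for the cohort.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: k-space undersampling structure, motion,
B1+ non-uniformity, slice profiles, partial-volume mixing at ROI borders,
magnetisation transfer, multi-compartment relaxation, and DCE enhancement
kinetics. ROI statistics, not images, are the product.

## Statistics

Per-ROI means are the unit of analysis. CV = 100·SD/mean with sample SD
(n−1) everywhere; CV < 25% (strictly) is flagged acceptable. Bland–Altman
limits of agreement use the fixed 1.96 normal-theory multiplier (no
small-sample t correction, matching the convention of 95% LOA figure
captions). Regression is ordinary least squares with R² the squared
Pearson correlation. Group contrasts: Shapiro–Wilk normality recorded per
group (on differences for paired data); paired/unpaired t-tests reported
regardless, with a non-normality flag rather than a switch to
nonparametrics; planned lesion-vs-normal paired comparisons unadjusted,
all other contrasts Holm–Šidák adjusted as one family at α = 0.05. ROIs
with failed fits are excluded pairwise for agreement analyses and listwise
for paired tests.

The bundled published summary table doubles as a "table replay": feeding
its means/SDs through `compute_cv` reproduces the published CV table to
±0.1 for the fingerprinting T1/T2 and conventional VFA/MSE columns. Two
published cells are arithmetically inconsistent with their own summary
row (all-lesion MSE T2: 27.8/76.6 = 36.3 vs printed 24.0; fat ADC:
0.07/0.08 = 87.5 vs printed 8.0) and are excluded and flagged; the
remaining ADC cells are printed to only 2 decimals, so their CVs are not
held to ±0.1. The published pooled and patient-matched normal-tissue
values differ (pooled vs lesion-host subsets); both variants are bundled
and labelled.

## Pipelines and problem sizes

The phantom pipeline (64×64 grid, 14 spheres, SNR 100, T1-fine dictionary
restricted to the phantom range) and the cohort pipeline (14 patients,
48×48 slices, SNR 50, coarse cohort dictionary, acquisition and matching
restricted to labelled voxels) are sized so a full run of either takes
tens of seconds on one CPU; grids, SNR and cohort size are configuration.
Outputs are deterministic per seed; each directory carries a manifest
(config, seed, version, config hash) and per-stage CSV intermediates from
which a matching re-run resumes. Coordinates are voxel-index space with
the affine carried through; nothing is resampled — real-data users must
supply co-registered inputs.

## Known limitations

- The fingerprinting T2 axis inherits the reference experiment's weakness:
  with TE 2.5 ms and this train, long T2 values are poorly encoded, and
  the published in vivo T2 summary values exceed T1-range plausibility for
  several tissues; the package reproduces the pattern without endorsing
  the values.
- No B1+ correction: VFA bias under flip-angle miscalibration is not
  modelled (only VFA's noise sensitivity is, which the simulation
  comparison against IR documents).
- The host/non-host normal-TZ mixture models a *selection* effect of the
  small reference cohort; it is the package's design choice for
  reproducing the paired-contrast pattern, not an estimate of population
  biology.
- The published PZ pooled and patient-matched values are mutually
  inconsistent as an exact mixture (the implied non-host variance is
  negative), so no analogous PZ mixture is attempted.
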