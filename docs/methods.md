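# Methods

This note records the models behind `alpskit`, the defaults that matter,
and what the synthetic data can and cannot show.

## DWI phantom

Each labelled voxel holds a two-compartment mixture:

* a **fiber compartment** (weight `1 − f`): cylindrically symmetric tensor
  with eigenvalues `λ∥ = 1.7e-3`, `λ⊥ = 0.3e-3` mm²/s along the region's
  fiber axis — projection regions along z, association regions along y,
  all three corpus-callosum regions along x;
* a **perivascular compartment** (weight `f`): cylindrical tensor with
  `λ∥ = 3.0e-3`, `λ⊥ = 0.3e-3` mm²/s along the region's vessel axis —
  x in the ALPS regions, y in the genu and splenium, z in the callosal body.

The noiseless signal is the analytic mixture
`S = S0 · Σᵢ fᵢ exp(−b gᵀ Dᵢ g)`; mixing a fast perivascular compartment
into a voxel is the mechanism by which perivascular diffusivity elevates
the *fitted single tensor* along the vessel axis, which is exactly the
effect the ALPS ratios measure.

Defaults: a 20³ grid of 2 mm voxels with one 8-voxel cube per region
(two per hemisphere for the ALPS regions; positions are arbitrary since no
registration is modelled); `f = 0.1` in the ALPS regions and `f = 0.04` in
the corpus callosum. The callosal fraction is deliberately smaller: the
variant indices are meant to land slightly above 1 (noiseless ≈ 1.13)
while the ALPS index sits near 1.4, mirroring the observation that the
callosal effect is smaller than the ALPS-region effect. With a uniform
`f = 0.1` the variant indices would be as large as ALPS itself (≈ 1.47),
which would defeat the comparison the variants exist for. Background
voxels are isotropic at `0.8e-3` mm²/s.

**Gradient scheme.** A fixed 12-axis table obtained by minimising the
antipodally symmetric electrostatic energy on the sphere, plus two b = 0
volumes (averaged before fitting, mirroring a two-average acquisition),
single shell at b = 1000 s/mm². Twelve-axis clinical tables are vendor
specific, so the packaged table is an explicit stand-in; the loader
validates unit norms and full design-matrix rank.

**Noise.** Rician: the magnitude of the complex signal after adding two
independent Gaussian channels with `σ = S0 / SNR`; default SNR 20 at b = 0,
the standard magnitude-MRI model. Noiseless simulation (`snr = inf`)
returns the analytic mixture exactly.

**Head motion.** A Gaussian random walk over the 6 rigid parameters.
Step SDs (0.0376 mm translations, 7.52e-4 rad rotations) are calibrated so
Power-style framewise displacement, `FD_t = Σ|Δtrans| + r·Σ|Δrot|` with
r = 50 mm, has expectation ≈ 0.18 mm per frame, split evenly between
translations and rotations. The cohort-level generator multiplies each
subject's step SDs by a unit-mean log-normal scale (log-SD 0.3754) so the
across-subject SD of per-subject mean FD is ≈ 0.07 mm — motion varies far
more between patients than within a scan.

## Tensor fitting

Ordinary log-linear least squares per voxel:
`−ln(S/S0) = B d` with `B` built from outer products of the directions and
`d` the six unique tensor components; `S0` is the mean of the b = 0
volumes. The estimator is deterministic and exact on noiseless
single-compartment data, which is what the recovery tests exploit; a
signal-weighted variant (weights S²) is available behind a flag but off by
default. Non-positive signals are clamped to `1e-6·S0` and the voxel
flagged. FA is computed on eigenvalues clamped at zero (so FA ∈ [0, 1]);
the raw axis diffusivities Dxx/Dyy/Dzz are reported *unclamped* because
they feed the ALPS ratios directly.

## Index computation

Left and right hemisphere ROIs of the same class are pooled into a single
regional mean before the ratio (the pooling rule is configurable in
spirit: per-hemisphere means are recoverable from the label map, but the
packaged aggregation pools, which is the simplest reading of a single
reported index). Session change Δ is 9 AM minus 4 PM throughout.
Median/IQR reporting uses linear-interpolation quantiles.

## Synthetic cohort

The tabular generator is a Gaussian copula with a subject/session factor
structure. Per subject, a latent vector `U ~ N(0, R)` spans all variables;
each session's scan-level latent is
`Z_s = √ρ·U_scan + √(1−ρ)·E_s`, `E_s ~ N(0, R_scan)` i.i.d. across
sessions. Consequences: same-session cross-variable correlations equal the
planted `R`; each scan variable's within-subject 4 PM/9 AM correlation is
`ρ` (default 0.7 — chosen because, with the session SDs 0.261/0.253,
`Var(Δ) = σ₄² + σ₉² − 2ρσ₄σ₉` then reproduces the target ΔALPS SD of
0.199); subject-level variables (age, PSG metrics) are shared by both
scans, with their planted scan-level correlations divided by `√ρ` on the
latent scale so the pooled-scan correlation matches the planted value.

**PSD repair.** The planted matrix (calibration block of imaging–imaging
and imaging–sleep correlations; all unlisted pairs 0) need not be positive
semi-definite after the cross-level inflation. Repair is by alternating
projections between the PSD cone and the affine set fixing the unit
diagonal *and the planted entries*, so the free (default-zero) entries
absorb the adjustment; generation aborts, naming the offending pairs, if
the planted entries themselves must move by more than 0.05.

**In-sample planting.** Factor sampling realises `R` only in expectation,
and within-subject clustering inflates the sampling noise of pooled-scan
correlations well beyond the nominal n (effective n ≈ 59 for 100 scans at
ρ = 0.7). Because the generator's purpose is a calibrated test-bed, the
pooled scan-level latent scores are recolored (Cholesky whitening of the
empirical covariance followed by recoloring to the repaired target) so
their empirical correlation matrix equals the planted one exactly; the
map is applied to both sessions identically, which preserves the session
structure up to small perturbations (realised ρ ≈ 0.69, ΔALPS SD ≈ 0.20).
The step requires more scans than scan-level variables and is skipped —
with provenance unchanged — for smaller tables; it can be disabled via
`match_sample_corr=False`.

**Marginals.** Plain Gaussian for unbounded variables, truncated Gaussian
for bounded ones (sleep efficiency and stage percentages in [0, 100],
rates and volumes ≥ 0). Bounds sit ≥ 1.3 SD from the mean wherever
possible so truncation distorts the targeted moments by well under the
testing tolerance. ALPS has session-specific means/SDs (1.391 ± 0.261 at
4 PM, 1.419 ± 0.253 at 9 AM), giving the overnight shift of 0.028 by
construction. PSG marginal targets are plausible sleep-clinic values for
an OSA population — configuration, not estimates. Volumes satisfy
`rCPV = CPV/TIV` and `rWMHV = WMHV/TIV` identically, with TIV drawn
independently per subject (1.45e6 ± 1.2e5 mm³). Diagnosis groups are
mutually exclusive with fixed counts (14 bipolar, 14 depression,
7 schizophrenia, 6 ADHD, 1 OCD, 8 none at n = 50; largest-remainder
scaling otherwise); 9 subjects carry the CPAP-pretreatment flag and 33
are male.

**Voxel-backed mode.** Each scan's phantom perivascular fractions are set
by inverting a noiseless fraction→index calibration curve at the scan's
tabular targets, then the phantom is simulated at the configured SNR and
re-fitted. Simulation noise and the nonlinear fraction→index map mean the
planted covariance is inherited only approximately (and index targets
below 1 clamp to `f = 0`); the tabular route is the statistical reference
surface, the voxel route the imaging one. The mode is recorded in the
table's provenance.

## Statistics

* Correlation grids: pairwise complete-case Pearson r with two-tailed p;
  BH-FDR within each declared family — one family per heatmap panel
  (a session's full imaging × sleep grid), since per-analysis correction
  without a defined family is the natural reading; the family scope is an
  argument. Strength categories: |r| < 0.20 very weak, < 0.40 weak,
  < 0.60 moderate, < 0.80 strong, else very strong.
* Standardized regression: continuous variables z-scored, 0/1 dummies
  left as-is; OLS with normal-approximation 95% CIs by default (t-based
  behind a flag); VIF per predictor; perfect collinearity detected up
  front and reported with the offending pair.
* Mediation: two nested least-squares fits (`M ~ X + cov`,
  `Y ~ X + M + cov`); ACME = a·b, ADE = c′, total = a·b + c′ — an exact
  identity of the point estimates. Percentile 95% CIs over case
  resamples (default 1000); degenerate resamples are redrawn and counted,
  with an error beyond 10%. Proportion mediated is ACME/total, reported
  as NaN when |total| < 1e-12. BCa intervals are not implemented;
  percentile is the default reading of "nonparametric bootstrap". The
  ten-model battery runs a fixed path list (association- and
  projection-internal mediators first, then the three callosal-body
  mediators for each of assocDxx and projDxx), age-adjusted, one shared
  seed. Raw-unit coefficients are the default; z-scored effects are
  available via `standardize=True`, and no attempt is made to chase any
  particular coefficient magnitude, which depends entirely on the units
  of the diffusivity inputs (~1e-3 mm²/s against a unitless ratio
  outcome).
* The FD–ALPS motion check is a single pre-specified test outside any
  FDR family, reported with a Fisher-z CI.
* Sensitivity subsets: `no_psych` keeps subjects with all diagnosis
  dummies zero (8 subjects, 16 scans at the default split); `no_cpap`
  drops the 9 flagged subjects. The joint-entry regression (all four
  indices in one model) is the default for the forest plots; per-predictor
  models can be run by passing a single predictor.

## Pipeline and reproducibility

One global seed fans out through fixed `SeedSequence` spawn keys to the
cohort, imaging and stats stages, so stages can be re-run in isolation;
identical config + seed yields byte-identical `summary.json` (timings are
logged but excluded from the reproducible surface). Any stage failure
aborts with the stage name. Analyses that a deliberately tiny cohort
cannot support (e.g. the ten-coefficient regression on a 2-subject
voxel-mode smoke run) are recorded as skipped in the summary instead of
failing the run.

## Problem sizes and limitations

The packaged defaults — 50 subjects × 2 sessions, a 20³ phantom grid with
8-voxel ROIs, 50 noisy phantom replicates, 1000 bootstrap draws — are the
calibration conditions of the generator and keep any single analysis in
the seconds-to-a-minute range.

What passing tests show is internal consistency: the estimators recover
what the simulators plant, under the geometry and noise model stated
above. They do not show anything about real acquisitions: there is no EPI
distortion, eddy-current artefact, partial-volume CSF contamination,
registration error, or template-ROI misplacement; fiber orientations are
exactly axis-aligned; the perivascular compartment is a simple fast
cylinder rather than a flow model; PSG metrics are copula draws, not
physiology; and the planted correlation structure realises printed
summary statistics rather than any underlying biology. Conclusions about
the behaviour of the indices on clinical data require clinical data.
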