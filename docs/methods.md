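# Methods

This note documents the models, conventions and design choices behind
`actibrain`, in the spirit of the methods documentation of statistical
simulation packages: what is computed, under what assumptions, which knobs
matter, and what the synthetic experiments do and do not establish.

## Synthetic data model

**Activity.** Each subject carries latent unitless traits
`t ~ N(0, I)` (defaults: 3 traits). A day of activity is 1,440 one-minute
epochs. The expected count profile is a raised cosine peaking at 14:00 and
clamped at zero, which is positive roughly 08:00–20:00 and zero at night —
the simplest shape producing a realistic day/night contrast for a device
removed at bedtime. The baseline amplitude is 2,000 counts/min (an
ActiGraph-like daytime scale); trait 0 scales it multiplicatively by
`exp(0.4·t₀)`, so daytime mean count increases monotonically with trait 0.
Trait 1 adds ultradian modulation (3 cycles/day, ±30 % per trait SD,
clipped at zero) and trait 2 perturbs the day-to-day level. Counts are the
profile times Gamma(shape 3, mean 1) multiplicative noise — non-negative and
right-skewed, as device counts are; no distribution is prescribed by the
procedure being modelled, so this is a package choice. With probability
`missing_run_prob` per day, one contiguous daytime missing run of uniform
length 5–120 min is inserted (NaN counts, True mask). Runs are placed only in
daytime so the >30-min exclusion rule is actually exercised; night
missingness is treated as non-wear by design. Missingness is always explicit
in the mask — zeros are valid data. Triaxial mode splits each magnitude
across three axes with random positive weights whose squares sum to one, so
the vector-magnitude collapse recovers the uniaxial series exactly.

**Volumes.** Regional volume = intercept + traits·B + covariates·Γ + ε,
ε ~ N(0, σ²) per region. Covariates resemble an elderly memory-clinic
cohort: age ~ N(74.07, 7.05) years, education ~ N(9.14, 4.56) years
(clipped at 0), sex ~ Bernoulli(0.316) for male coded 1 (a 0/1 numeric
nuisance covariate), TIV ~ N(1450, 130) mL. Default trait coefficients are
N(0, 2²) in volume units per trait SD against noise SD 1, giving a signal-
dominated but not degenerate linear problem. The generating parameters are
stored (sidecar JSON) so the regression layer can be tested for parameter
recovery. The true generative link between activity and regional volume is
unknown; the linear-trait model is an assumption made for testability, not a
scientific claim.

## Preprocessing conventions

- Daytime is the half-open window [09:00, 21:00) — exactly 720 minutes;
  nighttime [21:00, 09:00) is discarded before anything else sees the data.
- A day is excluded iff its longest *daytime* missing run exceeds 30
  consecutive minutes (strict inequality: a 30-min gap is retained).
  Exclusion is a logged, normal outcome. Night content never affects it.
- Surviving gaps (≤ 30 min) are linearly interpolated; edge gaps extend the
  nearest observed value. The autoencoder requires dense input.
- Standardization uses one mean/SD per dataset, computed over non-missing
  daytime values with the sample (n−1) SD convention, applied to all of that
  dataset's records. Normalizing from daytime values only is a deliberate
  choice: statistics over epochs that are then discarded would shift the
  standardized scale without benefit. Constant input (SD 0) is a data error.

## Autoencoder

Encoder: three 1-D conv blocks, channels (8, 16, 32), kernel 7, strides
(3, 2, 2), ReLU, mapping 720 → 240 → 120 → 60 time steps; paddings (and the
decoder's output paddings) are derived automatically from the geometry.
Decoder mirrors with transposed convolutions and a linear output layer. This
is the minimal structure consistent with a 60-step convolutional latent;
channels, kernel and strides are configurable so alternatives are drop-in,
under the invariant `prod(strides) × latent_length = input_length`.

Training: Adam (lr 1e-3, batch 64, default 100 epochs), seeded batch
shuffling, subject-level 8:1:1 train/validation/test split (subject-level to
prevent a subject's days leaking across splits; counts are
round(0.1·n) for validation and test, remainder train). The reported loss is
reconstruction RMSE; the update direction is the MSE gradient — RMSE is a
monotone transform of MSE so the minimizers coincide, and Adam's
normalization makes the raw gradient scale immaterial. The best-validation
checkpoint is restored at the end of training. Layers are float64 numpy
(im2col convolutions with exact adjoint transposed convolutions); analytic
gradients are verified against central finite differences in the test suite,
and training at test scale (hundreds of segments) runs in seconds per epoch
on one CPU.

Features: per day, encode to the C×60 latent and take the unweighted
arithmetic mean over channels (60 values); per subject, average over retained
days. Hence exactly 60 features per subject for any channel configuration,
invariant to day order. Subjects with zero retained days are skipped and
reported.

## Time-frequency features

STFT of a 720-sample segment with a symmetric Hamming window of 60 samples
(60 min), 50 % overlap (hop 30), zero-padded to a 256-point transform — the
classical default behaviour for a 60-sample analysis window; at 1 sample/min
the sampling rate is 1/60 Hz (0.0167). This yields 23 frames and a one-sided
129-bin magnitude spectrogram, `|rfft(window·frame, 256)|` with **no
scaling** (matching the unscaled STFT output of classical spectrogram
routines, and making the brute-force windowed-DFT oracle exact). Magnitudes
(moduli, not powers) are averaged over frames; the DC bin is dropped to
obtain 128 frequency indices — a 60-point window cannot produce 128 indices
without zero padding, and 256-point padding with DC dropped is the minimal
consistent reading; the Nyquist-drop alternative is selectable. The 128
values are averaged within 64 consecutive pairs; subject vectors are day
averages. A rectangular window is selectable (`window_shape="rectangular"`)
because "short-time squared window" descriptions of this analysis are
ambiguous between a rectangular window and squared-magnitude spectra; the
Hamming reading is the default.

Two leakage caveats are documented rather than hidden: a constant segment
concentrates energy at DC but the window mainlobe (±2/60 cycles/min ≈ 8.5
bins of 256) leaks into neighbouring low bins, so "all energy in DC" holds
only up to sidelobe level (<1 % beyond the mainlobe); and after DC-dropping,
adding a constant to a segment still perturbs low-frequency features through
that same leakage.

## Atlas and residualization

The packaged table lists the 116 AAL regions (checksum-verified): 90
cerebral with lobe labels (central 8, frontal 24, insula 2, limbic 14,
occipital 14, parietal 10, subcortical 10, temporal 8 — the grouping that
places the temporal poles with the limbic lobe, the fusiform gyri with the
occipital lobe and the amygdalae with the subcortical nuclei), 18 cerebellar
hemisphere regions, and 8 midline vermis regions. Vermis regions are
modelled at the region level but excluded from lobe summaries — the only
reading that reconciles "116 regions" with a 108-region lobe tabulation.

Residualization regresses each region on [1, age, sex, TIV, education] by
OLS and keeps the residuals; columns are exactly orthogonal to the
covariates and mean-zero, and the operation is idempotent. Volumes stay in
native units: r and R² are scale-invariant. Rank-deficient covariate
matrices are rejected with the collinear columns named.

## Regional models

`fit_ols` solves least squares by QR with standard t and F inference (it
matches `statsmodels.OLS` to ~1e-10 in the tests, including at 7 residual
degrees of freedom). Backward elimination refits and removes the single
feature with the largest p ≥ α, breaking ties toward the latest column, until
all retained p < α or none remain; exact collinearity among candidates is
resolved by dropping the latest dependent column. When the candidate set is
too large for the sample (K ≥ n−1), it is pre-screened to the n−10 features
with largest |marginal correlation| (with a warning) so small synthetic runs
remain defined; at the analysis-scale corner (n = 132, K = 124, 7 residual
df) the saturated start is allowed.

The overall p entering FDR control is the F-test p of the final
post-elimination model. BH-FDR is the standard step-up (flags monotone in p;
adjusted p by reverse cumulative minimum), cross-checked against both a
brute-force implementation and statsmodels. Regions retaining no features or
failing FDR are flagged excluded with a reason. In-sample r is the Pearson
correlation between fitted and observed values *on the fitting data* and is
labelled as such; for OLS with intercept r² equals R² to 1e-10, which the
suite asserts.

Lobe summaries report mean and sample SD of r and R² over non-excluded
regions per lobe. Feature-set comparison uses t-tests paired by region
(the same regions are modelled under both candidate sets) per lobe and
metric, Bonferroni-corrected by the 9 summary lobes; zero-variance
differences return p = 1 with a warning. The long-format violin export
(108 regions × 2 feature sets) reproduces the lobe means exactly.

**The overfitting mechanism, quantified.** With n = 132 subjects and 124
candidate features, elimination at α = 0.05 applied to pure noise retains
~31 features per region and yields a median in-sample r of roughly 0.6–0.7
(seeds 100–102: 0.71 / 0.61 / 0.70) — against ~0.09 for a single pre-chosen
null regressor. This is why near-unity in-sample correlations at such
feature-to-subject ratios cannot be read as predictive accuracy; the package
reproduces the in-sample protocol faithfully and surfaces the null level in
its acceptance report rather than adding a cross-validation stage that the
protocol does not contain.

## Pipeline and problem sizes

The pipeline mirrors the two-corpus design: the autoencoder trains on a
reference corpus, features are extracted from an analysis corpus with
volumes. All randomness funnels through named per-stage seeds derived from
one master seed; identical config ⇒ byte-identical CSVs (fixed float
formatting). The manifest records per-stage counts, the config hash and the
package version, and marks the failing stage on error.

Default problem sizes are chosen so the complete test suite runs in a few
minutes on one CPU: the acceptance experiments use 500 training segments ×
50 epochs for the autoencoder sanity check, n = 1,000 subjects × 20
replicates for recovery of a planted 5-feature subset, and 116 null regions
× several replicates at n = 132 / K = 124 for the overfitting
quantification. The end-to-end cohort run in `scripts/acceptance.py` uses 60
reference + 132 analysis subjects × 7 days with a 10-epoch autoencoder —
enough to show the qualitative ordering (combined features beat
time-frequency-only, e.g. mean in-sample r ≈ 0.94 vs ≈ 0.70 at volume noise
SD 0.5) without hour-scale training.

The parameter-recovery experiment draws its 64 candidate columns iid
standard normal and plants 5 true ones. Feature tables computed from the
circadian simulator are intentionally *not* used there: all 64 spectral
features of a smooth circadian profile are driven by a few latent traits and
are therefore nearly collinear, which makes exact support recovery ill-posed
for any method; the iid design tests the elimination machinery itself under
an identifiable truth.

## Known limitations

- The synthetic circadian model has no weekday/weekend structure, naps,
  sleep-phase variation between subjects, or device-specific count
  calibration; passing tests show the pipeline's statistical machinery is
  correct, not that real cohorts would yield similar fit levels.
- The activity→volume link is linear in latent traits by construction; real
  associations need not be linear or trait-mediated.
- No out-of-sample validation is implemented, matching the in-sample
  protocol; the null-overfitting experiment is the package's substitute for
  an honesty check.
- The autoencoder is a small CPU model; at population scale (tens of
  thousands of subject-days) a framework implementation would be preferable,
  though the architecture and training contract would be unchanged.
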