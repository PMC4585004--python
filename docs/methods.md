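# Methods

## Problem and model

`avloc` analyses open-loop egocentric localization of visual (V), auditory
(A), and spatially/temporally congruent bimodal (VA) targets on a 2D
frontal-field grid (azimuth positive rightward, elevation positive upward,
fixation at the origin; angular coordinates treated as planar Euclidean
degrees throughout, as is standard for fields of this extent).

Repeated responses to one target by one subject are modelled as draws from
a bivariate normal with mean **μ** and covariance **Σ**.  Precision is the
*variable error* VE = √(σ²ₓ + σ²ᵧ) (degrees); accuracy is the *constant
error* CE = ‖μ − target‖.  Dispersion geometry is summarised by the 95%
coverage ellipse: semi-axes a, b = √(λᵢ·q) with λᵢ the covariance
eigenvalues and q = χ²₂(0.95) ≈ 5.991, axial orientation θₐ ∈ [0°, 180°) of
the leading eigenvector, and anisotropy ratio ε = b/a (1 = no preferred
direction).  An alternative printed form 1 − (b/a)² exists in the
literature; it inverts the stated reading (values near 1 should mean
isotropy) and is exposed only as `anisotropy_printed`.

### MLE cue fusion

For independent Gaussian cues and a flat prior over stimulus position, the
maximum-likelihood bimodal estimate is the reliability-weighted average:

    σ²_VA = σ²_V σ²_A / (σ²_V + σ²_A)             (≤ min of the two)
    W_V   = (1/σ²_V) / (1/σ²_V + 1/σ²_A),  W_A = 1 − W_V
    r̂_VA  = W_V r̂_V + W_A r̂_A

and in 2D the precision-weighted product of Gaussians:

    Σ_VA = (Σ_V⁻¹ + Σ_A⁻¹)⁻¹,
    μ_VA = Σ_VA (Σ_V⁻¹ μ_V + Σ_A⁻¹ μ_A).

This is the unique MLE for the product of the two bivariate likelihoods;
`grid_product_oracle` verifies the algebra by numerically normalising the
pointwise density product on a grid (moments agree to 1e−4 relative at a
0.05° step).  Per-axis Eq.-style weights are computed from the marginal
variances (ignoring ρ); the full-matrix fusion is used for the predicted
field.  A singular covariance is inverted after adding 1e−8 × trace to the
diagonal and the result is flagged.  The per-target *scalar* visual weight
reported by the pipeline is the mean of the two axis weights, which equals
tr(Σ_VA Σ_V⁻¹)/2 for axis-aligned covariances.

### Integration metrics

Redundancy gain is a relative dispersion reduction,
RG = 100·(VE_best − VE_VA)/VE_best, with "best unimodal" fixed to vision by
default (a per-target argmin option exists).  The variance-ratio form
100·σ²_VA/σ²_V is exposed as `redundancy_gain_printed`; it is a residual
percentage, not a gain, and is inconsistent with gain-scale values (~18%
gain corresponds to a ~67% residual ratio).  Inverse effectiveness is the
Pearson correlation of per-target RG with the best-unimodal dispersion (or
its square).  Hierarchical regressions (method Enter) are nested OLS fits
via statsmodels with per-step R², adjusted R², R² change and its F/p, plus
VIF per predictor in the full model.  Observed-vs-predicted fields are
compared with a paired t statistic and an across-target Pearson
correlation.  Repeated-measures ANOVA machinery is deliberately out of
scope; paired comparisons and correlations carry the comparison stage.

## Outlier rule

Within each (subject, modality, target) cell, a response is removed when
|x − mean| > k·SD or |y − mean| > k·SD (k = 3), single pass, with the mean
and SD from the unfiltered cell.  The per-axis form matches the "± k SD"
phrasing; a Mahalanobis variant would need a different calibration and is
not implemented.  A structural caveat documented here because it is easy
to miss: for a cell of n samples, max |x − mean|/SD = (n−1)/√n, which is
2.85 at n = 10 — at the standard 10-repetition cell size the rule cannot
remove anything, whatever the data.  It only bites for larger cells
(tests exercise it at n = 10⁵, where the removal fraction of clean
Gaussian data is 1 − (2Φ(3) − 1)² ≈ 0.54%).  Cells with fewer than 3
repetitions are passed through and flagged.

## Synthetic-data generator

The generator emulates the statistical structure of a 2D pointing study:
a 7 × 5 target grid at 10° spacing (±30° azimuth, ±20° elevation), 10
subjects, 10 repetitions per modality × target (1050 trials per subject),
bivariate-normal scatter and modality-specific constant-error fields.

Bias field: mean response = (g_r·az, h + g_e·(el − h)) with
hemifield-specific radial gain g_r (chosen by the sign of target
elevation; averaged on the horizontal meridian) and elevation gain g_e
about a horizon offset h (chosen by the side of the horizon).  This is the
simplest field that reproduces proportional undershoot, hemifield
asymmetry, and a best-accuracy locus off the geometric horizon.

Calibrated defaults (chosen once, in closed form, against the reported
field summaries; `avloc.default_profiles()`):

| parameter | A | V | rationale |
|---|---|---|---|
| orientation | vertical | radial | upright auditory ellipses everywhere; visual ellipses aligned with target direction |
| major-axis SD (centre) | 5.408° | 1.225° | mean VE on the 25-target grid 5.73° / 1.78° |
| axis ratio ε | 0.35 | 0.5 | reported anisotropy ranges |
| azimuth slope | 0 | 0.025/deg | visual VE grows with \|azimuth\| only; horizontal/vertical-meridian VE ratio ≈ 1.37 |
| radial gain (up/low) | 1.0 / 1.0 | 0.86 / 0.93 | auditory azimuth accurate; visual undershoot ~11% of eccentricity, stronger above |
| elevation gain (up/low) | 0.65 / 0.75 | 0.86 / 0.93 | auditory elevation compression toward a raised horizon, stronger below (lower-field CE ≈ 3× upper) |
| horizon offset h | +10° | 0° | best auditory accuracy ~10° above the geometric horizon |
| lapse rate / scale | 0.002 / 1.4° | 0.002 / 1.4° | see below |

The bimodal condition defaults to `mle_exact`: its generating distribution
is the exact fusion of the two unimodal ground truths, so the dataset
embodies optimal integration by construction (the implied bimodal VE is
~1.54°, gain ~12% over vision).  An `independent_profile` mode draws VA
from its own profile instead.

Lapses are drawn as cell mean + amplitude·(cos φ, sin φ) with φ uniform
and amplitude ~ U[4, 8] × 1.4° (5.6–11.2°).  The rate is kept at 0.2% so
that the contamination the 10-repetition cells cannot shed (see the
outlier-rule caveat) adds only ~0.15 deg² to any cell's 2D variance and
leaves the VE/RG calibration intact.  Each subject's stream derives from
`SeedSequence(seed, spawn_key=(subject_index,))`, so subjects are
exchangeable and a dataset is a pure function of the seed.

What the generator does **not** emulate: subject-level heterogeneity
(subjects are i.i.d. replicates of one profile), session structure,
front–back confusions, suboptimal or history-dependent integration,
motor/trackball noise as a separate stage.  Passing tests therefore show
that the pipeline recovers the structure it targets when the model holds;
they do not certify behaviour on real panels, whose weights and gains are
noisier and need not be internally MLE-consistent.

## Aggregation conventions

Table-style measures (VE, CE, orientation/direction deviations) and the
visual weights are computed per subject and averaged over subjects
(matching a subject-level analysis, and the convention under which
reported weight values in this literature are interpretable — weights from
9-df variance estimates are shrunk toward 0.5 by estimator noise).  The
observed-vs-predicted field comparison instead fuses **pooled** per-target
summaries: harmonic fusion of per-subject 9-df variance estimates is
biased low by ~4% (Jensen), which would turn a model-adequacy comparison
into a bias detector, while the pooled (~100-df) fusion bias is ~0.04%.
Direction deviations are emitted in both circular ([0°, 180°]; 180 = pure
undershoot) and axial ([0°, 90°]) conventions, because both appear in this
literature; the summary table uses the axial form and the per-target CSV
carries both.  The comparison stage drops the ±30° azimuth columns so
azimuth and elevation cover the same ±20° range (25 targets); the central
target has no direction and is excluded from orientation/direction
deviations.

## Numerical choices and degenerate inputs

χ²₂ quantile for ellipse scaling (the coverage convention is stated, since
several exist); closed-form 2 × 2 eigendecomposition with axial angles
θ ≡ θ + 180°; isotropic covariances have undefined orientation (flagged,
reported 0); a collapsed axis yields b = 0, ε = 0, orientation along the
surviving axis; ρ for a degenerate cell is reported 0 with a flag.  The
affine target→endpoint map is the least-squares fit, decomposed as
rotation ∘ shear ∘ scale via QR with positive diagonal (a reflection, if
ever present, lands in a negative y-scale); collinear target layouts are
rejected.  Distortion-grid fold-overs are detected by orientation flips of
the triangulated grid cells.  Zero-variance inputs to correlations are
flagged `defined=False` rather than propagating NaN.

## Known limitations

* With the dispersion anchors above, the elevation-axis visual weight is
  necessarily ≥ 0.92 everywhere (σ_A,y ≈ 5.4° vs σ_V,y ≤ 1.8°): any
  faithful exact-MLE simulation yields elevation weights above the 0.6–0.9
  range that real panels report, whose printed weights are not internally
  consistent with their printed dispersions under the fusion equations.
  The calibration consistency check in the test suite documents this
  honestly rather than adjusting the conditions to mask it.
* Mean redundancy gain at full scale (10 × 10) has a run-level SD of
  ~1.8 percentage points around ~12%; single runs occasionally fall below
  10%.
* The pipeline estimates moments per cell without robust alternatives
  (no trimmed covariances, no kernel fields), by design.
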