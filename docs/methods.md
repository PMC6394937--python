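# Methods

## Problem and scope

The package classifies a delineated shoulder-ultrasound lesion as
supraspinatus *tear* or *tendinopathy*. Inputs are an 8-bit grayscale
frame, a lesion ROI (polygon vertices or binary mask) and a label;
delineation itself (clinically done by an expert, e.g. in ImageJ) is out
of scope, as are DICOM ingestion, automatic segmentation and scanner
calibration.

## Geometry conventions

Coordinates are 0-based `(row, col)`. Pixel `(r, c)` occupies the unit
square centered at `(r + 0.5, c + 0.5)`. Polygon vertices are given in
pixel-index units and placed at pixel centers; a pixel belongs to the
rasterized mask iff its center is inside the polygon by the even-odd rule
*or exactly on its boundary*. Boundary inclusion makes the axis-aligned
rectangle with corners `(0,0)`–`(3,3)` select the full 4×4 pixel block it
visually spans, which is the least surprising reading of hand-delineated
vertex lists. Color images whose channels are identical (a common
workstation export artifact) are collapsed to one channel; genuinely
colored input is rejected rather than silently converted.

## Intensity features

Population central moments of the masked intensities: mean, variance
m₂, skewness m₃/m₂^{3/2} and kurtosis m₄/m₂² (non-excess; Gaussian
reference 3). Divide-by-n moments are used without small-sample
correction — lesion ROIs contain thousands of pixels, where the
distinction is far below measurement noise. At zero variance, skewness
and kurtosis are undefined and reported as `nan`, the package-wide
undefined sentinel; downstream code must treat `nan` explicitly (the
classifier refuses tables with undefined values in selected features,
and directional texture means propagate it).

## Texture features

Intensities are quantized by `level = floor(value · G / 256)` with G = 8
levels — eight bins match the pattern granularity a clinical reader
distinguishes, and the mapping splits [0, 255] into exactly equal bins of
32 values. For each direction θ ∈ {0°, 45°, 90°, 135°} (offsets (0,+d),
(−d,+d), (−d,0), (−d,−d)) and distance d = 1, a G×G co-occurrence matrix
counts ordered level pairs **symmetrically** (both (i,j) and (j,i) per
pair), so matrices are symmetric and marginals well defined. Pairs are
counted only when *both* pixels are inside the lesion mask; background
texture never leaks into the lesion statistics. d = 1 is the default to
resolve small lesions (sub-centimeter tears); it is exposed as a knob.

The matrix is normalized to probabilities once per direction; the 14
statistics are computed per direction; the *features*, not the matrices,
are then averaged over the four directions. Entropies use the natural
logarithm by default (`log_base="2"` switches to bits; base rescales
entropy-family features but never reorders cases). The inverse-difference
forms are the normalized variants dividing by G and G²: on near-uniform
ultrasound textures they sit above plain homogeneity, consistent with
their use as separate features. Difference variance is the variance of
the gray-level difference distribution p_{|i−j|} — a formula distinct
from contrast, even though on some clinical data the two can be reported
with near-identical summaries. Correlation and the information measure of
correlation are undefined (nan) when a marginal is degenerate (constant
lesion).

## Screening

Each feature is screened for a class difference at α = 0.05. A
Kolmogorov–Smirnov test against a normal law with sample-estimated mean
and SD decides normality per class; the t-test (classic pooled-variance
Student; Welch by flag) is used only when *both* classes look normal
(p > 0.05), otherwise the two-sided Mann–Whitney U (exact null
distribution for small tie-free samples, tie-corrected normal
approximation otherwise, scipy's policy). Estimating the normal's
parameters from the sample is the Lilliefors situation: the naive KS
p-value is biased upward, so the routing favors the t-test; a
Lilliefors-corrected option (statsmodels) is available. No
multiple-testing correction is applied — screening is reported for
transparency and does not feed the classifier's feature selection, which
is performed independently by backward elimination.

## Classifier

Binary logistic regression parameterized as
`P(tear) = 1/(1 + exp(−(Σ fᵢCᵢ − constant)))`, threshold 0.5 with ties
called tears. Fitting is damped Newton maximum likelihood (step halving;
converged when the log-likelihood change drops below 1e−8, capped at 100
iterations). Features are z-scored internally purely for conditioning and
coefficients mapped back to the raw scale — the unpenalized ML optimum is
equivariant under affine feature maps, so this changes arithmetic, not
the model. Degenerate inputs fail loudly: constant features, numerically
collinear pairs (|r| ≈ 1, the error names the pair), single-class data,
fewer than two cases per class, undefined feature values.

**Separation.** If the fitted direction classifies the training data
perfectly, a separating hyperplane exists and the ML optimum diverges;
this (or a singular Hessian, or a diverging coefficient norm) triggers a
refit with a tiny ridge penalty (1e−6, intercept unpenalized) and sets a
`separation_` flag. Flagged fits yield saturated, honest probabilities
near 0/1 but their coefficients are not interpretable; the flag is
serialized with the model. Because flagged fits are stopped by the
iteration cap, warm- and cold-started refits can differ in the saturated
tail (~1e−4 in probability) — irrelevant for classification.

**Feature selection** is greedy backward elimination: evaluate the LOOCV
error of the current set; evaluate it for every single-feature removal;
remove the feature whose removal yields the smallest error if that error
does not exceed the current one, breaking exact ties by the largest Wald
p-value in the full-data fit of the current set (Wald z-scores are
computed on the standardized parameterization, where they are invariant
to per-feature rescaling); stop when every removal strictly increases the
error or one feature remains. The criterion is deterministic given the
data. A known limitation: LOOCV 0/1 error has granularity 1/N and
fold-correlated noise, so with several pure-noise features the greedy
loop can stall at a local minimum that retains one of them — at n = 200
with three noise features, all three are removed in roughly half of
random replicates, not almost always. Significance-threshold elimination
would be more aggressive but trades the error-rate criterion for an
arbitrary p cutoff; the error-rate criterion is kept.

**Cross-validation.** LOOCV is case-wise: each case is predicted by a
model fitted on the other N−1 (folds whose training half degenerates to
one class fall back to the training majority rate and are the only
non-model predictions). Three selection protocols are first-class:
`fixed` (no selection; LOOCV the given set), `paper` (select once on all
data, then LOOCV the fixed surviving set — the protocol a study reporting
a single global selected set most plausibly used; optimistic because
selection saw every case), and `inside` (selection repeated within every
training fold; leakage-free and much slower). The default is `fixed` with
an explicit feature list, so the protocols can be compared deliberately.
Fold fits are warm-started from the full-data solution; for unpenalized
ML fits this is purely a speed device (folds are refitted to their own
optimum at tolerance 1e−8). Patient-grouped folding is not implemented;
with multiple images per shoulder in a real dataset, case-wise LOOCV is
mildly optimistic, which is a limitation to keep in mind when reading
absolute numbers.

## Evaluation

Confusion counts with tear as the positive class; accuracy, sensitivity,
specificity, PPV and NPV as raw proportions, with `nan` for empty
denominators. Display truncates (floors) proportions to integer percent —
the convention under which count fractions and printed percentages in
reference clinical reports agree cell-by-cell; raw proportions are always
kept alongside. The ROC is the empirical threshold sweep over observed
scores and Az its trapezoidal area, identical (ties at half credit) to
the all-pairs Mann–Whitney probability; no binormal curve fitting is
performed, so Az values here are not comparable to binormal-MLE software
to the third decimal. Paired model comparison uses the exact McNemar test
(Binomial(b + c, ½) on discordant correctness).

## Synthetic phantom

Each case is `clip(round(μ(r,c) · S(r,c)))` on a 128×128 frame, where S
is unit-mean multiplicative speckle: gamma(k = 4) noise smoothed by a
Gaussian PSF (σ = 1 px). μ encodes the class:

* tendinopathy — mean 117 with oblique sinusoidal fibrillar bands
  (amplitude 25, period 16 px) plus 1–2 hypoechoic Gaussian patches whose
  depth scales with the band amplitude (so amplitude 0 is the exact
  noise-free limit);
* tear — mean 43 with one focal anechoic disk at level 15 covering 10% of
  the lesion.

The ROI is a random convex polygon covering ~20–60% of the frame (center
jitter, Gaussian point cloud, convex hull rescaled to a target area and
clamped to the frame — clamping can shave the realized fraction). Class
means 117/43 anchor the echogenicity contrast between tendinopathy and
tear lesions; the structural terms are deliberately modest so that
echogenicity separation dominates separability. Case k draws from the
dedicated substream `default_rng([seed, k])`, making any single case
reproducible in isolation.

What the phantom reproduces: the direction of every class contrast the
classifier exploits — tears darker (lower mean, lower variance), more
peaked (higher kurtosis), more uniform (higher energy, lower entropy)
than tendinopathies. What it does not: acoustic physics (beamforming,
attenuation, shadowing, anisotropy of real tendon fibers), realistic
lesion morphology, inter-patient variability, and the sign of skewness
(phantom tears are left-skewed because the anechoic core sits below a
homogeneous background, whereas clinical tears, bounded below by black,
skew right). Consequently, passing end-to-end tests demonstrates that the
pipeline is wired correctly and separates classes whose feature-level
contrasts match the clinical directions — it does not certify clinical
accuracy. At the default contrast the phantom is in fact linearly
separable even by texture alone, so LOOCV accuracy is ~100% at every
echogenicity separation; absolute phantom accuracies carry no clinical
meaning.

## Problem sizes and numerical choices

The reference phantom study uses 50 cases per class (a deliberate
desk-scale default that keeps a full LOOCV study under a second while
leaving class-summary medians stable); elimination caches LOOCV errors
per feature subset and warm-starts fold fits. Newton tolerance 1e−8,
iteration cap 100, ridge 1e−6 on separation, collinearity guard at
|r| > 1 − 1e−7. Entropy terms use 0·log 0 = 0. All tabular artifacts are
headered CSV; models serialize to JSON with their separation flag.
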