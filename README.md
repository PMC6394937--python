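# sonotear

Texture-based computer-aided classification of **rotator cuff tears versus
tendinopathy** in shoulder ultrasound.

Shoulder ultrasound is the first-line examination for supraspinatus tears,
but its accuracy is strongly operator dependent. Given an 8-bit grayscale
frame and an expert-delineated lesion region of interest (ROI), this
package quantifies the lesion's sonographic appearance and turns it into a
calibrated tear probability, so that the same case always yields the same
recommendation. It is aimed at musculoskeletal-imaging researchers who
have delineated ultrasound lesions and labels and want a reproducible,
testable reference pipeline.

## The model

For each case the lesion pixels are summarised by 18 features:

* **Histogram moments** (first-order): mean, variance, skewness and
  kurtosis of the ROI intensity distribution (population moments;
  kurtosis in the non-excess form m₄/m₂², Gaussian reference 3). Tears
  are hypoechoic — lower mean, more peaked distribution.
* **Co-occurrence statistics** (second-order): the ROI is quantized to
  G = 8 gray levels; symmetric gray-level co-occurrence matrices
  P = [p(i,j | d, θ)] are built at distance d = 1 for θ ∈ {0°, 45°, 90°,
  135°} from pixel pairs that lie *entirely inside* the lesion mask, and
  14 standard statistics (energy, entropy, contrast, correlation, cluster
  shade/prominence, homogeneity, difference variance/entropy, information
  measure of correlation, inverse difference normalized/moment, …) are
  averaged over the four directions.

Features are screened univariately (Kolmogorov–Smirnov normality routing
to Student's t or Mann–Whitney U, α = 0.05) and combined in a binary
logistic regression

    P(tear) = 1 / (1 + exp(−(f₁C₁ + ⋯ + fₙCₙ − constant)))

fitted by Newton maximum likelihood, with greedy backward elimination of
features driven by leave-one-out cross-validation (LOOCV) error. A case is
called a tear when P(tear) ≥ 0.5. Performance is reported as accuracy,
sensitivity, specificity, PPV and NPV (displayed as truncated integer
percent) plus the empirical area under the ROC curve (Az).

Because clinical images cannot be redistributed, the package ships a
**synthetic phantom generator**: speckled 8-bit lesions in which tears are
darker, more peaked and more uniform than tendinopathies, with a single
seed fixing every image bit-exactly. It exists so that every stage of the
pipeline — and its end-to-end behavior — is testable on any machine.

## Worked example

```sh
sonotear simulate  --out-dir demo/data --n-per-class 25 --dims 96 --seed 3
sonotear extract   --manifest demo/data/manifest.csv --out demo/features.csv
sonotear screen    --features demo/features.csv --out demo/screen.csv
sonotear train-eval --features demo/features.csv --out-dir demo/eval \
                    --feature-set combined --selection-mode paper
```

which prints (stderr):

```
wrote 50 cases and manifest to demo/data/manifest.csv
wrote feature table (50 cases) to demo/features.csv
18/18 features significant at alpha=0.05
backward elimination kept: Mean
LOOCV accuracy 1.000, Az 1.0000 -> demo/eval
```

and writes `demo/eval/report.txt`:

```
	combined
Accuracy	100% (50/50)
Sensitivity	100% (25/25)
Specificity	100% (25/25)
PPV	100% (25/25)
NPV	100% (25/25)
Az	1.0000
```

On the default phantom the two classes differ in mean echogenicity by
74 gray levels, so all 18 features separate the classes (18/18 significant
at α = 0.05), elimination collapses the model to the single `Mean` feature,
and LOOCV classifies every case correctly — the phantom is deliberately an
easy problem; its purpose is pipeline verification, not difficulty.
`--selection-mode inside` repeats the feature selection inside every
training fold instead of selecting once on all data.

The same commands run on real data: point `--manifest` at a CSV with
columns `case_id,patient_id,image_file,roi_file,label` where images are
8-bit PNG/TIFF, ROIs are either `row,col` vertex CSVs or mask PNGs, and
labels are `tendinopathy`/`tear`.

Library use mirrors scikit-learn: `NewtonLogisticRegression` and
`BackwardEliminationLogistic` are estimators with `fit`/`predict_proba`,
and `extract_features`, `screen`, `loocv`, `roc_and_az` are plain
functions over pandas tables.

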