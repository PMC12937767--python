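# hchsnet

Handcrafted multimodal features for six-class skin-lesion classification.

Clinical photographs of pigmented skin lesions (the six PAD-UFES-20
diagnostic categories: actinic keratosis ACK, basal cell carcinoma BCC,
melanoma MEL, nevus NEV, squamous cell carcinoma SCC, seborrheic
keratosis SEK) are classified from a compact, fully interpretable
feature vector instead of a deep network. Each image is smoothed with a
5×5 Gaussian (σ = 1.0), resampled to 224×224, and summarised by

* **F_color ∈ ℝ⁹⁶** — 32-bin HSV histograms (H, S, V), each block
  L2-normalized: `ĥ = h / (‖h‖₂ + ε)`;
* **F_texture ∈ ℝ¹³** — the 13 Haralick statistics (ASM, contrast,
  correlation, variance, IDM, sum/difference statistics, entropies,
  information measures of correlation) of the symmetric gray-level
  co-occurrence matrix `P_θ,d(i,j)`, averaged over θ ∈ {0°, 45°, 90°,
  135°} at d = 1;
* **F_shape ∈ ℝ⁷** — the seven Hu moment invariants of the grayscale
  intensity image, from normalized central moments
  `η_pq = μ_pq / μ₀₀^((p+q)/2+1)`, log-stabilized as
  `h̃ᵢ = −sign(hᵢ)·log₁₀(|hᵢ| + ε)`;
* **F_meta ∈ ℝ¹²** — the clinical record (age, gender, two lesion
  diameters, smoke/drink, six symptom flags), continuous fields
  z-scored with training-set statistics.

The fused vector `F = [F_color | F_texture | F_shape | F_meta] ∈ ℝ¹²⁸`
is classified by a soft-voting ensemble of three gradient boosters
(XGBoost, LightGBM, and scikit-learn's histogram gradient boosting),
each with 500 iterations, depth 6, learning rate 0.03; the prediction
is `argmax_k (1/3) Σ_m P_m(y = k | F)`.

Supporting machinery keeps the evaluation honest: patient-level
stratified splitting (all images of a patient on one side), offline
augmentation of the training side only to a balanced per-class target,
a bootstrap-CI metric battery (accuracy, macro precision/recall/F1,
specificity, one-vs-rest AUC, Gorodkin MCC, Cohen's κ), and a synthetic
lesion generator so the whole pipeline is verifiable without any
dataset download.

## Worked example

```python
from hchsnet.synthetic import gen_dataset
from hchsnet.pipeline import run_pipeline

ds = gen_dataset(20, separability=1.0, seed=11)   # 120 synthetic lesions
result = run_pipeline(ds.images, ds.manifest, seed=11, iterations=200)
print(result.results.summary())
print(result.report.summary())
```

```
Lesion ensemble (gradient boosting, soft voting)
========================================================
n obs:     95    n features:  128    classes: 6
label order: ACK, BCC, MEL, NEV, SCC, SEK
schema hash: 09fefdd9493e7948
--------------------------------------------------------
member       iterations  depth     lr   seed
xgboost             200      6   0.03     11
lightgbm            200      6   0.03     12
histgb              200      6   0.03     13
--------------------------------------------------------
training accuracy: 1.0000

Metric                 Value   95% CI
accuracy               1.0000
macro_precision        1.0000
macro_recall           1.0000
macro_f1               1.0000
macro_specificity      1.0000
macro_auc              1.0000
mcc                    1.0000
kappa                  1.0000
```

At separability 1.0 the six synthetic classes have disjoint hue,
texture and shape parameter ranges, so a correct pipeline recovers the
labels of all 25 held-out images (patients never span the split). The
fitted ensemble is inspectable — here hue-histogram bins and the first
lesion diameter carry the most split gain:

```python
print(result.results.feature_importance().head(5))
```

```
  feature  importance
colorH_25    0.127072
colorH_06    0.117349
colorH_11    0.110267
meta_d1_z    0.109589
colorH_31    0.094320
```

Lowering `separability` makes the class recipes overlap and the
held-out accuracy falls accordingly; `metadata_separability` can be set
independently to probe how informative clinical records compensate for
ambiguous images.

A CLI mirrors the library (`hchsnet simulate / preprocess / extract /
train / predict / ablate / augment`); run `hchsnet --help`.

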