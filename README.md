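# slcau — sparse locally-coherent 3D morphable models for facial action units

Facial Action Units (AUs) — the elementary muscle movements catalogued by the
Facial Action Coding System, such as the lip-corner puller or the outer-brow
raiser — deform only a small, often asymmetric patch of the face. Classical
3D morphable models (3DMMs) are built with PCA, whose components have global
support: every component moves every vertex, which makes them a poor language
for describing AUs. `slcau` implements the alternative: a 3DMM whose
deformation components are *sparse and locally coherent*, learned by treating
each vertex coordinate's across-scan displacement profile as a training
sample and solving a non-negative elastic-net sparse-coding problem. It then
uses that model to detect and synthesize AUs on raw 3D scans.

The package is aimed at researchers in 3D face analysis who want a fully
scriptable, download-free reference implementation of this pipeline, complete
with a synthetic-face generator that stands in for licensed scan corpora.

## The model

Registered training scans `f_i ∈ R^{3m}` (all on one template topology, in
mm) give a mean face `m = (1/N) Σ f_i` and displacements `v_i = f_i − m`.
Transposing the displacement matrix makes each of the `3m` coordinates an
`N`-vector sample `v'_i`, decomposed as

```
min_{D,C}  (1/3m) Σ_i ‖v'_i − D c_i‖² + λ₁‖c_i‖₁ + λ₂‖c_i‖²,   D ≥ 0, C ≥ 0
```

The rows of `C` (k × 3m) are the deformation components: the ℓ1 term makes
them sparse, the ℓ2 term induces the grouping effect (vertices that move
coherently under one muscle load the same atom), and positivity promotes
complementary, part-like atoms. Each component j carries a weight
`μ_j = mean(C_j)`, its average intensity.

Fitting the model to a raw scan iterates four closed-form steps: nearest-
neighbour correspondence, similarity estimation `S = t̂_c·P + T` (P solved in
least squares, factored by QR into rotation and scale), realignment of the
target, and ridge-regularized deformation
`α = (CᵀC + λ·diag(μ̂⁻¹))⁻¹ CᵀX` with `X = t̂_c − S`, applied as
`S ← S + Σ_j α_j c_j`, until the mean vertex error stabilizes below `τ_e`.

AU-specific coefficients come from a two-step decoupling: fit the mean to a
subject's *neutral* scan (identity), snap the fitted shape to the scan
vertices (`ŝ_n`), then fit `ŝ_n` to the subject's *expressive* scan — the
per-iteration coefficients, averaged, form `α_e`, which feeds a One-vs-Rest
RBF-kernel SVM (leave-one-subject-out evaluation) and, averaged per AU
across subjects, yields prototypes `α_e^AU` that activate the AU on any
registered neutral face.

## Worked example

```python
from slcau import (MorphableModel, TrainingSet, SyntheticConfig,
                   generate_corpus, fit_identity, resample_neutral,
                   extract_au_coefficients, loocv_evaluate)

train = generate_corpus(SyntheticConfig(seed=11, n_subjects=12))
training = TrainingSet.from_shapes(train.registered_shapes())
model = MorphableModel.from_training_set(training, kind="slc", k=50, seed=11)
print(model.summary())

test = generate_corpus(SyntheticConfig(seed=99, n_subjects=10))
records = []
for subject in sorted({e.subject_id for e in test.scans}):
    scans = [e for e in test.scans if e.subject_id == subject]
    neutral = next(e for e in scans if e.label == "neutral")
    s_n, alpha_id, res = fit_identity(model, neutral.raw)
    s_hat = resample_neutral(res.deformed_target_frame, neutral.raw)
    for e in scans:
        if e.label != "neutral":
            records.append(extract_au_coefficients(
                model, s_hat, e.raw, subject_id=subject, au_label=e.label))

print(loocv_evaluate(records).summary())
```

prints

```
MorphableModel(kind=slc, k=50, vertices=481)
  topology: synthetic-face-481
  weights mu: min=0.002814 max=3.429
  l1=0.2, l2=0.01, sparsity=58.5% near-zero entries
  training objective: 75.98 -> 11.46 over 60 iterations
Leave-one-subject-out over 10 subjects, 40 test scans
  accuracy=1.000  mean F1=1.000  mean AUC=1.000
     AU-BROW-L  F1=1.000  AUC=1.000
     AU-BROW-R  F1=1.000  AUC=1.000
    AU-CHEEK-L  F1=1.000  AUC=1.000
      AU-MOUTH  F1=1.000  AUC=1.000
```

The model summary shows the elastic-net penalties produced a basis with 59%
exactly-sparse entries while the training objective fell monotonically; the
evaluation block shows that on this strongly-separable synthetic corpus the
extracted deformation coefficients classify all four AU activations of ten
unseen subjects perfectly under leave-one-subject-out cross-validation.

The same objects drive the `slcau` command line
(`simulate`, `build-model`, `fit`, `extract`, `evaluate`, `synthesize`);
see `slcau --help`.

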