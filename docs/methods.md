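# Methods

## Model

A morphable model here is a mean shape `m ∈ R^{3m}` (vertex coordinates in
mm, layout `[x1,y1,z1,…]`) plus `k` linear deformation fields, the rows of
`C ∈ R^{k×3m}`, and per-component weights `μ ∈ R^k_{>0}`. New shapes are
`m + Σ_j α_j c_j`.

**Sparse locally-coherent basis.** The distinguishing construction is the
change of sample: instead of one sample per scan, each of the `3m` vertex
coordinates contributes its `N`-vector of displacements across the `N`
training scans. Stacking these as columns of `V' = Vᵀ`, the basis solves

    min_{D,C} (1/3m) Σ_i ( ‖v'_i − D c_i‖² + λ₁‖c_i‖₁ + λ₂‖c_i‖² ),
    D ≥ 0, C ≥ 0, ‖d_j‖ ≤ 1.

Coordinates that move coherently (one muscle's patch) have correlated
columns and, through the ℓ2 grouping effect, receive similar codes; the ℓ1
term zeroes the rest. The result is deformation fields that are sparse and
spatially contiguous, unlike the global PCA basis (also provided, as
`kind="pca"`: top-k right-singular directions of `Vᵀ`, weights
`σ_j/√(N−1)`).

Because displacements are signed while the program is posed over
non-negative factors, learning operates on `V'` shifted by its global
minimum. The offset is stored in the model (`data_offset`) and affects only
training-side reconstruction — fitting uses `C` with unconstrained `α`, so
no shape expressible by the basis is lost.

**Solver.** Alternating minimization, both halves monotone: the codes by
cyclic non-negative coordinate descent (soft threshold `λ₁/2`, vectorized
across all `3m` samples), the dictionary by projected gradient with a `1/L`
step and exact projection onto `{D ≥ 0, ‖d_j‖ ≤ 1}` (clip, then scale). The
per-outer-iteration objective trace is recorded and asserted non-increasing
(tolerance 1e-9) on every run. Initialization draws `k` distinct training
samples (seeded); all stochastic steps store their seed in the model.

**Component weights.** `μ_j` is the mean of row j of the non-negative `C`,
floored at 1e-8 — a per-component average intensity. During fitting the
ridge penalty is `λ Σ_j α_j²/μ_j`, so stronger components absorb more
residual. (The quadratic matching the closed-form normal equations with
`diag(μ⁻¹)` is used as printed; the variant with `diag(μ⁻²)` is available as
`penalty="squared"`.)

**Defaults.** `k = 50` (with `k = 300` meaningful only for corpora with
hundreds of scans); `λ₁ = 0.2`, `λ₂ = 0.01`, 60 outer iterations. The
penalties were chosen by the locality diagnostic — the fraction of
components whose above-half-max support concentrates ≥70% in a single
generator region — on localized-deformation corpora: large `λ₂` actively
*delocalizes* the basis because the grouping effect spreads the
globally-shared offset baseline across many duplicate atoms, so `λ₂` is kept
an order of magnitude below `λ₁`.

## Fitting

After an optional rigid ICP pre-alignment (Kabsch inner step, relative
improvement tolerance 1e-6, max 50 iterations), the fit iterates:

1. **correspond** — each model vertex takes its nearest target vertex
   (many-to-one allowed, lowest-index tie-break);
2. **similarity** — the 3×3 matrix `P` (rotation·scale) minimizing
   `‖(S−S̄) − (t̂_c−t̄_c)P‖²` in closed form, translation as the centroid
   residual, `P = R·Sc` by QR with signs fixed so `diag(Sc) > 0` and
   `det(R) = +1`;
3. **realign** — `t̂_c ← (t̂_c·R)·Sc + T`, applied to the full target too;
4. **deform** — `α_t = (CᵀC + λ·diag(μ⁻¹))⁻¹ Cᵀ(t̂_c − S)` by a symmetric
   positive-definite solve, `S ← S + Σ_j α_{t,j} c_j`.

Iteration stops when the mean vertex-to-nearest-target distance, or its
change between iterations, falls below `τ_e`, or at `max_iter`. Defaults:
`λ = 0.05`, `τ_e = 1e-3` mm, `max_iter = 30`. The deformation accumulates
across iterations; the per-iteration increments `α_t` are recorded and their
element-wise mean is the scan's summary coefficient vector (alternatives:
`max`, `first`, `threshold`).

Two numerical safeguards surround the printed procedure:

* **Robust similarity (`sim_trim = 0.8`).** The similarity step is estimated
  on the best-matching 80% of correspondences (realignment still moves
  everything). Estimated on all vertices, a one-sided localized deformation
  contributes a nonzero mean residual that is absorbed as a spurious
  translation/scale each iteration; the drift then leaks into the
  coefficients of *uninvolved* regions and shows up as out-of-region bleed
  in synthesis. Trimming removes the bias whenever the static part of the
  surface is the majority.
* **Divergence guard.** When the error rises three iterations in a row
  (possible under trimming when the deformation is global and the
  "static majority" assumption fails), the loop stops and rolls back to the
  lowest-error state; the recorded iteration list is truncated to match.

Fit results are compared in the fit's own aligned frame
(`aligned_target − base`): the similarity transform is part of the model, so
the recovered deformation field is defined up to it.

## Two-step identity/expression decoupling

Per subject: (1) fit the model mean to the neutral scan → identity
coefficients and the fitted neutral `s_n`; (2) map `s_n` back into the raw
scan's frame (inverse of the accumulated similarity) and snap each vertex to
its nearest scan vertex → `ŝ_n`, a template-topology shape whose every point
is an exact scan sample; (3) for each expressive scan, translate nose tips
together, rigidly ICP-align — aligning the sparse `ŝ_n` *into* the dense
scan and inverting, which has an exact minimum because `ŝ_n` is a subset of
the scan — and fit again with base `ŝ_n`. The averaged increments `α_e`
encode only the expression-side motion; the residual small deformations from
alignment and sensor noise are approximately zero-mean across iterations and
cancel in the average.

For scans without a nose-tip annotation the proxy is the maximum-z vertex in
the canonical frame (the nose protrudes by construction on the synthetic
template, and on real frontal scans).

## Classification and synthesis

Features are the `α_e` vectors: L2-normalized per vector, standardized per
feature, and projected onto the fewest principal directions carrying ≥95%
of the variance — all statistics from the training records only, frozen for
the test fold. The classifier is one binary C-SVM per class (One-vs-Rest,
explicitly instantiated so C classes always give C machines) with the RBF
kernel `exp(−‖x−x'‖²/2σ²)`; `σ` defaults to the median pairwise training
distance and the regularization constant to `C = 1` (both exposed).
Evaluation is leave-one-subject-out: confusion matrix (rows = actual),
per-class F1, accuracy, and per-class One-vs-Rest ROC-AUC from pooled
decision values. Early fusion of two bases is vector concatenation on
matched record sequences.

AU prototypes are arithmetic means of `α_e` over all records with the label;
synthesis applies them (averaged element-wise, for combinations) to any
shape on the model topology — the mean, a fitted neutral, or an unseen
identity. Synthesis is linear, so the added displacement field is exactly
identity-independent.

## Synthetic data

The generator replaces licensed scan corpora. The template is a
half-ellipsoid face (60 × 80 × 50 mm semi-axes) on a polar vertex grid with
a fixed relief: a 10 mm nose protrusion at the apex and gentle 2.5 mm
undulations. The relief is essential, not cosmetic: rigid registration and
nearest-neighbour correspondence on a featureless ovoid are tangentially
ill-posed, while real faces are registrable precisely because of their
relief. Landmarks sit at fixed parametric positions; a rule over the polar
parameters partitions the vertices into seven labelled regions (nose, brows
L/R, cheeks L/R, mouth, jaw), which also defines the landmark-bounded quad
scheme used by the correspondence module.

Subjects are the template plus a smooth identity field (five 40 mm Gaussian
bumps, random directions, RMS normalized to `identity_scale`). AUs are
compact cosine-tapered fields on one region — exactly zero outside it —
of three kinds: `bump` (outward normal), `asymmetric` (bump on one lateral
half), and `pull` (motion toward the region centre mixed with an equal
outward-normal bunching component; a purely tangential slide of a smooth
surface would be invisible to a scanner point cloud). AU fields are defined
in template coordinates, hence identical across subjects — the premise that
makes expression/identity disentangling achievable in principle.

Raw scans are sampled on an independent, 4×-denser jittered surface grid
(scanners resolve the face far more finely than a model's vertex count),
with the identity and AU fields evaluated at those points, vertex order
shuffled, and zero-mean Gaussian noise (`noise_sigma`) added. Registered
ground truth stays on the template grid. Everything is deterministic given
the config seed.

**Study conditions** (chosen once): template `m = 500` (481 realized
vertices), identity RMS 2 mm, four AUs at 6 mm peak magnitude (brow bump,
asymmetric brow, mouth pull, cheek bump), scanner noise 0.1 mm. Model
corpora use 12 subjects × (neutral + 4 AUs) registered shapes (N = 60, so
both SLC-50 and PCA-50 are well-posed); the classification corpus is 10
*unseen* subjects' raw scans, emulating a cross-dataset protocol. The
locality diagnostic uses identity RMS 0.3 mm so the displacement variance is
dominated by the region-localized fields it is probing.

**What the generator does not emulate:** anatomical shape statistics,
open-mouth topology changes, occlusions and holes, texture, scanner-specific
noise structure, or correlated identity/expression variation. Passing tests
show the pipeline's mechanics — basis locality, decoupling, detection,
synthesis — under its stated premises, not performance on real faces.

## Numerical notes and limitations

* Vertex ordering is the correspondence; faces are carried for export only.
* The closed-form similarity is validated through round-trip contracts
  (synthetically transformed point sets map back to 1e-6 mm), so the
  row-vector convention cannot silently corrupt results.
* Point-to-point NN fitting recovers the *surface*, not the semantic
  parameterization: on a smooth surface, per-vertex accuracy against ground
  truth saturates near the scan-sampling floor (1.5–2.5 mm at these
  conditions) even when the in-basis optimum is ~0.3 mm, because tangential
  mismatch is unobservable. The two-step pipeline is largely insensitive —
  `ŝ_n` re-samples the scan, and only consistency across a subject's scans
  matters — but absolute per-vertex claims about fitted neutrals should not
  be made.
* In-basis recovery fixtures use full-face RMS 1 mm deformations (the scale
  of a 6 mm-peak tapered AU field); much larger deformations degrade NN
  correspondence and, with it, field recovery.
* Degenerate inputs raise: empty targets, collinear ICP inputs,
  rank-deficient similarity estimation, non-positive `μ` or `λ`, mixed
  topology or component bases, zero vectors at L2 normalization, single
  training class.
* A class present in only one subject is kept with a warning; its test fold
  has no training positives and its AUC may be undefined (NaN).
* Requiring a neutral scan per subject is inherent to the two-step design;
  removing it (a posteriori separation via identity- and AU-prototype
  spaces) is future work.
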