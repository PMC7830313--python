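"""Action-unit coefficient extraction, classification and synthesis.

The deformation coefficients recovered by a dense fit mix identity (bone
structure, proportions) with expression (muscle activation).  The two are
decoupled in two steps:

1. fit the model mean to the subject's *neutral* scan, giving identity
   coefficients ``alpha_id`` and a fitted neutral shape ``s_n``; snap each
   vertex of ``s_n`` to its nearest raw-scan vertex to obtain ``s_hat_n``, a
   template-topology shape sampled from the actual surface;
2. fit the model again to the subject's *expressive* scan using ``s_hat_n``
   as the base — the new coefficients ``alpha_e`` now encode only the
   AU-induced motion.

Per expressive scan the iterative fit yields a variable-length list of
coefficient vectors; averaging across iterations cancels the near-zero-mean
noise terms and gives one feature vector per scan.  Those vectors feed a
One-vs-Rest RBF-kernel SVM (single-label multi-class), evaluated by
leave-one-subject-out cross-validation; averaged per AU they form prototypes
that synthesize the AU on any registered neutral face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .meshio import RegisteredShape, TriMesh, delinearize
from . import fitting
from .fitting import FitOptions, FitResult, RigidTransform, icp_align

__all__ = [
    "AUCoefficientRecord",
    "ClassifierBundle",
    "EvaluationReport",
    "FeaturePipeline",
    "fit_identity",
    "resample_neutral",
    "extract_au_coefficients",
    "aggregate_coefficients",
    "prepare_features",
    "fuse_features",
    "train_au_classifier",
    "loocv_evaluate",
    "compute_au_prototype",
    "synthesize_au",
]


@dataclass
class AUCoefficientRecord:
    """One extracted coefficient vector: the unit of classification.

    ``model_id`` binds the record to one component basis; records from
    different bases are never mixed except via explicit feature fusion.
    """

    subject_id: str
    au_label: str
    alpha_e: np.ndarray
    n_iterations: int = 0
    model_id: str = ""

    def __post_init__(self):
        self.alpha_e = np.asarray(self.alpha_e, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.alpha_e)):
            raise ValueError("alpha_e contains non-finite values")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "au_label": self.au_label,
            "alpha_e": self.alpha_e.tolist(),
            "n_iterations": self.n_iterations,
            "model_id": self.model_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AUCoefficientRecord":
        return cls(d["subject_id"], d["au_label"], np.asarray(d["alpha_e"]),
                   d.get("n_iterations", 0), d.get("model_id", ""))


# --------------------------------------------------------------------------
# two-step decoupling

def fit_identity(model, neutral_scan: TriMesh, options: FitOptions | None = None):
    """Fit the model mean to a neutral scan: identity shape and coefficients.

    Returns ``(s_n, alpha_id, result)`` — the fitted neutral shape on the
    template topology, the aggregated identity coefficients, and the full
    :class:`FitResult` (whose ``aligned_target`` is needed downstream).
    """
    result = fitting.fit(model, neutral_scan, base=None, options=options)
    return result.deformed, result.alpha, result


def resample_neutral(s_n: RegisteredShape, neutral_scan) -> RegisteredShape:
    """Snap each fitted-neutral vertex to its nearest raw-scan vertex.

    The result keeps the template topology but every point is an exact sample
    of the actual scan surface, improving the expressive-fit base.  Pass the
    *aligned* scan points (``FitResult.aligned_target``) when the fit moved
    the scan into the model frame.
    """
    pts = neutral_scan.vertices if isinstance(neutral_scan, TriMesh) else np.asarray(neutral_scan, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("empty scan")
    _, idx = cKDTree(pts).query(s_n.points)
    return RegisteredShape(pts[idx].reshape(-1), s_n.topology_id)


def _nose_tip(points: np.ndarray, landmarks: dict | None) -> np.ndarray:
    if landmarks and "nose_tip" in landmarks:
        return np.asarray(landmarks["nose_tip"], dtype=np.float64)
    # proxy: in the canonical frame the face looks along +z, apex = nose
    return points[int(np.argmax(points[:, 2]))]


def extract_au_coefficients(
    model,
    s_hat_n: RegisteredShape,
    expressive_scan: TriMesh,
    options: FitOptions | None = None,
    *,
    au_label: str | None = None,
    subject_id: str | None = None,
    allow_nose_proxy: bool = True,
) -> AUCoefficientRecord:
    """Extract expression coefficients for one expressive scan of a subject.

    Aligns the scan's nose tip to the resampled neutral, runs a rigid ICP to
    absorb residual roto-translation, then fits with base ``s_hat_n``; the
    per-iteration coefficients are aggregated (default: mean) into
    ``alpha_e``.
    """
    opts = options or FitOptions()
    pts = expressive_scan.vertices
    if expressive_scan.landmarks is None or "nose_tip" not in (expressive_scan.landmarks or {}):
        if not allow_nose_proxy:
            raise ValueError("expressive scan lacks a 'nose_tip' landmark and the proxy is disabled")
    nose_scan = _nose_tip(pts, expressive_scan.landmarks)
    nose_base = _nose_tip(s_hat_n.points, None)
    aligned = pts + (nose_base - nose_scan)
    # ICP from the sparse template-topology shape into the dense scan has an
    # exact minimum (its points are scan samples); invert to move the scan
    icp = icp_align(s_hat_n.points, aligned)
    aligned = (aligned - icp.T) @ icp.P.T

    inner = FitOptions(lam=opts.lam, tau_e=opts.tau_e, max_iter=opts.max_iter,
                       icp=False, penalty=opts.penalty, aggregate=opts.aggregate)
    result = fitting.fit(model, aligned, base=s_hat_n, options=inner)
    return AUCoefficientRecord(
        subject_id=subject_id or expressive_scan.subject_id or "",
        au_label=au_label or expressive_scan.label or "",
        alpha_e=aggregate_coefficients(result.alphas, opts.aggregate),
        n_iterations=result.iterations,
        model_id=model.model_id,
    )


def aggregate_coefficients(alphas, strategy: str = "mean", threshold: float = 1e-3) -> np.ndarray:
    """Collapse per-iteration coefficient vectors into one summary vector.

    ``mean`` (default, best-performing: near-zero-mean noise terms cancel),
    ``max`` (element-wise entry of maximal magnitude, sign kept), ``first``,
    or ``threshold`` (mean after zeroing entries with ``|value| < threshold``).
    """
    if len(alphas) == 0:
        raise ValueError("empty coefficient list")
    A = np.asarray(alphas, dtype=np.float64)
    if strategy == "mean":
        return A.mean(axis=0)
    if strategy == "max":
        idx = np.argmax(np.abs(A), axis=0)
        return A[idx, np.arange(A.shape[1])]
    if strategy == "first":
        return A[0].copy()
    if strategy == "threshold":
        masked = np.where(np.abs(A) < threshold, 0.0, A)
        return masked.mean(axis=0)
    raise ValueError(f"unknown aggregation strategy {strategy!r}")


# --------------------------------------------------------------------------
# feature preparation and classification

class FeaturePipeline:
    """L2 normalization -> standardization -> 95%-variance PCA projection.

    All statistics (feature means/scales, principal directions) come from the
    training records only; test records are transformed with the frozen
    statistics, so no information leaks across the evaluation split.
    """

    def __init__(self, variance: float = 0.95):
        self.variance = variance
        self.scaler: StandardScaler | None = None
        self.projector: PCA | None = None

    @staticmethod
    def _l2(X: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("cannot L2-normalize a zero feature vector")
        return X / norms[:, None]

    def fit(self, X: np.ndarray) -> "FeaturePipeline":
        X = self._l2(np.asarray(X, dtype=np.float64))
        self.scaler = StandardScaler().fit(X)
        Xs = self.scaler.transform(X)
        n_comp = min(Xs.shape[0], Xs.shape[1])
        full = PCA(n_components=n_comp, svd_solver="full").fit(Xs)
        cum = np.cumsum(full.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, self.variance) + 1)
        self.projector = PCA(n_components=keep, svd_solver="full").fit(Xs)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None or self.projector is None:
            raise RuntimeError("pipeline not fitted")
        return self.projector.transform(self.scaler.transform(self._l2(np.asarray(X, dtype=np.float64))))

    @property
    def n_components(self) -> int:
        return int(self.projector.n_components_)

    @property
    def explained_variance(self) -> float:
        return float(np.sum(self.projector.explained_variance_ratio_))


def prepare_features(records, variance: float = 0.95):
    """Fit the preprocessing pipeline on a record set and transform it.

    All records must share one ``model_id``.  Returns ``(features, pipeline)``.
    """
    ids = {r.model_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix component bases: {sorted(ids)}")
    X = np.vstack([r.alpha_e for r in records])
    pipe = FeaturePipeline(variance).fit(X)
    return pipe.transform(X), pipe


def fuse_features(a: np.ndarray, b: np.ndarray, records_a=None, records_b=None) -> np.ndarray:
    """Early fusion by concatenation: row-wise ``[a | b]``.

    When record lists are given, they must describe the same (subject, label)
    sequence in the same order.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0:
        return b.copy()
    if b.size == 0:
        return a.copy()
    if a.shape[0] != b.shape[0]:
        raise ValueError("feature sets have different numbers of records")
    if records_a is not None and records_b is not None:
        keys_a = [(r.subject_id, r.au_label) for r in records_a]
        keys_b = [(r.subject_id, r.au_label) for r in records_b]
        if keys_a != keys_b:
            raise ValueError("record sequences differ between the fused modalities")
    return np.hstack([a, b])


def _median_sigma(X: np.ndarray) -> float:
    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


@dataclass
class ClassifierBundle:
    """Frozen preprocessing + one binary RBF SVM per class (One-vs-Rest)."""

    pipeline: FeaturePipeline | None
    svms: dict
    classes: list
    sigma: float
    C: float
    model_id: str = ""

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, C) decision values, column order = ``classes``."""
        return np.column_stack([self.svms[c].decision_function(X) for c in self.classes])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_matrix(X)
        # argmax breaks ties toward the lowest class index
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def train_au_classifier(
    features: np.ndarray,
    labels,
    C: float = 1.0,
    sigma: float | None = None,
    pipeline: FeaturePipeline | None = None,
    model_id: str = "",
) -> ClassifierBundle:
    """Train one binary RBF-SVM per class (One-vs-Rest).

    The kernel is ``K(x, x') = exp(-||x - x'||^2 / (2 sigma^2))``; ``sigma``
    defaults to the median pairwise training distance.  Prediction is the
    argmax of per-class decision values.  Deterministic given inputs.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("classification needs at least 2 classes")
    if sigma is None:
        sigma = _median_sigma(X)
    gamma = 1.0 / (2.0 * sigma**2)
    svms = {}
    for c in classes:
        yc = (y == c).astype(int)
        svms[c] = SVC(C=C, kernel="rbf", gamma=gamma).fit(X, yc)
    return ClassifierBundle(pipeline, svms, classes, float(sigma), float(C), model_id)


# --------------------------------------------------------------------------
# leave-one-subject-out evaluation

@dataclass
class EvaluationReport:
    """Aggregated leave-one-subject-out results.

    ``confusion`` rows are actual classes, columns predicted; metrics are
    accumulated over every test fold (one per subject).
    """

    classes: list
    confusion: np.ndarray
    accuracy: float
    per_class_f1: dict
    per_class_auc: dict
    folds: list = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(list(self.per_class_f1.values())))

    @property
    def mean_auc(self) -> float:
        vals = [v for v in self.per_class_auc.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)

    def summary(self) -> str:
        rows = []
        for c in self.classes:
            rows.append(
                f"  {c:>12}  F1={self.per_class_f1[c]:.3f}  AUC={self.per_class_auc[c]:.3f}"
            )
        head = (
            f"Leave-one-subject-out over {len(self.folds)} subjects, "
            f"{int(self.confusion.sum())} test scans\n"
            f"  accuracy={self.accuracy:.3f}  mean F1={self.mean_f1:.3f}  mean AUC={self.mean_auc:.3f}"
        )
        return "\n".join([head, *rows])

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_f1": {k: float(v) for k, v in self.per_class_f1.items()},
            "per_class_auc": {k: float(v) for k, v in self.per_class_auc.items()},
            "n_folds": len(self.folds),
        }

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.confusion_frame()
        im = ax.imshow(frame.values, cmap="Blues")
        ax.set_xticks(range(len(self.classes)), self.classes, rotation=45, ha="right")
        ax.set_yticks(range(len(self.classes)), self.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("actual")
        plt.colorbar(im, ax=ax)
        return ax


def _f1_from_confusion(conf: np.ndarray) -> np.ndarray:
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


def loocv_evaluate(
    records,
    C: float = 1.0,
    sigma: float | None = None,
    variance: float = 0.95,
    label_map=None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of the AU classifier.

    Per left-out subject: fit the feature pipeline and the One-vs-Rest SVMs
    on the remaining subjects only, transform and predict the held-out scans,
    and accumulate the confusion matrix and decision values.  Per-class
    ROC-AUC is computed One-vs-Rest from the pooled decision values.

    ``label_map`` optionally relabels records (e.g. for shuffle controls).
    """
    records = list(records)
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    get_label = (lambda r: label_map[id(r)]) if label_map else (lambda r: r.au_label)
    classes = sorted({get_label(r) for r in records})
    cls_index = {c: i for i, c in enumerate(classes)}

    for c in classes:
        owners = {r.subject_id for r in records if get_label(r) == c}
        if len(owners) < 2:
            warnings.warn(
                f"class {c!r} appears in a single subject; its test fold has no training positives",
                stacklevel=2,
            )

    n_cls = len(classes)
    confusion = np.zeros((n_cls, n_cls), dtype=np.int64)
    all_scores: list = []
    all_true: list = []
    folds = []
    for subject in subjects:
        train = [r for r in records if r.subject_id != subject]
        test = [r for r in records if r.subject_id == subject]
        train_labels = [get_label(r) for r in train]
        if len(set(train_labels)) < 2:
            warnings.warn(f"fold {subject!r}: fewer than 2 training classes; skipped", stacklevel=2)
            continue
        X_train, pipe = prepare_features(train, variance)
        bundle = train_au_classifier(X_train, train_labels, C=C, sigma=sigma, pipeline=pipe)
        X_test = pipe.transform(np.vstack([r.alpha_e for r in test]))
        pred = bundle.predict(X_test)
        scores = bundle.decision_matrix(X_test)
        true = [get_label(r) for r in test]
        for t, p in zip(true, pred):
            if p in cls_index:
                confusion[cls_index[t], cls_index[p]] += 1
        # decision columns in this fold's class order -> re-index to global order
        fold_cols = {c: j for j, c in enumerate(bundle.classes)}
        S = np.full((len(test), n_cls), -np.inf)
        for c, j in fold_cols.items():
            if c in cls_index:
                S[:, cls_index[c]] = scores[:, j]
        all_scores.append(S)
        all_true.extend(true)
        folds.append({
            "subject": subject,
            "n_test": len(test),
            "n_correct": int(sum(t == p for t, p in zip(true, pred))),
            "pipeline": pipe,
            "scaler_mean": pipe.scaler.mean_.copy(),
            "scaler_scale": pipe.scaler.scale_.copy(),
            "train_subjects": sorted({r.subject_id for r in train}),
        })

    scores = np.vstack(all_scores)
    true_arr = np.asarray(all_true, dtype=object)
    accuracy = float(np.trace(confusion) / max(confusion.sum(), 1))
    f1 = _f1_from_confusion(confusion)
    per_class_f1 = {c: float(f1[i]) for c, i in cls_index.items()}
    per_class_auc = {}
    for c, i in cls_index.items():
        y_bin = (true_arr == c).astype(int)
        col = scores[:, i]
        valid = np.isfinite(col)
        if y_bin[valid].min(initial=1) == y_bin[valid].max(initial=0) or valid.sum() == 0:
            per_class_auc[c] = float("nan")
        else:
            per_class_auc[c] = float(roc_auc_score(y_bin[valid], col[valid]))
    return EvaluationReport(classes, confusion, accuracy, per_class_f1, per_class_auc, folds)


# --------------------------------------------------------------------------
# prototypes and synthesis

def compute_au_prototype(records, au_label: str) -> np.ndarray:
    """AU-specific prototype: the mean ``alpha_e`` over matching records."""
    vecs = [r.alpha_e for r in records if r.au_label == au_label]
    if not vecs:
        raise ValueError(f"no records with AU label {au_label!r}")
    return np.mean(vecs, axis=0)


def synthesize_au(base: RegisteredShape, model, prototypes, combine: str = "mean") -> TriMesh:
    """Activate one or more AU prototypes on a registered neutral face.

    Multiple prototypes are averaged element-wise (the complementarity of AU
    components makes plain averaging sufficient for combinations), then
    applied as ``base + sum_j alpha_j^AU c_j``.  ``base`` may be the model
    mean, a fitted neutral, or any shape on the model topology.
    """
    if base.topology_id != model.topology_id:
        raise ValueError("base shape topology does not match the model")
    protos = np.atleast_2d(np.asarray(prototypes, dtype=np.float64))
    if protos.shape[1] != model.k:
        raise ValueError(f"prototype length {protos.shape[1]} != model k={model.k}")
    if combine != "mean":
        raise ValueError(f"unknown combination strategy {combine!r}")
    alpha = protos.mean(axis=0)
    deformed = fitting.apply_deformation(base, model.components, alpha)
    faces = model.template_faces if model.template_faces is not None else np.zeros((0, 3), dtype=np.int64)
    return delinearize(deformed, faces)
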