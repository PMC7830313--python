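"""Statistical shape models of the face: sparse locally-coherent and PCA bases.

A morphable model is a mean shape ``m`` plus ``k`` linear deformation fields
(the rows of ``components``); new faces are ``m + sum_j alpha_j * c_j``.  Two
bases are supported:

* ``kind="slc"`` — components learned by non-negative elastic-net sparse
  coding over per-coordinate displacement samples (:mod:`slcau.dictlearn`),
  yielding sparse, spatially localized deformation fields;
* ``kind="pca"`` — the classical global basis: top-k principal directions of
  the displacement matrix, rows orthonormal.

Each component j carries a positive weight ``mu_j`` (its average intensity:
the mean of its non-negative coordinate profile for SLC, the modelled
standard deviation for PCA) used to scale the ridge penalty during fitting so
that stronger components are allowed larger coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dictlearn
from .meshio import RegisteredShape

__all__ = ["TrainingSet", "MorphableModel", "compute_mean", "build_training_matrix"]

_EPS_WEIGHT = 1e-8
_ARCHIVE_VERSION = "slcau-model-1"


@dataclass
class TrainingSet:
    """A registered training corpus: shape vectors column-wise plus metadata.

    ``F`` is 3m x N; all columns share one template topology.
    """

    F: np.ndarray
    topology_id: str
    subject_ids: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (3m x N)")
        if self.F.shape[0] % 3 != 0:
            raise ValueError("row count of F must be divisible by 3")
        if self.F.shape[1] < 2:
            raise ValueError("a training set needs at least 2 scans")

    @classmethod
    def from_shapes(cls, shapes, subject_ids=None, labels=None) -> "TrainingSet":
        shapes = list(shapes)
        if not shapes:
            raise ValueError("no shapes given")
        topo = shapes[0].topology_id
        for s in shapes[1:]:
            shapes[0].require_same_topology(s)
        F = np.column_stack([s.vector for s in shapes])
        return cls(F, topo, list(subject_ids or []), list(labels or []))

    @property
    def n_scans(self) -> int:
        return self.F.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.F.shape[0] // 3


def compute_mean(training: TrainingSet | np.ndarray) -> np.ndarray:
    """Average 3D face: the column mean of the training matrix."""
    F = training.F if isinstance(training, TrainingSet) else np.asarray(training, dtype=np.float64)
    return F.mean(axis=1)


def build_training_matrix(training: TrainingSet | np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Displacement matrix V with columns v_i = f_i - m."""
    F = training.F if isinstance(training, TrainingSet) else np.asarray(training, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64).ravel()
    if mean.size != F.shape[0]:
        raise ValueError(f"mean length {mean.size} does not match 3m={F.shape[0]}")
    return F - mean[:, None]


def compute_component_weights(C: np.ndarray) -> np.ndarray:
    """Per-component average intensity: row means of C >= 0, floored at 1e-8."""
    C = np.asarray(C, dtype=np.float64)
    if C.min() < -1e-12:
        raise ValueError("component weights are defined for non-negative C")
    return np.maximum(C.mean(axis=1), _EPS_WEIGHT)


@dataclass
class MorphableModel:
    """Mean shape + linear deformation components + per-component weights.

    Build from a registered corpus with :meth:`from_training_set`, fit to a raw
    scan with :meth:`fit` (returns a :class:`slcau.fitting.FitResult`).
    """

    mean: np.ndarray
    components: np.ndarray       # k x 3m, rows are deformation fields
    weights: np.ndarray          # k positive
    kind: str
    topology_id: str
    hyperparams: dict = field(default_factory=dict)
    template_faces: np.ndarray | None = None
    objective_trace: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.components = np.asarray(self.components, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        k, n = self.components.shape
        if self.mean.size != n:
            raise ValueError("mean and components disagree on 3m")
        if self.weights.size != k:
            raise ValueError("weights and components disagree on k")
        if np.any(self.weights <= 0):
            raise ValueError("component weights must be strictly positive")
        if self.kind not in ("slc", "pca"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    # ------------------------------------------------------------------
    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    @property
    def model_id(self) -> str:
        h = self.hyperparams
        return f"{self.kind}-k{self.k}-seed{h.get('seed', 0)}-{self.topology_id}"

    @property
    def mean_shape(self) -> RegisteredShape:
        return RegisteredShape(self.mean.copy(), self.topology_id)

    # ------------------------------------------------------------------
    @classmethod
    def from_training_set(
        cls,
        training: TrainingSet,
        kind: str = "slc",
        k: int = 50,
        l1: float = 0.2,
        l2: float = 0.01,
        *,
        n_iter: int = 60,
        seed: int = 0,
        template_faces: np.ndarray | None = None,
    ) -> "MorphableModel":
        """Build an SLC or PCA model from a registered training set.

        For ``kind="slc"`` the displacement matrix is transposed so the 3m
        coordinate profiles become the samples, globally offset to be
        non-negative (the offset only affects training-side reconstruction,
        never fitting, and is recorded in ``hyperparams['data_offset']``).
        """
        mean = compute_mean(training)
        V = build_training_matrix(training, mean)
        if kind == "slc":
            Vp = V.T.copy()                       # N x 3m, coordinate samples column-wise
            offset = float(min(Vp.min(), 0.0))
            res = dictlearn.learn_components(Vp - offset, k, l1, l2, n_iter=n_iter, seed=seed)
            components = res.C                    # k x 3m, non-negative
            weights = compute_component_weights(components)
            hyper = {
                "k": k, "l1": l1, "l2": l2, "data_offset": offset,
                "n_iter": n_iter, "seed": seed,
            }
            return cls(mean, components, weights, "slc", training.topology_id,
                       hyper, template_faces, res.objective)
        if kind == "pca":
            model = build_pca_model(V, k, topology_id=training.topology_id, mean=mean)
            model.template_faces = template_faces
            model.hyperparams["seed"] = seed
            return model
        raise ValueError(f"unknown model kind {kind!r}")

    # ------------------------------------------------------------------
    def fit(self, target, base: RegisteredShape | None = None, options=None, **kwargs):
        """Fit the model to a raw target scan; see :func:`slcau.fitting.fit`."""
        from . import fitting

        return fitting.fit(self, target, base=base, options=options, **kwargs)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Write a single-file ``.npz`` archive with a version tag."""
        path = Path(path)
        meta = {
            "version": _ARCHIVE_VERSION,
            "kind": self.kind,
            "topology_id": self.topology_id,
            "hyperparams": self.hyperparams,
        }
        arrays = {
            "mean": self.mean,
            "components": self.components,
            "weights": self.weights,
            "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        }
        if self.template_faces is not None:
            arrays["template_faces"] = np.asarray(self.template_faces, dtype=np.int64)
        if self.objective_trace is not None:
            arrays["objective_trace"] = np.asarray(self.objective_trace)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MorphableModel":
        path = Path(path)
        try:
            with np.load(path) as data:
                arrays = {key: data[key] for key in data.files}
        except Exception as exc:  # noqa: BLE001 - zipfile/pickle errors vary
            raise ValueError(f"{path}: not a readable model archive: {exc}") from exc
        if "meta_json" not in arrays:
            raise ValueError(f"{path}: missing metadata; not a model archive")
        meta = json.loads(arrays["meta_json"].tobytes().decode())
        if meta.get("version") != _ARCHIVE_VERSION:
            raise ValueError(
                f"{path}: archive version {meta.get('version')!r} != {_ARCHIVE_VERSION!r}"
            )
        return cls(
            arrays["mean"],
            arrays["components"],
            arrays["weights"],
            meta["kind"],
            meta["topology_id"],
            meta["hyperparams"],
            arrays.get("template_faces"),
            arrays.get("objective_trace"),
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        h = self.hyperparams
        lines = [
            f"MorphableModel(kind={self.kind}, k={self.k}, vertices={self.n_vertices})",
            f"  topology: {self.topology_id}",
            f"  weights mu: min={self.weights.min():.4g} max={self.weights.max():.4g}",
        ]
        if self.kind == "slc":
            frac = float(np.mean(self.components < 1e-6))
            lines.append(f"  l1={h.get('l1')}, l2={h.get('l2')}, sparsity={frac:.1%} near-zero entries")
            if self.objective_trace is not None and len(self.objective_trace):
                lines.append(
                    f"  training objective: {self.objective_trace[0]:.4g} -> {self.objective_trace[-1]:.4g}"
                    f" over {len(self.objective_trace)} iterations"
                )
        return "\n".join(lines)


def build_pca_model(
    V: np.ndarray, k: int, topology_id: str = "pca", mean: np.ndarray | None = None
) -> MorphableModel:
    """Classical PCA shape basis from a 3m x N displacement matrix.

    Components are the top-k right-singular directions of V^T (orthonormal
    rows, decreasing singular value); weights are the modelled standard
    deviations sigma_j / sqrt(N - 1), floored at 1e-8.
    """
    V = np.asarray(V, dtype=np.float64)
    N = V.shape[1]
    if k > N - 1:
        raise ValueError(f"PCA supports at most N-1={N - 1} components, requested {k}")
    # economy SVD of V (3m x N): right-singular vectors of V^T are U's columns
    U, s, _ = np.linalg.svd(V, full_matrices=False)
    components = U[:, :k].T
    weights = np.maximum(s[:k] / np.sqrt(N - 1), _EPS_WEIGHT)
    if mean is None:
        mean = np.zeros(V.shape[0])
    return MorphableModel(mean, components, weights, "pca", topology_id, {"k": k})
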