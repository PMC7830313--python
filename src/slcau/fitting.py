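"""Dense fitting of a morphable model to a raw 3D scan.

After a preliminary rigid ICP alignment, the fit iterates four steps until the
per-vertex error stabilizes:

1. correspondence — each model vertex finds its nearest target vertex;
2. similarity estimation — a closed-form least-squares 3x3 matrix P (rotation
   + scale) and translation T between model and corresponded target, factored
   into rotation and scale by QR;
3. realignment — the corresponded (and full) target is mapped back onto the
   model frame with the recovered transform;
4. deformation — ridge-regularized closed-form coefficients
   ``alpha = (C^T C + lam * diag(1/mu))^{-1} C^T X`` over the residual
   ``X = t_c - S``, applied as ``S <- S + sum_j alpha_j c_j``.

Conventions are row-vector throughout: points are (m, 3) rows, transforms act
as ``x @ P + T``.  Every step is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .meshio import RegisteredShape, TriMesh

__all__ = [
    "RigidTransform",
    "FitOptions",
    "FitResult",
    "icp_align",
    "correspond",
    "estimate_similarity",
    "solve_coefficients",
    "apply_deformation",
    "per_vertex_error",
    "fit",
]


@dataclass
class RigidTransform:
    """A similarity transform in row-vector convention: ``x @ P + T``.

    ``P = R @ Sc`` with R a proper rotation (det = +1) and Sc upper-triangular
    with positive diagonal (scale, possibly with shear), from the QR
    factorization of P with signs fixed.
    """

    P: np.ndarray
    T: np.ndarray
    R: np.ndarray = None
    Sc: np.ndarray = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=np.float64).reshape(3)
        if self.R is None or self.Sc is None:
            self.R, self.Sc = _qr_factor(self.P)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, T: np.ndarray) -> "RigidTransform":
        return cls(np.asarray(R, dtype=np.float64), T)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.P + self.T

    def apply_factored(self, points: np.ndarray) -> np.ndarray:
        """Apply as ``((x @ R) @ Sc) + T`` — identical to :meth:`apply`."""
        return (np.asarray(points, dtype=np.float64) @ self.R) @ self.Sc + self.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``self`` then ``other``."""
        return RigidTransform(self.P @ other.P, self.T @ other.P + other.T)


def _qr_factor(P: np.ndarray):
    """QR of P with column signs fixed so diag(Sc) > 0 and R is a rotation."""
    if np.linalg.det(P) <= 0:
        raise ValueError("transform matrix is singular or reflecting (det <= 0)")
    Q, U = np.linalg.qr(P)
    signs = np.sign(np.diag(U))
    signs[signs == 0] = 1.0
    Q = Q * signs[None, :]
    U = U * signs[:, None]
    return Q, U


def _rank_check(points: np.ndarray, min_rank: int = 2, what: str = "point set"):
    pts = np.asarray(points, dtype=np.float64)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < min_rank:
        raise ValueError(f"degenerate {what}: needs at least {min_rank + 1} non-collinear points")


def _kabsch(source: np.ndarray, target: np.ndarray):
    """Best rigid (rotation + translation, unit scale) mapping source -> target."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (source - mu_s).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    # row-vector convention: x @ R
    R = (U @ D @ Vt)
    T = mu_t - mu_s @ R
    return R, T


def _nearest(points: np.ndarray, targets: np.ndarray):
    """Nearest target index per point; lowest-index tie-break for small sets."""
    if points.shape[0] * targets.shape[0] <= 2_000_000:
        d2 = np.sum((points[:, None, :] - targets[None, :, :]) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        dist = np.sqrt(d2[np.arange(len(points)), idx])
        return dist, idx
    dist, idx = cKDTree(targets).query(points)
    return dist, idx


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, TriMesh):
        return obj.vertices
    if isinstance(obj, RegisteredShape):
        return obj.points
    pts = np.asarray(obj, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point set, got shape {pts.shape}")
    return pts


# --------------------------------------------------------------------------

def icp_align(
    source, target, init: RigidTransform | None = None, *, max_iter: int = 50, tol: float = 1e-6
) -> RigidTransform:
    """Rigid ICP: the transform mapping ``source`` onto ``target``.

    Alternates nearest-neighbour matching and closed-form rigid estimation
    until the relative error improvement drops below ``tol`` (default 1e-6) or
    ``max_iter`` (default 50) iterations.  Deterministic.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("ICP requires non-empty point sets")
    _rank_check(src, what="ICP source")
    _rank_check(tgt, what="ICP target")
    transform = init if init is not None else RigidTransform.identity()
    tree = cKDTree(tgt)
    prev_err = np.inf
    for _ in range(max_iter):
        moved = transform.apply(src)
        dist, idx = tree.query(moved)
        err = float(dist.mean())
        if prev_err - err < tol * max(prev_err, 1e-30):
            break
        prev_err = err
        R, T = _kabsch(src, tgt[idx])
        transform = RigidTransform.from_rotation_translation(R, T)
    return transform


def correspond(S: RegisteredShape | np.ndarray, target) -> np.ndarray:
    """Per model vertex, the nearest target vertex (many-to-one allowed).

    Ties are broken by the lowest target index.  Returns an (m, 3) array.
    """
    model_pts = _as_points(S)
    tgt = _as_points(target)
    if tgt.shape[0] == 0:
        raise ValueError("empty target")
    _, idx = _nearest(model_pts, tgt)
    return tgt[idx]


def estimate_similarity(S, t_c) -> RigidTransform:
    """Closed-form similarity (P, T) mapping corresponded target onto the model.

    Solves ``min_P ||(S - mean) - (t_c - mean) P||^2`` in least squares; the
    translation is the centroid residual ``T = mean(S) - mean(t_c) P``.  The
    QR factorization of P (signs fixed for positive scale diagonal) gives the
    rotation and scale factors; applying ``(t_c @ R) @ Sc + T`` re-aligns the
    target onto S.
    """
    S_pts = _as_points(S)
    tc = _as_points(t_c)
    if S_pts.shape != tc.shape:
        raise ValueError("model and corresponded target must have equal shapes")
    if S_pts.shape[0] < 4:
        raise ValueError("similarity estimation needs at least 4 points")
    mu_s = S_pts.mean(axis=0)
    mu_t = tc.mean(axis=0)
    A = tc - mu_t
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise ValueError("rank-deficient corresponded target; similarity is underdetermined")
    P, *_ = np.linalg.lstsq(A, S_pts - mu_s, rcond=None)
    T = mu_s - mu_t @ P
    return RigidTransform(P, T)


def solve_coefficients(
    X: np.ndarray,
    components: np.ndarray,
    mu: np.ndarray,
    lam: float,
    penalty: str = "inverse",
) -> np.ndarray:
    """Closed-form ridge deformation coefficients.

    Solves ``(C^T C + lam * diag(w)) alpha = C^T X`` by a symmetric
    positive-definite solve, where ``components`` is the 3m x k matrix C of
    column deformation fields and ``w = 1/mu`` (default ``penalty="inverse"``,
    the quadratic ``lam * sum_j alpha_j^2 / mu_j``) or ``w = 1/mu^2``
    (``penalty="squared"``).  Stronger components (larger average intensity
    mu_j) are penalized less and so absorb more of the residual.
    """
    X = np.asarray(X, dtype=np.float64).ravel()
    Cmat = np.asarray(components, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64).ravel()
    if lam <= 0:
        raise ValueError("regularization lambda must be > 0")
    if np.any(mu <= 0):
        raise ValueError("component weights mu must be strictly positive")
    if Cmat.shape[0] != X.size or Cmat.shape[1] != mu.size:
        raise ValueError("dimension mismatch between X, components and mu")
    if penalty == "inverse":
        w = 1.0 / mu
    elif penalty == "squared":
        w = 1.0 / mu**2
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    A = Cmat.T @ Cmat + lam * np.diag(w)
    b = Cmat.T @ X
    return scipy.linalg.solve(A, b, assume_a="pos")


def apply_deformation(base, components: np.ndarray, alpha: np.ndarray):
    """``base + sum_j alpha_j * component_row_j``; preserves the input type."""
    alpha = np.asarray(alpha, dtype=np.float64).ravel()
    comp = np.asarray(components, dtype=np.float64)
    if comp.shape[0] != alpha.size:
        raise ValueError("alpha length does not match component count")
    delta = alpha @ comp
    if isinstance(base, RegisteredShape):
        return RegisteredShape(base.vector + delta, base.topology_id)
    return np.asarray(base, dtype=np.float64).ravel() + delta


def per_vertex_error(S, target) -> float:
    """Mean distance (mm) from each model vertex to its nearest target vertex."""
    model_pts = _as_points(S)
    tgt = _as_points(target)
    if tgt.shape[0] == 0:
        raise ValueError("empty target")
    dist, _ = _nearest(model_pts, tgt)
    return float(dist.mean())


# --------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Tunables of the iterative fit.

    lam : ridge regularization weight (default 0.05);
    tau_e : stopping threshold on the per-vertex error change, mm (1e-3);
    max_iter : iteration cap (30);
    icp : run the preliminary rigid ICP alignment (True);
    penalty : ``"inverse"`` (default) or ``"squared"`` mu weighting;
    aggregate : strategy for the summary coefficient vector ("mean");
    sim_trim : fraction of best-matching correspondences used to estimate the
        per-iteration similarity (1.0 = all).  The default 0.8 makes the
        rigid/scale estimate robust to the very deformation being fitted —
        otherwise a one-sided deformation's nonzero mean is absorbed as a
        spurious translation that later leaks into the coefficients.
    """

    lam: float = 0.05
    tau_e: float = 1e-3
    max_iter: int = 30
    icp: bool = True
    penalty: str = "inverse"
    aggregate: str = "mean"
    sim_trim: float = 0.8


@dataclass
class FitResult:
    """Outcome of fitting a model to one target scan.

    ``alphas`` holds the per-iteration coefficient increments; ``alpha`` the
    aggregated summary vector; ``errors`` the per-iteration mean vertex error
    (mm).  ``deformed`` is the fitted shape on the template topology and
    ``aligned_target`` the target points mapped into the model frame.
    """

    deformed: RegisteredShape
    transform: RigidTransform
    alphas: list
    alpha: np.ndarray
    errors: list
    iterations: int
    converged: bool
    aligned_target: np.ndarray = None
    base: RegisteredShape = None

    @property
    def final_error(self) -> float:
        return self.errors[-1]

    @property
    def total_alpha(self) -> np.ndarray:
        return np.sum(self.alphas, axis=0)

    @property
    def displacement(self) -> np.ndarray:
        """Fitted deformation field relative to the base shape (length 3m)."""
        return self.deformed.vector - self.base.vector

    def map_to_target_frame(self, points: np.ndarray) -> np.ndarray:
        """Map model-frame points back into the raw target's original frame."""
        return (np.asarray(points, dtype=np.float64) - self.transform.T) @ np.linalg.inv(self.transform.P)

    @property
    def deformed_target_frame(self) -> RegisteredShape:
        """The fitted shape expressed in the raw target's original frame."""
        return RegisteredShape(
            self.map_to_target_frame(self.deformed.points).reshape(-1), self.deformed.topology_id
        )

    def summary(self) -> str:
        lines = [
            f"FitResult: {self.iterations} iterations, "
            f"{'converged' if self.converged else 'max_iter reached'}",
            f"  mean vertex error: {self.errors[0]:.4f} -> {self.final_error:.4f} mm",
            f"  |alpha| (aggregated): {np.linalg.norm(self.alpha):.4g}",
            f"  scale diag: {np.diag(self.transform.Sc)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "errors_mm": [float(e) for e in self.errors],
            "alpha": [float(a) for a in self.alpha],
            "alphas": [[float(a) for a in v] for v in self.alphas],
            "transform": {
                "P": self.transform.P.tolist(),
                "T": self.transform.T.tolist(),
            },
        }

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(1, len(self.errors) + 1), self.errors, marker="o")
        ax.set_xlabel("iteration")
        ax.set_ylabel("mean vertex error (mm)")
        return ax


def fit(model, target, base: RegisteredShape | None = None, options: FitOptions | None = None, **kwargs) -> FitResult:
    """Iteratively fit ``model`` to a raw ``target`` scan.

    ``base`` defaults to the model mean; supplying a fitted neutral shape
    instead restricts the recovered coefficients to expression-like motion.
    Stops when the per-vertex error, or its change between iterations, falls
    under ``tau_e``, or at ``max_iter``.
    """
    from .au import aggregate_coefficients

    opts = options or FitOptions(**kwargs)
    if options is not None and kwargs:
        raise TypeError("pass either a FitOptions or keyword overrides, not both")
    if opts.max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    base_shape = base if base is not None else model.mean_shape
    if base_shape.topology_id != model.topology_id:
        raise ValueError("base shape topology does not match the model")
    comp_T = model.components.T  # 3m x k

    target_pts = _as_points(target)
    overall = RigidTransform.identity()
    if opts.icp:
        overall = icp_align(target_pts, base_shape.points)
        target_pts = overall.apply(target_pts)

    S = RegisteredShape(base_shape.vector.copy(), base_shape.topology_id)
    alphas: list = []
    errors: list = []
    converged = False
    best = None  # (error, iteration index, S vector, target points, transform)
    rising = 0
    for _ in range(opts.max_iter):
        t_c = correspond(S, target_pts)
        if opts.sim_trim < 1.0:
            resid = np.linalg.norm(t_c - S.points, axis=1)
            keep = np.argsort(resid)[: max(4, int(opts.sim_trim * resid.size))]
            sim = estimate_similarity(S.points[keep], t_c[keep])
        else:
            sim = estimate_similarity(S.points, t_c)
        t_c = sim.apply(t_c)
        target_pts = sim.apply(target_pts)
        overall = overall.compose(sim)
        X = (t_c - S.points).reshape(-1)
        alpha_t = solve_coefficients(X, comp_T, model.weights, opts.lam, opts.penalty)
        S = apply_deformation(S, model.components, alpha_t)
        err = per_vertex_error(S, target_pts)
        alphas.append(alpha_t)
        errors.append(err)
        if best is None or err < best[0]:
            best = (err, len(alphas), S.vector.copy(), target_pts.copy(), overall)
        if err < opts.tau_e or (len(errors) > 1 and abs(errors[-2] - err) < opts.tau_e):
            converged = True
            break
        # divergence guard: a persistently rising error means the similarity
        # and deformation updates are feeding each other; keep the best state
        rising = rising + 1 if len(errors) > 1 and err > errors[-2] else 0
        if rising >= 3:
            break

    _, n_keep, S_vec, target_pts, overall = best
    S = RegisteredShape(S_vec, base_shape.topology_id)
    alphas = alphas[:n_keep]
    errors = errors[:n_keep]
    return FitResult(
        deformed=S,
        transform=overall,
        alphas=alphas,
        alpha=aggregate_coefficients(alphas, opts.aggregate),
        errors=errors,
        iterations=len(alphas),
        converged=converged,
        aligned_target=target_pts,
        base=base_shape,
    )
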