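"""Non-negative elastic-net dictionary learning over per-coordinate displacements.

The sparse locally-coherent model treats each of the 3m vertex coordinates as
an independent training sample: the sample is the N-vector of displacements
that coordinate undergoes across the N training scans.  Stacking them gives
V' = V^T in R^{N x 3m}, and the decomposition problem is

    min_{D, C}  (1/3m) * sum_i ( ||v'_i - D c_i||^2 + l1*||c_i||_1 + l2*||c_i||^2 )
    s.t.  D >= 0,  C >= 0,  ||d_j|| <= 1,

an elastic-net sparse coding with positivity.  The l1 term drives sparsity,
the l2 term the grouping effect (correlated coordinates — vertices moving
coherently under one muscle — receive similar coefficients), and positivity
promotes complementary, part-like atoms.  Together they yield deformation
fields that are sparse and spatially localized.

Solver: block-coordinate alternating minimization —

* C-step: cyclic coordinate descent on each code with the non-negative
  soft-threshold update, vectorized across all 3m samples;
* D-step: projected gradient with a 1/L step (L from the spectral norm of
  C C^T), projecting onto {D >= 0, ||d_j|| <= 1}.

Both steps are monotone, so the objective trace is non-increasing; this is
asserted on every run (tolerance 1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DictLearnResult", "learn_components", "elastic_net_objective"]


@dataclass
class DictLearnResult:
    """Learned dictionary ``D`` (N x k), codes ``C`` (k x n) and objective trace."""

    D: np.ndarray
    C: np.ndarray
    objective: np.ndarray

    @property
    def n_iter(self) -> int:
        return len(self.objective)


def elastic_net_objective(Vp: np.ndarray, D: np.ndarray, C: np.ndarray, l1: float, l2: float) -> float:
    """Mean per-sample elastic-net reconstruction objective."""
    n = Vp.shape[1]
    resid = Vp - D @ C
    return float((np.sum(resid * resid) + l1 * np.sum(np.abs(C)) + l2 * np.sum(C * C)) / n)


def _update_codes(Vp, D, C, l1, l2, sweeps):
    """Cyclic non-negative coordinate descent on all codes jointly (C >= 0)."""
    G = D.T @ D                 # k x k
    B = D.T @ Vp                # k x n
    diag = np.diag(G).copy()
    for _ in range(sweeps):
        for j in range(C.shape[0]):
            denom = diag[j] + l2
            if denom < 1e-12:
                C[j, :] = 0.0
                continue
            # partial residual correlation for atom j, all samples at once
            rho = B[j] - G[j] @ C + diag[j] * C[j]
            C[j, :] = np.maximum(0.0, (rho - l1 / 2.0) / denom)
    return C


def _project_dictionary(D):
    """Euclidean projection onto {D >= 0, column norms <= 1} (clip then scale)."""
    D = np.maximum(D, 0.0)
    norms = np.linalg.norm(D, axis=0)
    over = norms > 1.0
    if np.any(over):
        D[:, over] /= norms[over]
    return D

def _update_dictionary(Vp, D, C, steps=2):
    """Projected-gradient dictionary update with a 1/L stepsize (monotone)."""
    CCt = C @ C.T
    L = 2.0 * max(np.linalg.norm(CCt, 2), 1e-12)
    VCt = Vp @ C.T
    for _ in range(steps):
        grad = 2.0 * (D @ CCt - VCt)
        D = _project_dictionary(D - grad / L)
    return D


def learn_components(
    Vp: np.ndarray,
    k: int,
    l1: float,
    l2: float,
    *,
    n_iter: int = 60,
    code_sweeps: int = 3,
    seed: int = 0,
    tol: float = 0.0,
) -> DictLearnResult:
    """Learn ``k`` non-negative atoms and sparse non-negative codes for ``Vp``.

    Parameters
    ----------
    Vp : (N, n) array
        Training samples column-wise (for shape models, ``n = 3m`` coordinate
        displacement samples of dimension ``N`` scans).  Must be >= 0; callers
        handle signed data by recording a global offset.
    k : int
        Number of atoms; must satisfy ``k < min(N, n)``.
    l1, l2 : float
        Elastic-net penalties (>= 0).
    n_iter : int
        Outer alternating iterations.
    seed : int
        Initializes the dictionary from ``k`` distinct training samples.
    tol : float
        Early stop when the relative objective decrease falls below ``tol``.

    Returns
    -------
    DictLearnResult
        With ``D >= 0`` (columns at unit norm or less), ``C >= 0`` and the
        non-increasing per-iteration objective trace.
    """
    Vp = np.asarray(Vp, dtype=np.float64)
    if Vp.ndim != 2:
        raise ValueError("Vp must be a 2-D array of samples column-wise")
    N, n = Vp.shape
    if not k < min(N, n):
        raise ValueError(f"k={k} must be < min(N={N}, n_samples={n})")
    if l1 < 0 or l2 < 0:
        raise ValueError("elastic-net penalties must be non-negative")
    if Vp.min() < -1e-12:
        raise ValueError("Vp must be non-negative (apply a data offset first)")

    rng = np.random.default_rng(seed)
    cols = rng.choice(n, size=k, replace=False)
    D = Vp[:, cols].copy()
    # avoid dead all-zero atoms at init
    dead = np.linalg.norm(D, axis=0) < 1e-12
    if np.any(dead):
        D[:, dead] = rng.random((N, int(dead.sum())))
    D = _project_dictionary(D)
    C = np.zeros((k, n))

    trace = []
    prev = np.inf
    for _ in range(n_iter):
        C = _update_codes(Vp, D, C, l1, l2, code_sweeps)
        D = _update_dictionary(Vp, D, C)
        obj = elastic_net_objective(Vp, D, C, l1, l2)
        if obj > prev + 1e-9:
            raise RuntimeError(
                f"objective increased ({prev:.6e} -> {obj:.6e}); solver invariant violated"
            )
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, 1e-30):
            prev = obj
            break
        prev = obj
    return DictLearnResult(D=D, C=C, objective=np.asarray(trace))
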