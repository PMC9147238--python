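"""PARAFAC (parallel factor analysis) by alternating least squares.

Decomposes a 3-way dose x time x wavenumber tensor X into R trilinear
components,

    X[d, t, w]  ~  sum_r  C[d, r] * B[t, r] * A[w, r]

with A the spectral loadings, B the time loadings and C the dose scores.
The scale indeterminacy is resolved by normalizing each column of A and B
to unit Euclidean norm, so all magnitude is carried by C; the sign
indeterminacy is resolved by orienting each time loading forward in time
(final element >= first) and each dose-score column upward (final element
>= first), compensating in the remaining factor so the reconstruction is
unchanged.  For the monotone hydrolysis signals this assay produces, the
dose scores therefore trend nonnegative.

The assay of interest uses a single component (R = 1); the implementation
is generic in R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParafacModel", "parafac_als", "dose_scores", "explained_variation"]


@dataclass
class ParafacModel:
    """Fitted PARAFAC factors and diagnostics.

    spectral_loadings: (wavenumber x R), unit-norm columns (Matrix A).
    time_loadings:     (time x R), unit-norm columns (Matrix B).
    dose_scores:       (dose x R), carries all magnitude (Matrix C).
    """

    spectral_loadings: np.ndarray
    time_loadings: np.ndarray
    dose_scores: np.ndarray
    n_iterations: int
    converged: bool
    residual_ss: float
    total_ss: float
    explained_fraction: float
    residual_history: tuple[float, ...]

    @property
    def n_components(self) -> int:
        return self.dose_scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "dr,tr,wr->dtw",
            self.dose_scores,
            self.time_loadings,
            self.spectral_loadings,
        )


def _as_array(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    # Row index (i, j) -> i * V.shape[0] + j, matching C-order unfoldings.
    r = U.shape[1]
    return (U[:, None, :] * V[None, :, :]).reshape(-1, r)


def _init_factors(T, n_components, init, seed):
    factors = []
    if init == "svd":
        for mode in range(3):
            unf = _unfold(T, mode)
            u, _, _ = np.linalg.svd(unf, full_matrices=False)
            factors.append(u[:, :n_components].copy())
    elif init == "random":
        rng = np.random.default_rng(seed)
        factors = [
            rng.standard_normal((T.shape[mode], n_components)) for mode in range(3)
        ]
    else:
        raise ValueError(f"unknown init {init!r}; expected 'svd' or 'random'")
    return factors


def parafac_als(
    X,
    n_components: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: str = "svd",
    seed: int = 0,
) -> ParafacModel:
    """Fit an R-component PARAFAC model by alternating least squares.

    Accepts a DoseSeriesTensor or a plain 3-way array.  The objective
    (residual sum of squares) is non-increasing across iterations;
    convergence is declared when its relative change drops below ``tol``.
    """
    T = _as_array(X)
    if T.ndim != 3:
        raise ValueError("PARAFAC input must be a 3-way tensor")
    if not np.all(np.isfinite(T)):
        raise ValueError("tensor contains non-finite entries")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if any(s < n_components for s in T.shape):
        raise ValueError("every tensor dimension must be >= n_components")
    if not tol > 0:
        raise ValueError("tol must be > 0")

    total_ss = float(np.sum(T * T))
    if total_ss == 0.0:
        raise ValueError("zero tensor")

    factors = _init_factors(T, n_components, init, seed)
    unfolds = [_unfold(T, mode) for mode in range(3)]

    history: list[float] = []
    prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            # C-order unfolding pairs mode m with (others in increasing mode
            # order), the first varying slowest.
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            factors[mode] = (unfolds[mode] @ kr) @ np.linalg.pinv(gram)
        rec = np.einsum("dr,tr,wr->dtw", factors[0], factors[1], factors[2])
        residual = float(np.sum((T - rec) ** 2))
        history.append(residual)
        if prev < np.inf:
            denom = max(prev, np.finfo(float).tiny)
            if abs(prev - residual) / denom < tol:
                converged = True
                break
        prev = residual

    C, B, A = factors  # modes: dose, time, wavenumber
    C, B, A = _normalize_and_orient(C, B, A)

    residual_ss = history[-1]
    return ParafacModel(
        spectral_loadings=A,
        time_loadings=B,
        dose_scores=C,
        n_iterations=n_iter,
        converged=converged,
        residual_ss=residual_ss,
        total_ss=total_ss,
        explained_fraction=1.0 - residual_ss / total_ss,
        residual_history=tuple(history),
    )


def _normalize_and_orient(C, B, A):
    C = C.copy()
    B = B.copy()
    A = A.copy()
    for r in range(C.shape[1]):
        na = np.linalg.norm(A[:, r])
        nb = np.linalg.norm(B[:, r])
        if na > 0:
            A[:, r] /= na
        if nb > 0:
            B[:, r] /= nb
        C[:, r] *= na * nb
        # Reaction progresses forward: flip B (and compensate in C).
        if B[-1, r] < B[0, r]:
            B[:, r] = -B[:, r]
            C[:, r] = -C[:, r]
        # Dose scores trend upward: flip A (and compensate in C).
        if C[-1, r] < C[0, r]:
            A[:, r] = -A[:, r]
            C[:, r] = -C[:, r]
    return C, B, A


def dose_scores(model: ParafacModel, component: int = 1) -> np.ndarray:
    """Dose-mode score vector of a component (1-based index)."""
    if not 1 <= component <= model.n_components:
        raise IndexError(
            f"component {component} out of range 1..{model.n_components}"
        )
    return model.dose_scores[:, component - 1].copy()


def explained_variation(model: ParafacModel, X) -> float:
    """Fraction of the tensor's sum of squares captured by the model.

    Recomputed from scratch against ``X`` (1 - SS_res / SS_tot).
    """
    T = _as_array(X)
    rec = model.reconstruct()
    if rec.shape != T.shape:
        raise ValueError(f"shape mismatch: model {rec.shape} vs tensor {T.shape}")
    total = float(np.sum(T * T))
    if total == 0.0:
        raise ValueError("zero tensor")
    return 1.0 - float(np.sum((T - rec) ** 2)) / total
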