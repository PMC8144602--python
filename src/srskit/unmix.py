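"""Pixel-wise LASSO spectral unmixing of hyperspectral stacks.

The bilinear mixing model writes the flattened stack as ``D = C S + E`` where
``D`` is the (Nx*Ny, n_channels) data matrix with pixels in raster order,
``S`` holds the K intensity-normalized pure-component reference spectra, and
``C`` the per-pixel concentrations.  Plain least squares produces chemical
maps with heavy crosstalk when reference spectra overlap, so each pixel is
solved with an L1 penalty (sparsity: only a few chemicals dominate any one
location):

    C_i = argmin_c  1/2 ||D(i,:) - c S||^2 + beta ||c||_1

Each pixel's problem is independent; the solver runs cyclic coordinate
descent with soft-thresholding, vectorized across all pixels at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import HyperspectralStack, ReferenceLibrary

__all__ = [
    "UnmixConfig",
    "ConcentrationMaps",
    "stack_to_matrix",
    "matrix_to_stack",
    "lasso_objective",
    "lasso_solve",
    "lasso_solve_pixel",
    "unmix_stack",
    "tune_beta",
]


@dataclass(frozen=True)
class UnmixConfig:
    """Solver settings for the per-pixel L1-penalized fit.

    ``beta`` weighs the L1 term on the raw intensity scale of the data:
    normalize stacks before unmixing, or retune beta, when intensity units
    change.  ``nonnegative=True`` clamps coefficients at zero (physical
    concentrations); the plain objective leaves them unconstrained.
    """

    beta: float = 0.0
    nonnegative: bool = False
    max_iter: int = 1000
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class ConcentrationMaps:
    """Per-pixel component abundances plus the per-pixel residual norm."""

    maps: np.ndarray  # (Ny, Nx, K)
    names: tuple[str, ...]
    residual_norm: np.ndarray  # (Ny, Nx), ||E(i,:)||_2 per pixel
    converged: bool = True

    def component(self, name: str) -> np.ndarray:
        return self.maps[..., self.names.index(name)]


def stack_to_matrix(stack: HyperspectralStack) -> np.ndarray:
    """Flatten a (lambda, y, x) stack to the (Ny*Nx, n_channels) data matrix.

    Row ``i`` is the spectrum of pixel ``i`` in row-major raster order:
    pixel (y, x) maps to row ``y * Nx + x``.
    """
    nl, ny, nx = stack.shape
    return np.ascontiguousarray(
        stack.data.reshape(nl, ny * nx).T.astype(np.float64)
    )


def matrix_to_stack(matrix: np.ndarray, stack_like: HyperspectralStack) -> HyperspectralStack:
    """Inverse of :func:`stack_to_matrix`, restoring (lambda, y, x) order."""
    nl, ny, nx = stack_like.shape
    if matrix.shape != (ny * nx, nl):
        raise ValueError("matrix shape does not match the template stack")
    return HyperspectralStack(
        data=matrix.T.reshape(nl, ny, nx), axis=stack_like.axis
    )


def lasso_objective(C: np.ndarray, D: np.ndarray, S: np.ndarray, beta: float) -> float:
    """Total objective 1/2 ||D - C S||_F^2 + beta * sum |C| over all pixels."""
    resid = D - C @ S
    return 0.5 * float(np.sum(resid**2)) + beta * float(np.sum(np.abs(C)))


def _soft_threshold(rho: np.ndarray, beta: float, nonnegative: bool) -> np.ndarray:
    if nonnegative:
        return np.maximum(rho - beta, 0.0)
    return np.sign(rho) * np.maximum(np.abs(rho) - beta, 0.0)


def lasso_solve(
    D: np.ndarray,
    S: np.ndarray,
    config: UnmixConfig,
    collect_objective: bool = False,
) -> tuple[np.ndarray, bool, list[float]]:
    """Cyclic coordinate descent on all pixels simultaneously.

    Returns ``(C, converged, objective_history)`` where ``C`` is (n_pixels, K).
    Convergence: the largest coefficient change in a full sweep falls below
    ``config.tolerance``.  The per-coordinate update is the exact minimizer
    of the one-dimensional subproblem (soft-thresholding), so the objective
    is non-increasing sweep over sweep.
    """
    D = np.atleast_2d(np.asarray(D, dtype=np.float64))
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(S))):
        raise ValueError("non-finite values in data or reference spectra")
    n_pixels, n_chan = D.shape
    k_comp, n_chan_s = S.shape
    if n_chan != n_chan_s:
        raise ValueError("data and reference spectra have different channel counts")
    norms = np.einsum("kl,kl->k", S, S)
    if np.any(norms == 0):
        raise ValueError("reference spectrum with zero norm")

    C = np.zeros((n_pixels, k_comp))
    R = D.copy()  # residual D - C S, maintained incrementally
    history: list[float] = []
    if collect_objective:
        history.append(lasso_objective(C, D, S, config.beta))
    converged = False
    for _ in range(config.max_iter):
        max_delta = 0.0
        for k in range(k_comp):
            rho = R @ S[k] + C[:, k] * norms[k]
            c_new = _soft_threshold(rho, config.beta, config.nonnegative) / norms[k]
            delta = C[:, k] - c_new
            nz = delta != 0.0
            if nz.any():
                R[nz] += np.outer(delta[nz], S[k])
                max_delta = max(max_delta, float(np.abs(delta).max()))
            C[:, k] = c_new
        if collect_objective:
            history.append(lasso_objective(C, D, S, config.beta))
        if max_delta < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {config.max_iter} sweeps",
            stacklevel=2,
        )
    return C, converged, history


def lasso_solve_pixel(
    d: np.ndarray, S: np.ndarray, config: UnmixConfig
) -> np.ndarray:
    """Solve the L1-penalized fit for a single pixel spectrum; returns (K,)."""
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 1:
        raise ValueError("pixel spectrum must be 1-D")
    C, _, _ = lasso_solve(d[None, :], S, config)
    return C[0]


def unmix_stack(
    stack: HyperspectralStack,
    library: ReferenceLibrary,
    config: UnmixConfig,
) -> ConcentrationMaps:
    """Unmix every pixel of a stack into component concentration maps.

    The stack's spectral axis must match the library's (no resampling is
    attempted).  Pixels are independent, so the result does not depend on
    processing order.
    """
    if len(stack.axis) != len(library.axis) or not np.allclose(
        stack.axis.wavenumbers, library.axis.wavenumbers
    ):
        raise ValueError("stack and library spectral axes differ; resample first")
    nl, ny, nx = stack.shape
    D = stack_to_matrix(stack)
    C, converged, _ = lasso_solve(D, library.spectra, config)
    resid = D - C @ library.spectra
    return ConcentrationMaps(
        maps=C.reshape(ny, nx, library.n_components),
        names=library.names,
        residual_norm=np.linalg.norm(resid, axis=1).reshape(ny, nx),
        converged=converged,
    )


def crosstalk_score(
    maps: ConcentrationMaps, pure_masks: dict[str, np.ndarray]
) -> float:
    """Mean off-component abundance inside regions known to be pure.

    For each component with a mask of pixels containing only that chemical,
    average the absolute abundance assigned to every *other* component there;
    the score is the mean over components.  Zero means no crosstalk.
    """
    scores = []
    for name, mask in pure_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"pure mask for {name!r} is empty")
        k = maps.names.index(name)
        others = [j for j in range(len(maps.names)) if j != k]
        if others:
            scores.append(float(np.abs(maps.maps[mask][:, others]).mean()))
    if not scores:
        raise ValueError("crosstalk score needs at least two components")
    return float(np.mean(scores))


def tune_beta(
    stack: HyperspectralStack,
    library: ReferenceLibrary,
    candidates: list[float],
    pure_masks: dict[str, np.ndarray],
    config: UnmixConfig | None = None,
) -> float:
    """Pick the candidate beta minimizing crosstalk in known-pure regions.

    Ties break toward the smaller beta (least shrinkage that already removes
    the crosstalk).  This is an explicit surrogate for the qualitative
    "suppress crosstalk while avoiding artifacts" tuning done by eye.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one beta candidate")
    base = config or UnmixConfig()
    best_beta, best_score = None, np.inf
    for beta in sorted(candidates):
        cfg = UnmixConfig(
            beta=beta, nonnegative=base.nonnegative,
            max_iter=base.max_iter, tolerance=base.tolerance,
        )
        score = crosstalk_score(unmix_stack(stack, library, cfg), pure_masks)
        if score < best_score - 1e-15:
            best_beta, best_score = beta, score
    return float(best_beta)
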