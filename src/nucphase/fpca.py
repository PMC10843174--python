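"""Functional principal component analysis of nucleosome profiles.

Each 1200-bp profile X(t), t in [-200, 1000) relative to the +1 dyad, is
treated as one realisation of a stochastic process with mean mu(t): the
profile is projected onto a small open-uniform B-spline basis (20 cubic
splines by default, which already imposes strong smoothing at nucleosome
length scales), and the centered functions are decomposed into orthonormal
eigenfunctions phi^k(t) that successively maximise the variance of the
projection Var(integral (X - mu) phi dt). Per-gene scores

    zeta_k = integral (X(t) - mu(t)) phi^k(t) dt

then describe each gene by how it deviates from the mean profile; two scores
suffice to interpret the correlation clusters downstream.

Numerics: the functional inner product is discretized on the 1-bp grid with
trapezoidal quadrature. The eigenproblem is solved in basis-coefficient
space: with Gram matrix M = B' W B and coefficient covariance V, the
symmetric problem M^(1/2) V M^(1/2) u = lambda u yields coefficients
b = M^(-1/2) u with <phi_j, phi_k> = delta_jk. Eigenfunction signs are fixed
so each score distribution has non-negative skew (purely cosmetic; all
downstream statistics are invariant to joint sign flips).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import eigh
from scipy.stats import skew

from nucphase.profile_io import WINDOW_LENGTH, UPSTREAM

GRID = np.arange(-UPSTREAM, WINDOW_LENGTH - UPSTREAM, dtype=float)


def trapezoid_weights(n: int = WINDOW_LENGTH, dt: float = 1.0) -> np.ndarray:
    """Quadrature weights of the composite trapezoid rule on a uniform grid."""
    w = np.full(n, dt)
    w[0] = w[-1] = dt / 2.0
    return w


@dataclass(frozen=True)
class BasisConfig:
    n_basis: int = 20
    basis_order: int = 4  # spline order; 4 = cubic
    smoothing_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.n_basis < self.basis_order:
            raise ValueError("n_basis must be >= basis_order")
        if self.smoothing_penalty < 0:
            raise ValueError("smoothing_penalty must be non-negative")

    def design_matrix(self, grid: np.ndarray = GRID) -> np.ndarray:
        """Evaluate the open-uniform (clamped) B-spline basis on the grid."""
        degree = self.basis_order - 1
        a, b = grid[0], grid[-1]
        n_interior = self.n_basis - degree - 1
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        knots = np.concatenate(
            [np.full(degree + 1, a), interior, np.full(degree + 1, b)]
        )
        return BSpline.design_matrix(grid, knots, degree, extrapolate=False).toarray()


@dataclass
class SmoothedProfiles:
    """Profiles represented as B-spline linear combinations."""

    coefficients: np.ndarray  # n_genes x n_basis
    basis_matrix: np.ndarray  # n_grid x n_basis
    grid: np.ndarray
    gene_ids: list[str]
    config: BasisConfig

    @property
    def values(self) -> np.ndarray:
        """Smoothed functions evaluated on the grid (n_genes x n_grid)."""
        return self.coefficients @ self.basis_matrix.T

    @property
    def n_genes(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class FunctionalModel:
    """Mean function, eigenfunctions, per-gene scores and explained variance."""

    grid: np.ndarray
    mean_function: np.ndarray        # n_grid
    components: np.ndarray           # K x n_grid, orthonormal under trapezoid IP
    scores: np.ndarray               # n_genes x K
    eigenvalues: np.ndarray          # K, non-increasing
    total_variance: float
    gene_ids: list[str]

    @property
    def K(self) -> int:
        return self.components.shape[0]

    @property
    def explained_variance(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def fit_functional_representation(
    profiles, basis: BasisConfig = BasisConfig()
) -> SmoothedProfiles:
    """Penalized least-squares fit of each profile onto the B-spline basis.

    With the default zero penalty this is a plain projection; a positive
    ``smoothing_penalty`` adds an L2 ridge on the coefficients.
    """
    X = profiles.values if hasattr(profiles, "values") else np.asarray(profiles, float)
    gene_ids = (
        list(profiles.gene_ids)
        if hasattr(profiles, "gene_ids")
        else [str(i) for i in range(X.shape[0])]
    )
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    B = basis.design_matrix(GRID)
    gram = B.T @ B
    if basis.smoothing_penalty > 0:
        gram = gram + basis.smoothing_penalty * np.eye(B.shape[1])
    coeffs = np.linalg.solve(gram, B.T @ X.T).T
    return SmoothedProfiles(
        coefficients=coeffs, basis_matrix=B, grid=GRID.copy(),
        gene_ids=gene_ids, config=basis,
    )


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Flip each eigenfunction (and its scores) so the score skew is >= 0."""
    for k in range(components.shape[0]):
        s = skew(scores[:, k])
        if s < 0 or (s == 0 and components[k][np.argmax(np.abs(components[k]))] < 0):
            components[k] *= -1.0
            scores[:, k] *= -1.0


def fpca_decompose(smoothed: SmoothedProfiles, K: int = 2) -> FunctionalModel:
    """Eigendecomposition of the empirical covariance operator.

    Returns the leading K orthonormal eigenfunctions, per-gene scores (exact
    quadrature of the projection integral) and eigenvalues; the explained
    variance ratio is eigenvalue / total functional variance.
    """
    n = smoothed.n_genes
    if n < K + 1:
        raise ValueError(f"need at least {K + 1} genes to extract {K} components")
    C = smoothed.coefficients
    mean_coeffs = C.mean(axis=0)
    centered = C - mean_coeffs
    B = smoothed.basis_matrix
    w = trapezoid_weights(B.shape[0])
    M = B.T @ (w[:, None] * B)  # basis Gram matrix under the grid inner product
    V = centered.T @ centered / (n - 1)
    evals_M, evecs_M = eigh(M)
    if evals_M.min() <= 0:
        raise np.linalg.LinAlgError("B-spline Gram matrix is singular")
    M_half = (evecs_M * np.sqrt(evals_M)) @ evecs_M.T
    M_half_inv = (evecs_M / np.sqrt(evals_M)) @ evecs_M.T
    lam, U = eigh(M_half @ V @ M_half)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    rank = int(np.sum(lam > max(lam[0], 1.0) * 1e-12))
    if K > rank:
        raise ValueError(f"K={K} exceeds the rank ({rank}) of the centered data")
    b = M_half_inv @ U[:, :K]              # basis coefficients of eigenfunctions
    components = (B @ b).T                 # K x n_grid
    scores = centered @ (M @ b)            # zeta_ik = <X_i - mu, phi_k>
    model = FunctionalModel(
        grid=smoothed.grid.copy(),
        mean_function=B @ mean_coeffs,
        components=components,
        scores=scores,
        eigenvalues=lam[:K],
        total_variance=float(np.trace(V @ M)),
        gene_ids=list(smoothed.gene_ids),
    )
    _fix_signs(model.components, model.scores)
    return model


def reconstruct(model: FunctionalModel, gene_index: int, K_prime: int | None = None) -> np.ndarray:
    """Truncated expansion mu + sum_{k<=K'} zeta_k phi_k for one gene."""
    if K_prime is None:
        K_prime = model.K
    if K_prime > model.K:
        raise ValueError(f"K'={K_prime} exceeds the model's {model.K} components")
    out = model.mean_function.copy()
    for k in range(K_prime):
        out += model.scores[gene_index, k] * model.components[k]
    return out


def effect_curves(
    model: FunctionalModel, component: int, scale: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, mean + scale*phi, mean - scale*phi) for the 1-based component.

    The default scale of 20 amplifies the eigenfunction to the upper end of
    the typical score range so its effect on the profile is visible.
    """
    if not 1 <= component <= model.K:
        raise ValueError(f"component must be in 1..{model.K}")
    phi = model.components[component - 1]
    mu = model.mean_function
    return mu.copy(), mu + scale * phi, mu - scale * phi


def subset_refit(
    profiles,
    subset_mask: np.ndarray,
    labels: np.ndarray,
    basis: BasisConfig = BasisConfig(),
    K: int = 2,
) -> tuple[FunctionalModel, np.ndarray]:
    """Refit the functional model on a gene subset, carrying labels over.

    The mean and eigenfunctions are recomputed from the subset only, while
    the (all-gene) cluster labels are restricted unmodified — this is how
    gene-size effects on separability are probed: if the subset's functional
    description no longer captures what distinguished the clusters, their
    separability in score space collapses.
    """
    subset_mask = np.asarray(subset_mask)
    if subset_mask.dtype != bool:
        mask = np.zeros(len(labels), dtype=bool)
        mask[subset_mask] = True
        subset_mask = mask
    if not subset_mask.any():
        raise ValueError("subset must be non-empty")
    labels = np.asarray(labels)
    if labels.size != subset_mask.size:
        raise ValueError("labels must cover the full profile set")
    sub = profiles.subset(subset_mask) if hasattr(profiles, "subset") else profiles.values[subset_mask]
    smoothed = fit_functional_representation(sub, basis)
    model = fpca_decompose(smoothed, K=K)
    return model, labels[subset_mask]
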