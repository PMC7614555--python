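"""Regularised partial-correlation network estimation with bootstrap
edge-stability significance.

Edges are partial correlations derived from the precision matrix
(ρᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ)); spurious edges are shrunk to exactly zero with the
graphical lasso, whose penalty is tuned by K-fold cross-validated held-out
Gaussian log-likelihood. Stability is assessed with a nonparametric
bootstrap over children: each edge's occurrence probability (fraction of
resamples in which it survives regularisation) is compared against a
chance-fraction threshold — the chosen percentile of the per-resample total
edge counts divided by the number of possible edges — and 95% percentile
confidence intervals of the weights (absent edges counted as zero) give a
second significance mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from .clustering import mds_embed
from .preprocess import ZMatrix

__all__ = [
    "NetworkEstimate",
    "BootstrapSummary",
    "SignificanceConfig",
    "correlation_to_partial",
    "sample_partial_correlations",
    "graphical_lasso",
    "estimate_network",
    "lambda_grid",
    "select_lambda_cv",
    "bootstrap_network",
    "occurrence_significance",
    "edge_confidence_intervals",
    "node_layout",
    "holm_correlations",
]

_ZERO_TOL = 1e-8  # |precision| below this is an exact structural zero


@dataclass
class NetworkEstimate:
    node_names: list[str]
    node_categories: list[str]
    weights: np.ndarray  # p x p partial correlations, zero diagonal
    regularization: float
    layout: np.ndarray | None = None


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    bonferroni: bool = False
    m_edges: int = 171  # p(p-1)/2 for p = 19

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def percentile(self) -> float:
        """Edge-count percentile defining the chance threshold."""
        a = self.alpha / self.m_edges if self.bonferroni else self.alpha
        return 100.0 * (1.0 - a)


@dataclass
class BootstrapSummary:
    n_iterations: int
    edge_probability: np.ndarray  # p x p occurrence fractions
    ci_low: np.ndarray
    ci_high: np.ndarray
    edge_counts: np.ndarray  # per-iteration total edges, length B
    seed: int
    lambda_mode: str
    n_redrawn: int = 0
    chance_count_uncorrected: float | None = None
    chance_count_bonferroni: float | None = None
    chance_fraction_uncorrected: float | None = None
    chance_fraction_bonferroni: float | None = None
    significant_uncorrected: np.ndarray | None = None
    significant_bonferroni: np.ndarray | None = None
    significant_ci: np.ndarray | None = None

    @property
    def m_edges(self) -> int:
        p = self.edge_probability.shape[0]
        return p * (p - 1) // 2


def _precision_to_partial(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    partial[np.abs(partial) < _ZERO_TOL] = 0.0
    return partial


def correlation_to_partial(corr: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a correlation matrix, via inversion."""
    try:
        omega = np.linalg.inv(np.asarray(corr, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; consider regularisation"
        ) from exc
    return _precision_to_partial(omega)


def sample_partial_correlations(z: ZMatrix | np.ndarray) -> np.ndarray:
    """Unregularised partial correlations from the inverse correlation matrix."""
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete data required")
    return correlation_to_partial(np.corrcoef(x, rowvar=False))


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 200,
    enet_tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalised precision estimate and the implied partial correlations.

    Maximises the Gaussian log-likelihood penalised by lam·Σ|Ωᵢⱼ| over
    off-diagonal precision entries (coordinate descent, duality-gap
    tolerance ``tol``). lam = 0 falls back to plain inversion. Precision
    entries with magnitude below 1e-8 are treated as exact zeros. At very
    small penalties the dual gap can stall near the solver's numerical
    floor; the stalled solution is returned rather than raising, since the
    remaining gap is far below the scale of any quantity reported.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        omega = np.linalg.inv(S)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, omega = _sk_graphical_lasso(
                    S, alpha=lam, tol=tol, max_iter=max_iter, enet_tol=enet_tol
                )
        except FloatingPointError as exc:
            raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    omega = np.where(np.abs(omega) < _ZERO_TOL, 0.0, omega)
    return omega, _precision_to_partial(omega)


def _gaussian_loglik(S_test: np.ndarray, precision: np.ndarray) -> float:
    """Average held-out Gaussian log-likelihood (up to a constant)."""
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ precision))


def lambda_grid(S: np.ndarray, n_points: int = 30) -> np.ndarray:
    """Log-spaced penalty grid from lam_max (largest off-diagonal |S|)
    down to lam_max/100."""
    off = np.abs(S[~np.eye(S.shape[0], dtype=bool)])
    lam_max = off.max()
    if lam_max <= 0:
        raise ValueError("degenerate grid: no off-diagonal correlation")
    return np.logspace(np.log10(lam_max), np.log10(lam_max / 100.0), n_points)


def select_lambda_cv(
    z: ZMatrix | np.ndarray,
    n_folds: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Pick the graphical-lasso penalty by K-fold cross-validation.

    Scores each grid value by the mean held-out Gaussian log-likelihood of
    the precision fitted on the training rows; returns the maximiser. Fold
    assignment is a seeded permutation, so the choice is reproducible.
    """
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    n, p = x.shape
    if n < n_folds:
        raise ValueError("need at least n_folds rows")
    if grid is None:
        grid = lambda_grid(np.corrcoef(x, rowvar=False))
    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n) % n_folds)
    scores = np.zeros(len(grid))
    for f in range(n_folds):
        train, test = x[fold_of != f], x[fold_of == f]
        S_train = np.corrcoef(train, rowvar=False)
        xt = (test - train.mean(axis=0)) / train.std(axis=0, ddof=1)
        S_test = xt.T @ xt / xt.shape[0]
        for g, lam in enumerate(grid):
            try:
                omega, _ = graphical_lasso(S_train, lam)
            except (RuntimeError, np.linalg.LinAlgError):
                scores[g] += -np.inf
                continue
            scores[g] += _gaussian_loglik(S_test, omega)
    return float(grid[int(np.argmax(scores))])


def estimate_network(
    z: ZMatrix | np.ndarray,
    node_names: list[str] | None = None,
    node_categories: list[str] | None = None,
    lam: float | None = None,
    n_folds: int = 5,
    seed: int = 0,
    layout_seed: int | None = None,
) -> NetworkEstimate:
    """Full-data regularised network with CV-selected penalty and MDS layout."""
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if lam is None:
        lam = select_lambda_cv(z, n_folds=n_folds, seed=seed)
    S = np.corrcoef(x, rowvar=False)
    _, partial = graphical_lasso(S, lam)
    p = x.shape[1]
    names = node_names if node_names is not None else (
        z.columns if isinstance(z, ZMatrix) else [f"v{i}" for i in range(p)]
    )
    cats = node_categories if node_categories is not None else ["cognition"] * p
    layout = None
    if layout_seed is not None:
        layout = node_layout(z, seed=layout_seed)
    return NetworkEstimate(
        node_names=list(names),
        node_categories=list(cats),
        weights=partial,
        regularization=float(lam),
        layout=layout,
    )


def bootstrap_network(
    z: ZMatrix | np.ndarray,
    B: int = 3000,
    seed: int = 0,
    lambda_mode: str = "retune",
    lam: float | None = None,
    n_folds: int = 5,
    max_redraws: int = 100,
) -> BootstrapSummary:
    """Bootstrap the regularised network over children.

    Per iteration, n children are resampled with replacement and the network
    re-estimated; the penalty is re-selected by CV when
    ``lambda_mode='retune'``, or reused from the full-data fit
    (``'fixed'``). Records each edge's occurrence fraction, per-iteration
    edge totals, and 2.5th/97.5th weight percentiles over all iterations
    with absent edges entered as zero. A singular resample is redrawn and
    counted.
    """
    if lambda_mode not in ("retune", "fixed"):
        raise ValueError("lambda_mode must be 'retune' or 'fixed'")
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete data required")
    n, p = x.shape
    rng = np.random.default_rng(seed)
    if lam is None and lambda_mode == "fixed":
        lam = select_lambda_cv(z, n_folds=n_folds, seed=seed)
    weights = np.zeros((B, p, p))
    edge_counts = np.zeros(B, dtype=int)
    n_redrawn = 0
    iu = np.triu_indices(p, k=1)
    for b in range(B):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            xb = x[idx]
            sd = xb.std(axis=0, ddof=1)
            if np.any(sd == 0):
                n_redrawn += 1
                continue
            try:
                if lambda_mode == "retune":
                    lam_b = select_lambda_cv(
                        xb, n_folds=n_folds, seed=int(rng.integers(2**31))
                    )
                else:
                    lam_b = lam
                S = np.corrcoef(xb, rowvar=False)
                _, partial = graphical_lasso(S, lam_b)
            except (RuntimeError, np.linalg.LinAlgError):
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError("exceeded redraw budget for singular resamples")
        weights[b] = partial
        edge_counts[b] = int(np.count_nonzero(partial[iu]))
    edge_probability = (weights != 0).mean(axis=0)
    ci_low = np.percentile(weights, 2.5, axis=0)
    ci_high = np.percentile(weights, 97.5, axis=0)
    summary = BootstrapSummary(
        n_iterations=B,
        edge_probability=edge_probability,
        ci_low=ci_low,
        ci_high=ci_high,
        edge_counts=edge_counts,
        seed=seed,
        lambda_mode=lambda_mode,
        n_redrawn=n_redrawn,
    )
    occurrence_significance(summary, SignificanceConfig(m_edges=p * (p - 1) // 2))
    edge_confidence_intervals(summary)
    return summary


def occurrence_significance(
    summary: BootstrapSummary, config: SignificanceConfig | None = None
) -> BootstrapSummary:
    """Apply the chance-fraction edge-significance rule.

    The chance count is the 100·(1−α) percentile (uncorrected) or the
    100·(1−α/m) percentile (Bonferroni) of the per-iteration edge totals,
    with the linear-interpolation percentile convention; dividing by the m
    possible edges gives the chance fraction. An edge is significant when
    its occurrence probability strictly exceeds that fraction.
    """
    if config is None:
        config = SignificanceConfig(m_edges=summary.m_edges)
    m = summary.m_edges
    pct_unc = 100.0 * (1.0 - config.alpha)
    pct_bon = 100.0 * (1.0 - config.alpha / m)
    count_unc = float(np.percentile(summary.edge_counts, pct_unc))
    count_bon = float(np.percentile(summary.edge_counts, pct_bon))
    summary.chance_count_uncorrected = count_unc
    summary.chance_count_bonferroni = count_bon
    summary.chance_fraction_uncorrected = count_unc / m
    summary.chance_fraction_bonferroni = count_bon / m
    summary.significant_uncorrected = summary.edge_probability > count_unc / m
    summary.significant_bonferroni = summary.edge_probability > count_bon / m
    return summary


def edge_confidence_intervals(summary: BootstrapSummary) -> BootstrapSummary:
    """Mark edges whose 95% percentile CI excludes zero."""
    summary.significant_ci = (summary.ci_low > 0) | (summary.ci_high < 0)
    return summary


def node_layout(z: ZMatrix | np.ndarray, seed: int = 0, n_restarts: int = 4) -> np.ndarray:
    """Node coordinates: nonmetric MDS of distances between variable columns
    (the transposed data — children act as dimensions)."""
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    emb = mds_embed(x.T, seed=seed, n_restarts=n_restarts)
    return emb.coordinates


def holm_correlations(
    z: ZMatrix | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlations with Holm step-down significance.

    Returns the p × p correlation matrix and a boolean mask of pairs whose
    two-sided p-value survives Holm–Bonferroni correction at family level α.
    """
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if np.isnan(x).any():
        raise ValueError("complete data required")
    n, p = x.shape
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(p, k=1)
    pvals = np.array([
        stats.pearsonr(x[:, i], x[:, j]).pvalue for i, j in zip(*iu)
    ])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    mask = np.zeros((p, p), dtype=bool)
    mask[iu] = reject
    mask |= mask.T
    return corr, mask
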