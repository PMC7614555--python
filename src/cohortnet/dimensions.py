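"""Dimensionality: PCA on the correlation matrix, varimax rotation,
Horn's parallel analysis, the Kaiser rule, and the factor report.

Principal components are extracted from the Pearson correlation matrix of
the standardised data, so eigenvalues are on the "variance of one variable"
scale and sum to p. Component retention is decided two ways: Kaiser's
eigenvalue-over-1 rule, and parallel analysis, which compares each observed
eigenvalue against the same-index percentile of eigenvalues from simulated
pure-noise datasets of identical shape and stops at the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ZMatrix

__all__ = [
    "FactorSolution",
    "ParallelResult",
    "pca_correlation",
    "varimax",
    "parallel_analysis",
    "kaiser_count",
    "factor_solution",
    "factor_table",
]


@dataclass
class FactorSolution:
    """Eigenstructure and rotated solution for a correlation matrix."""

    measure_names: list[str]
    eigenvalues: np.ndarray  # length p, non-increasing, sum ~= p
    unrotated_loadings: np.ndarray  # p x k
    rotated_loadings: np.ndarray  # p x k, varimax
    uniqueness: np.ndarray  # 1 - row communality over the k kept components
    explained_variance_pct: np.ndarray  # eigenvalue / p * 100, first k
    ssl: np.ndarray  # sum of squared rotated loadings per component
    explained_common_variance_pct: np.ndarray  # ssl / p * 100
    retained_parallel: int
    retained_kaiser: int


@dataclass
class ParallelResult:
    thresholds: np.ndarray  # per-component reference eigenvalues
    n_iterations: int
    percentile: float
    retained: int
    seed: int


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column non-negative."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca_correlation(z: ZMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Pearson correlation matrix.

    Returns (eigenvalues, loadings) with eigenvalues sorted descending and
    loadings = eigenvector · √eigenvalue. Near-zero negative eigenvalues
    from rank deficiency are clipped at 0.
    """
    x = z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    if np.isnan(x).any():
        raise ValueError("pca_correlation requires complete data")
    n, p = x.shape
    if p < 2 or n <= p:
        raise ValueError("need p >= 2 and n > p")
    corr = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    loadings = eigvec * np.sqrt(eigval)
    return eigval, _fix_signs(loadings)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Varimax rotation of a p × k loading matrix.

    Orthogonal rotation maximising the variance of squared loadings within
    each column (simple structure), via the standard SVD update scheme. With
    ``kaiser_normalize`` the rows are scaled to unit communality before
    rotation and rescaled after. Columns of the result are ordered by
    descending sum of squared loadings, with the deterministic sign
    convention (largest-|entry| per column non-negative).
    """
    lam = np.asarray(loadings, dtype=float).copy()
    p, k = lam.shape
    if k < 2:
        return _fix_signs(lam)
    comm = np.sqrt((lam**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        lam = lam / safe[:, None]
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        basis = np.asarray(loadings, dtype=float)
        if kaiser_normalize:
            basis = basis / np.where(comm > 0, comm, 1.0)[:, None]
        lam = basis @ rot
        tmp = lam**3 - lam * (lam**2).sum(axis=0) / p
        u, s, vt = np.linalg.svd(basis.T @ tmp)
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    else:
        raise RuntimeError(
            f"varimax failed to converge; last criterion change "
            f"{var_new - var_old:.3e}"
        )
    basis = np.asarray(loadings, dtype=float)
    if kaiser_normalize:
        basis = basis / np.where(comm > 0, comm, 1.0)[:, None]
    lam = basis @ rot
    if kaiser_normalize:
        lam = lam * comm[:, None]
    order = np.argsort(-(lam**2).sum(axis=0), kind="stable")
    return _fix_signs(lam[:, order])


def varimax_criterion(loadings: np.ndarray) -> float:
    """The raw varimax objective: sum over columns of var(squared loadings)."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def parallel_analysis(
    observed_eigenvalues: np.ndarray,
    n: int,
    p: int,
    n_iterations: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> ParallelResult:
    """Horn's parallel analysis with sequential stopping.

    Simulates ``n_iterations`` standard-normal n × p datasets, takes the
    per-index ``percentile`` of their correlation-matrix eigenvalues as the
    noise reference, and retains leading observed components while each
    exceeds its reference, stopping at the first failure.

    ``observed_eigenvalues`` may list only the leading eigenvalues; retention
    can never exceed the number provided.
    """
    if n <= p:
        raise ValueError("need n > p")
    if n_iterations < 100:
        raise ValueError("need at least 100 iterations")
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iterations, p))
    for it in range(n_iterations):
        x = rng.standard_normal((n, p))
        ev = np.linalg.eigvalsh(np.corrcoef(x, rowvar=False))
        sims[it] = ev[::-1]
    thresholds = np.percentile(sims, percentile, axis=0)
    obs = np.asarray(observed_eigenvalues, dtype=float)
    retained = 0
    for i, lam in enumerate(obs[:p]):
        if lam > thresholds[i]:
            retained += 1
        else:
            break
    return ParallelResult(
        thresholds=thresholds,
        n_iterations=n_iterations,
        percentile=percentile,
        retained=retained,
        seed=seed,
    )


def kaiser_count(eigenvalues: np.ndarray) -> int:
    """Number of eigenvalues strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def factor_solution(
    z: ZMatrix,
    n_components: int | None = None,
    pa_iterations: int = 1000,
    pa_percentile: float = 95.0,
    seed: int = 0,
) -> FactorSolution:
    """Extract, rotate and summarise the component solution for a cohort.

    By default the number of rotated components follows the Kaiser rule
    (eigenvalue > 1), matching the published 5-component report; parallel
    analysis is run alongside and its (typically smaller) retention count is
    recorded in the solution.
    """
    eigval, loadings = pca_correlation(z)
    n, p = z.values.shape
    pa = parallel_analysis(
        eigval, n=n, p=p, n_iterations=pa_iterations,
        percentile=pa_percentile, seed=seed,
    )
    k_kaiser = kaiser_count(eigval)
    k = n_components if n_components is not None else max(k_kaiser, 1)
    rotated = varimax(loadings[:, :k])
    ssl = (rotated**2).sum(axis=0)
    uniqueness = 1.0 - (rotated**2).sum(axis=1)
    return FactorSolution(
        measure_names=list(z.columns),
        eigenvalues=eigval,
        unrotated_loadings=loadings[:, :k],
        rotated_loadings=rotated,
        uniqueness=uniqueness,
        explained_variance_pct=eigval[:k] / p * 100.0,
        ssl=ssl,
        explained_common_variance_pct=ssl / p * 100.0,
        retained_parallel=pa.retained,
        retained_kaiser=k_kaiser,
    )


def factor_table(solution: FactorSolution) -> pd.DataFrame:
    """Factor report: per-variable rotated loadings with the dominant
    loading flagged, uniqueness, and the four per-component summary rows
    (eigenvalue before rotation, explained variance %, sum of squared
    loadings, explained common variance %)."""
    p, k = solution.rotated_loadings.shape
    cols = [f"RC{i+1}" for i in range(k)]
    body = pd.DataFrame(
        solution.rotated_loadings, index=solution.measure_names, columns=cols
    )
    dominant = body.abs().values.argmax(axis=1)
    body["dominant"] = [cols[j] for j in dominant]
    body["uniqueness"] = solution.uniqueness
    summary = pd.DataFrame(
        [
            solution.eigenvalues[:k],
            solution.explained_variance_pct,
            solution.ssl,
            solution.explained_common_variance_pct,
        ],
        index=[
            "Eigenvalue (before rotation)",
            "Explained variance (%)",
            "Sum of squared loadings",
            "Explained common variance (%)",
        ],
        columns=cols,
    )
    summary["dominant"] = ""
    summary["uniqueness"] = np.nan
    return pd.concat([body, summary])
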