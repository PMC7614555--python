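"""Preprocessing: missingness exclusion, standardisation, kNN imputation,
and correlational power utilities.

The pipeline mirrors the study protocol: drop children with more than 20%
missing cells, z-score each measure over its observed values, then fill the
remaining holes with a 9-nearest-neighbour imputer trained on the complete
rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cohort import CohortTable

__all__ = [
    "PreprocessConfig",
    "ZMatrix",
    "exclude_high_missingness",
    "standardize",
    "impute_knn",
    "correlation_power",
    "min_detectable_r",
]


@dataclass
class PreprocessConfig:
    max_missing_fraction: float = 0.20
    knn_k: int = 9
    distance: str = "euclidean-shared"

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class ZMatrix:
    """Standardised child × measure matrix.

    ``values`` holds z-scores with NaN for missing cells; ``imputed_mask``
    marks cells that were filled by imputation (all False before
    :func:`impute_knn`).
    """

    values: np.ndarray
    columns: list[str]
    child_ids: list[str]
    imputed_mask: np.ndarray

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


def exclude_high_missingness(
    table: CohortTable, max_missing_fraction: float = 0.20
) -> tuple[CohortTable, list[str]]:
    """Drop rows whose missing fraction strictly exceeds the threshold.

    Returns the filtered table (row order preserved) and the excluded ids.
    """
    if table.n_children == 0:
        raise ValueError("empty table")
    frac = table.row_missing_fraction()
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("all rows exceed the missingness threshold")
    excluded = [cid for cid, k in zip(table.child_ids, keep) if not k]
    kept = CohortTable(
        child_ids=[cid for cid, k in zip(table.child_ids, keep) if k],
        measures=list(table.measures),
        values=table.values[keep],
        missing_mask=table.missing_mask[keep],
    )
    return kept, excluded


def standardize(table: CohortTable) -> ZMatrix:
    """Z-score each measure over its observed cells (mean 0, SD 1, n−1)."""
    vals = np.where(table.missing_mask, np.nan, table.values)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1)
    for name, s in zip(table.measure_names, sd):
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"measure {name!r} is constant or unobserved")
    z = (vals - mu) / sd
    return ZMatrix(
        values=z,
        columns=list(table.measure_names),
        child_ids=list(table.child_ids),
        imputed_mask=np.zeros_like(z, dtype=bool),
    )


def impute_knn(z: ZMatrix, k: int = 9) -> ZMatrix:
    """Fill missing z-scores with the mean of the k nearest complete rows.

    The donor pool contains complete rows only. Distance from an incomplete
    row to each donor is the Euclidean distance over the row's observed
    columns divided by √(number of shared columns), so rows with different
    missingness patterns are comparable. Ties are broken by donor row order.
    Observed cells are never modified.
    """
    vals = z.values.copy()
    missing = np.isnan(vals)
    complete_rows = ~missing.any(axis=1)
    donors = vals[complete_rows]
    if donors.shape[0] < k:
        raise ValueError(
            f"only {donors.shape[0]} complete rows available as donors; need {k}"
        )
    imputed = z.imputed_mask.copy()
    for i in np.flatnonzero(missing.any(axis=1)):
        obs = ~missing[i]
        diff = donors[:, obs] - vals[i, obs]
        dist = np.sqrt((diff**2).sum(axis=1)) / np.sqrt(obs.sum())
        # stable argsort => ties broken by donor row order
        nearest = np.argsort(dist, kind="stable")[:k]
        fill_cols = np.flatnonzero(missing[i])
        vals[i, fill_cols] = donors[np.ix_(nearest, fill_cols)].mean(axis=0)
        imputed[i, fill_cols] = True
    return ZMatrix(
        values=vals,
        columns=list(z.columns),
        child_ids=list(z.child_ids),
        imputed_mask=imputed,
    )


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power to detect a Pearson correlation of size r at level α.

    Uses the Fisher z approximation: atanh(ρ̂) is approximately normal with
    mean atanh(r) and SD 1/√(n−3), giving
    power ≈ Φ(|atanh(r)|·√(n−3) − z_{1−α/2}).
    """
    if not 0 <= r < 1:
        raise ValueError("r must be in [0, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_crit = norm.ppf(1 - alpha / 2)
    delta = abs(np.arctanh(r)) * np.sqrt(n - 3)
    # both rejection tails; the wrong-sign tail is negligible except near r=0
    return float(norm.cdf(delta - z_crit) + norm.cdf(-delta - z_crit))


def min_detectable_r(n: int, power: float = 0.80, alpha: float = 0.05) -> float:
    """Smallest correlation detectable with the given power at level α.

    Inverts the Fisher z approximation:
    r = tanh((z_{1−α/2} + z_power) / √(n−3)).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_crit = norm.ppf(1 - alpha / 2)
    z_pow = norm.ppf(power)
    return float(np.tanh((z_crit + z_pow) / np.sqrt(n - 3)))
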