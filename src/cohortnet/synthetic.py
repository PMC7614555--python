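"""Synthetic cohorts with known ground truth.

The study cohort itself is restricted (postcode-derived deprivation ranks
cannot be anonymised), so every downstream stage is exercised on synthetic
data instead. Two generators are provided:

* a latent-factor cohort generator whose loading structure, uniquenesses and
  per-measure scale targets are transcribed from the published 5-component
  varimax solution and descriptive table, giving cohorts with a known
  factor structure and realistic measure units; and
* a sparse Gaussian-graphical-model sampler with a known precision matrix,
  the oracle for network-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, MeasureDefinition

__all__ = [
    "FactorModelSpec",
    "GGMSpec",
    "spec_from_table2",
    "generate_factor_cohort",
    "generate_ggm_sample",
    "inject_missingness",
    "ANALYSIS_MEASURES",
    "COMPONENT_NAMES",
    "PRINTED_SUMMARY",
]

# ---------------------------------------------------------------------------
# Published 5-component varimax solution: 19 variables × 5 rotated components
# plus per-variable uniqueness. Rows in alphabetical variable order.
# ---------------------------------------------------------------------------

COMPONENT_NAMES = ("RC1", "RC2", "RC3", "RC4", "RC5")

#: variable -> (RC1..RC5 loadings, uniqueness)
_TABLE2: dict[str, tuple[tuple[float, float, float, float, float], float]] = {
    "Affluence":          ((0.071, 0.017, 0.029, 0.050, 0.491), 0.751),
    "Anxiety":            ((-0.075, -0.125, 0.563, 0.010, -0.016), 0.661),
    "Calm home":          ((0.017, 0.438, -0.173, 0.003, 0.085), 0.770),
    "Class distraction":  ((-0.213, -0.340, 0.335, 0.064, -0.021), 0.722),
    "Conscientiousness":  ((-0.038, 0.655, 0.045, 0.030, -0.066), 0.562),
    "Depression":         ((-0.206, -0.222, 0.776, -0.007, -0.077), 0.300),
    "Deprivation":        ((-0.217, -0.059, 0.120, 0.035, -0.375), 0.793),
    "Fluid reasoning":    ((0.566, 0.103, -0.179, 0.000, 0.221), 0.588),
    "Grit":               ((0.154, 0.604, -0.016, 0.060, 0.198), 0.568),
    "Growth mindset":     ((0.132, 0.445, -0.157, 0.040, 0.047), 0.756),
    "Inhibition":         ((0.452, 0.106, -0.062, -0.007, -0.134), 0.762),
    "Number sense":       ((0.569, 0.051, -0.059, 0.059, 0.099), 0.656),
    "Reading":            ((0.506, 0.062, -0.047, 0.212, 0.145), 0.671),
    "School liking":      ((0.131, 0.524, -0.195, -0.030, -0.109), 0.658),
    "Search":             ((0.269, 0.055, -0.075, 0.206, -0.010), 0.877),
    "Spatial STM":        ((0.666, 0.095, -0.034, 0.020, 0.057), 0.542),
    "Speed":              ((0.211, 0.030, 0.089, 0.960, 0.044), 0.023),
    "Sums":               ((0.727, 0.067, -0.094, 0.149, 0.171), 0.406),
    "Verbal STM":         ((0.483, 0.073, -0.153, -0.017, 0.247), 0.677),
}

#: the published per-component summary rows (eigenvalue before rotation,
#: explained variance %, sum of squared rotated loadings, explained common
#: variance %), kept for cross-checks against computed internals.
PRINTED_SUMMARY = {
    "eigenvalue": (4.22, 2.12, 1.38, 1.20, 1.06),
    "explained_variance_pct": (22.17, 11.11, 7.24, 6.32, 5.56),
    "ssl": (2.63, 1.69, 1.23, 1.05, 0.65),
    "explained_common_variance_pct": (13.86, 8.92, 6.48, 5.53, 3.40),
}

# Per-measure scale targets (mean, SD, min, max in measure units) for the 16
# directly measured variables; the three composite variables (fluid
# reasoning, search, speed) are analysed as means of z-scored subscores, so
# their natural scale is the z scale.
_Z = (0.0, 1.0, -4.0, 4.0)
_SCALE: dict[str, tuple[float, float, float, float]] = {
    "Affluence":         (4.95, 3.11, -5.00, 12.00),
    "Anxiety":           (2.15, 1.32, 0.00, 5.00),
    "Calm home":         (0.74, 1.09, -3.00, 3.29),
    "Class distraction": (0.51, 0.32, 0.00, 1.00),
    "Conscientiousness": (1.58, 0.77, 0.00, 3.00),
    "Depression":        (1.79, 0.90, 0.00, 5.00),
    "Deprivation":       (-0.27, 0.94, -1.94, 2.29),
    "Fluid reasoning":   _Z,
    "Grit":              (2.87, 0.80, 0.36, 4.00),
    "Growth mindset":    (0.80, 0.28, 0.00, 1.00),
    "Inhibition":        (3.13, 0.93, -3.26, 4.95),
    "Number sense":      (0.63, 0.09, 0.32, 0.86),
    "Reading":           (45.24, 13.52, 4.0, 84.0),
    "School liking":     (0.04, 0.65, -1.00, 1.00),
    "Search":            _Z,
    "Spatial STM":       (5.94, 4.11, 0.0, 16.0),
    "Speed":             _Z,
    "Sums":              (34.47, 14.36, 0.0, 85.0),
    "Verbal STM":        (9.48, 4.12, 0.0, 20.0),
}

_CATEGORY: dict[str, str] = {
    "Affluence": "SES",
    "Deprivation": "SES",
    "Anxiety": "mental-health",
    "Depression": "mental-health",
    "Calm home": "attitude",
    "Class distraction": "attitude",
    "Conscientiousness": "attitude",
    "Grit": "attitude",
    "Growth mindset": "attitude",
    "School liking": "attitude",
    "Fluid reasoning": "cognition",
    "Inhibition": "cognition",
    "Number sense": "cognition",
    "Search": "cognition",
    "Spatial STM": "cognition",
    "Verbal STM": "cognition",
    "Speed": "speed",
    "Reading": "education",
    "Sums": "education",
}

_DISCRETE = {"Reading", "Spatial STM", "Sums", "Verbal STM"}
_LOWER_BETTER = {"Anxiety", "Depression", "Deprivation", "Class distraction"}

# The assessment battery reports some constructs as several subscores
# (two fluid-reasoning subtests, three search-organisation indices, two
# inter-click speed measures); the analysis uses one variable per construct.
# name -> (M, SD, min, max, category, discrete, higher_is_better)
_SUBSCORES: dict[str, tuple] = {
    "Fluid reasoning (series)": (5.80, 2.79, 0.0, 12.0, "cognition", True, True),
    "Fluid reasoning (classification)": (5.91, 1.95, 1.0, 11.0, "cognition", True, True),
    "Search (best R)": (0.61, 0.20, 0.02, 0.99, "cognition", False, True),
    "Search (intersect rate)": (0.18, 0.13, 0.00, 1.17, "cognition", False, False),
    "Search (pixel distance)": (326.24, 46.03, 240.76, 770.39, "cognition", False, False),
    "Speed (marked)": (0.63, 0.28, 0.30, 4.28, "speed", False, False),
    "Speed (unmarked)": (0.61, 0.35, 0.23, 6.93, "speed", False, False),
}

#: default reduction of subscore columns to single analysis variables
SUBSCORE_MAPPING: dict[str, list[str]] = {
    "Fluid reasoning": [
        "Fluid reasoning (series)", "Fluid reasoning (classification)"
    ],
    "Search": [
        "Search (best R)", "Search (intersect rate)", "Search (pixel distance)"
    ],
    "Speed": ["Speed (marked)", "Speed (unmarked)"],
}

_COMBINED = {name for group in SUBSCORE_MAPPING.values() for name in group}

#: the 23 battery columns as collected (16 direct measures + 7 subscores)
SUBSCORE_MEASURES: list[MeasureDefinition] = [
    MeasureDefinition(
        name=name,
        category=_CATEGORY[name],
        scale_min=_SCALE[name][2],
        scale_max=_SCALE[name][3],
        discrete=name in _DISCRETE,
        higher_is_better=name not in _LOWER_BETTER,
    )
    for name in _TABLE2
    if name not in SUBSCORE_MAPPING
] + [
    MeasureDefinition(
        name=name, category=cat, scale_min=lo, scale_max=hi,
        discrete=disc, higher_is_better=better,
    )
    for name, (_, _, lo, hi, cat, disc, better) in _SUBSCORES.items()
]

#: the 19 analysis measures, Table-2 row order
ANALYSIS_MEASURES: list[MeasureDefinition] = [
    MeasureDefinition(
        name=name,
        category=_CATEGORY[name],
        scale_min=_SCALE[name][2],
        scale_max=_SCALE[name][3],
        discrete=name in _DISCRETE,
        higher_is_better=name not in _LOWER_BETTER,
    )
    for name in _TABLE2
]


@dataclass
class FactorModelSpec:
    """Generative parameters for a latent-factor cohort.

    ``loadings`` (p × k) and ``uniqueness`` (p) define the standardised-score
    covariance ΛΛᵀ + diag(ψ); the target vectors map z-scores back onto
    measure units.
    """

    n_children: int
    measure_names: list[str]
    loadings: np.ndarray
    uniqueness: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray
    target_min: np.ndarray
    target_max: np.ndarray
    discrete_flags: np.ndarray
    cell_missing_rate: float = 0.0145
    seed: int = 20210904

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        p = self.loadings.shape[0]
        if np.any(self.uniqueness <= 0) or np.any(self.uniqueness > 1):
            raise ValueError("uniqueness entries must lie in (0, 1]")
        total = (self.loadings**2).sum(axis=1) + self.uniqueness
        if np.any(total < 0.9) or np.any(total > 1.1):
            raise ValueError("row communality + uniqueness must be within 10% of 1")
        if not 0 <= self.cell_missing_rate < 1:
            raise ValueError("cell_missing_rate must be in [0, 1)")
        if len(self.measure_names) != p:
            raise ValueError("measure_names length mismatch")

    @property
    def implied_correlation(self) -> np.ndarray:
        """Population correlation ΛΛᵀ + diag(ψ) of the standardised scores."""
        c = self.loadings @ self.loadings.T + np.diag(self.uniqueness)
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class GGMSpec:
    """Parameters for a sparse Gaussian-graphical-model sample."""

    p: int
    edge_density: float
    partial_range: tuple[float, float] = (0.25, 0.4)
    n_samples: int = 519
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        lo, hi = self.partial_range
        if not 0 < lo <= hi < 1:
            raise ValueError("partial_range must satisfy 0 < lo <= hi < 1")


def spec_from_table2(
    n_children: int = 519,
    cell_missing_rate: float = 0.0145,
    seed: int = 20210904,
) -> FactorModelSpec:
    """Factor-model spec transcribed from the published varimax solution.

    Loadings and uniquenesses come from the 19 × 5 rotated-component table;
    scale targets come from the descriptive table. The default missingness
    rate is set so that the expected fraction of complete rows matches the
    published complete-case count (397 of 519: (1−r)¹⁹ ≈ 0.765).
    """
    names = list(_TABLE2)
    loadings = np.array([_TABLE2[n][0] for n in names])
    uniq = np.array([_TABLE2[n][1] for n in names])
    scale = np.array([_SCALE[n] for n in names])
    return FactorModelSpec(
        n_children=n_children,
        measure_names=names,
        loadings=loadings,
        uniqueness=uniq,
        target_mean=scale[:, 0],
        target_sd=scale[:, 1],
        target_min=scale[:, 2],
        target_max=scale[:, 3],
        discrete_flags=np.array([n in _DISCRETE for n in names]),
        cell_missing_rate=cell_missing_rate,
        seed=seed,
    )


def generate_factor_cohort(
    spec: FactorModelSpec,
) -> tuple[CohortTable, np.ndarray]:
    """Draw a cohort from the latent-factor model.

    Standardised scores are X = FΛᵀ + E·diag(√ψ) with independent standard
    normal factors F (n × k) and noise E (n × p); they are then affinely
    mapped onto the target mean/SD, clipped to the target range, rounded for
    discrete measures, and hit with independent cell-wise missingness.

    Returns the cohort table and the true factor scores F.
    """
    if spec.n_children <= 0:
        raise ValueError("n_children must be positive")
    rng = np.random.default_rng(spec.seed)
    n, (p, k) = spec.n_children, spec.loadings.shape
    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p))
    z = factors @ spec.loadings.T + noise * np.sqrt(spec.uniqueness)
    vals = spec.target_mean + spec.target_sd * z
    vals = np.clip(vals, spec.target_min, spec.target_max)
    vals = np.where(spec.discrete_flags, np.round(vals), vals)
    mask = rng.random((n, p)) < spec.cell_missing_rate
    table = CohortTable(
        child_ids=[f"child_{i:04d}" for i in range(n)],
        measures=[
            MeasureDefinition(
                name=name,
                category=_CATEGORY.get(name, "cognition"),
                scale_min=float(lo),
                scale_max=float(hi),
                discrete=bool(d),
                higher_is_better=name not in _LOWER_BETTER,
            )
            for name, lo, hi, d in zip(
                spec.measure_names, spec.target_min, spec.target_max,
                spec.discrete_flags,
            )
        ],
        values=vals,
        missing_mask=mask,
    )
    return table, factors


def _precision_to_partial(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    return partial


def generate_ggm_sample(spec: GGMSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample from a zero-mean Gaussian with a known sparse precision matrix.

    The support of the precision matrix is Bernoulli(edge_density) on the
    upper triangle; nonzero magnitudes are uniform in ``partial_range`` with
    random signs. The diagonal starts at 1 and is inflated just enough to
    make the matrix positive definite (bounded inflation), which shrinks the
    realised partial correlations somewhat below the nominal range.

    Returns the n × p data matrix and the true partial-correlation matrix.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p
    lo, hi = spec.partial_range
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    support = rng.random(len(iu[0])) < spec.edge_density
    mags = rng.uniform(lo, hi, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    vals = np.where(support, mags * signs, 0.0)
    omega[iu] = vals
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0)

    min_eig = np.linalg.eigvalsh(omega)[0]
    if min_eig < 0.05:
        shift = 0.05 - min_eig
        if shift > 5.0:
            raise ValueError(
                "cannot make precision positive definite with bounded inflation"
            )
        omega[np.diag_indices(p)] += shift

    partial = _precision_to_partial(omega)
    cov = np.linalg.inv(omega)
    data = rng.multivariate_normal(np.zeros(p), cov, size=spec.n_samples,
                                   method="cholesky")
    return data, partial


def inject_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Flag each observed cell missing independently with probability rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    extra = rng.random(table.values.shape) < rate
    return CohortTable(
        child_ids=list(table.child_ids),
        measures=list(table.measures),
        values=table.values.copy(),
        missing_mask=table.missing_mask | extra,
    )
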