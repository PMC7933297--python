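"""Hyperparameter grid search and solution scoring.

A fitted partition is scored against external biology: a one-way ANOVA
F-statistic for each continuous covariate (e.g. an immune or stemness index)
and a Pearson chi-square statistic for each binary covariate (e.g. pathway
alteration status), with the per-test p-values combined by Fisher's method.
The grid search refits the model at every hyperparameter setting and ranks
the settings by the combined p-value — the best solution is the one that
explains maximal differences in the supplied biological covariates.  Also
provides partition-comparison metrics (classic and adjusted Rand index).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MultiModalDataset
from .graphs import GraphSet, IsingHyper
from .vb import FitConfig, FitResult, Hyperparameters, fit

__all__ = [
    "TestResult",
    "GridSpec",
    "SolutionScore",
    "anova_f",
    "chisq_stat",
    "fisher_combine",
    "rand_index",
    "grid_search",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    degenerate: str | None = None  # set when a convention replaced the test


def anova_f(values: Sequence[float], labels: Sequence[int]) -> TestResult:
    """One-way ANOVA of a continuous covariate across clusters.

    Degenerate conventions (logged in the result): a single group or no
    signal -> p = 1; perfect separation with zero within-group variance but
    distinct group means -> p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = [values[labels == lab] for lab in np.unique(labels)]
    if len(groups) < 2:
        return TestResult(0.0, 1.0, degenerate="single group")
    k = len(groups)
    n = values.size
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        return TestResult(0.0, 1.0, degenerate="no residual degrees of freedom")
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(0.0, 1.0, degenerate="all values identical")
        return TestResult(np.inf, 0.0, degenerate="perfect separation (zero within-group variance)")
    F = (ssb / df1) / (ssw / df2)
    return TestResult(float(F), float(stats.f.sf(F, df1, df2)))


def chisq_stat(binary: Sequence[int], labels: Sequence[int]) -> TestResult:
    """Pearson chi-square of a binary covariate against the cluster partition.

    Degenerate conventions: an empty margin (covariate constant, or a single
    cluster) -> p = 1; zero expected cells are flagged.
    """
    binary = np.asarray(binary)
    labels = np.asarray(labels)
    if binary.shape != labels.shape:
        raise ValueError("binary and labels must have equal length")
    if np.any((binary != 0) & (binary != 1)):
        raise ValueError("covariate must be binary 0/1")
    table = pd.crosstab(binary, labels).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return TestResult(0.0, 1.0, degenerate="empty margin")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        return TestResult(0.0, 1.0, degenerate="zero expected count")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p))


def fisher_combine(pvals: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: X = -2 sum ln p_i ~ chi-square with 2k df.

    Zero p-values are clamped to the smallest positive double with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clamped to the smallest positive double")
        p = np.maximum(p, np.finfo(float).tiny)
    X = -2.0 * float(np.sum(np.log(p)))
    return X, float(stats.chi2.sf(X, 2 * p.size))


def rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> tuple[float, float]:
    """(classic Rand index, adjusted Rand index) between two partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    from sklearn.metrics import adjusted_rand_score, rand_score

    return float(rand_score(labels_a, labels_b)), float(adjusted_rand_score(labels_a, labels_b))


@dataclass(frozen=True)
class GridSpec:
    """Finite hyperparameter grid.

    ``eta_values``/``nu_values`` entries are shared across modalities (and
    ``nu`` across the cross-modality coupling); supply tuples to spell out
    per-modality values instead.
    """

    alpha0_values: tuple[float, ...] = (10.0, 100.0, 1000.0)
    eta_values: tuple = (10.0, 100.0, 1000.0)
    nu_values: tuple = (1.0, 10.0)

    def __post_init__(self) -> None:
        if not (self.alpha0_values and self.eta_values and self.nu_values):
            raise ValueError("grid value lists must be non-empty")

    def points(self, n_modalities: int) -> list[Hyperparameters]:
        pts = []
        for a0, eta, nu in itertools.product(
            self.alpha0_values, self.eta_values, self.nu_values
        ):
            eta_t = tuple(eta) if isinstance(eta, (tuple, list)) else (float(eta),) * n_modalities
            if isinstance(nu, (tuple, list)):
                nu_t, nu_x = tuple(nu[:-1]), float(nu[-1])
            else:
                nu_t, nu_x = (float(nu),) * n_modalities, float(nu)
            pts.append(
                Hyperparameters(alpha0=a0, ising=IsingHyper(eta=eta_t, nu=nu_t, nu_cross=nu_x))
            )
        return pts


@dataclass
class SolutionScore:
    hyper: Hyperparameters
    tests: dict[str, TestResult] = field(default_factory=dict)
    fisher_statistic: float = 0.0
    fisher_p: float = 1.0
    occupied: int = 0
    converged: bool = True
    grid_order: int = 0


def score_partition(
    labels: np.ndarray,
    continuous: dict[str, np.ndarray] | None = None,
    binary: dict[str, np.ndarray] | None = None,
    extra_tests: dict[str, Callable[[np.ndarray], TestResult]] | None = None,
) -> tuple[dict[str, TestResult], float, float]:
    """Per-covariate tests and their Fisher combination for one partition.

    ``extra_tests`` is a pluggable hook mapping a name to a callable on the
    label vector (e.g. a survival log-rank scorer); each must return a
    TestResult whose p-value joins the combination.
    """
    tests: dict[str, TestResult] = {}
    for name, vals in (continuous or {}).items():
        tests[name] = anova_f(vals, labels)
    for name, vals in (binary or {}).items():
        tests[name] = chisq_stat(vals, labels)
    for name, fn in (extra_tests or {}).items():
        tests[name] = fn(labels)
    if not tests:
        raise ValueError("no scoring covariates supplied")
    pvals = [max(t.pvalue, np.finfo(float).tiny) for t in tests.values()]
    X, p = fisher_combine(pvals)
    return tests, X, p


def grid_search(
    data: MultiModalDataset,
    graphs: GraphSet | None,
    grid: GridSpec,
    *,
    continuous: dict[str, np.ndarray] | None = None,
    binary: dict[str, np.ndarray] | None = None,
    extra_tests: dict[str, Callable[[np.ndarray], TestResult]] | None = None,
    config: FitConfig = FitConfig(),
    H: int = 30,
) -> tuple[list[SolutionScore], FitResult]:
    """Fit every grid point (identically seeded) and rank settings.

    Ranking is ascending by combined p-value; ties break toward fewer
    occupied clusters, then grid order.  Returns the ranked scores and the
    best setting's FitResult.  A non-converged fit is scored but flagged.
    """
    n_mod = len(data.modalities)
    scores: list[SolutionScore] = []
    fits: list[FitResult] = []
    for order, hyper in enumerate(grid.points(n_mod)):
        hyper = replace(hyper, H=H)
        res = fit(data, graphs, hyper, config)
        tests, X, p = score_partition(
            res.labels, continuous=continuous, binary=binary, extra_tests=extra_tests
        )
        scores.append(
            SolutionScore(
                hyper=hyper,
                tests=tests,
                fisher_statistic=X,
                fisher_p=p,
                occupied=res.occupied,
                converged=res.converged,
                grid_order=order,
            )
        )
        fits.append(res)
    ranked = sorted(scores, key=lambda s: (s.fisher_p, s.occupied, s.grid_order))
    best = fits[ranked[0].grid_order]
    return ranked, best
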