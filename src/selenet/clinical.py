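"""IHC scoring statistics, marker correlations and survival comparison.

Immunohistochemistry cohorts carry an ordinal staining intensity per
marker (1 weak, 2 moderate, 3 strong), a tumor grade (2 or 3) and a
Ki67 proliferation percentage.  This module tabulates intensity by
grade, computes Pearson correlations (marker-marker, marker-grade,
marker-Ki67), splits a survival cohort on the combined expression of a
two-gene signature (mean of per-gene z-scores, median split) and
compares the resulting groups by Kaplan-Meier estimation with a
two-group log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from scipy import stats

from .errors import ParameterError, StatisticsError

INTENSITY_LEVELS = (1, 2, 3)
GRADES = (2, 3)


@dataclass
class IHCCohort:
    """Per-patient grade, Ki67 and ordinal marker intensities.

    ``data`` is indexed by patient id with columns ``grade`` (2 or 3),
    ``ki67`` (percent, 0-100) and one integer column in {1,2,3} per
    marker.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("grade", "ki67"):
            if col not in self.data.columns:
                raise ParameterError(f"IHC cohort missing column {col!r}")
        if not self.data["grade"].isin(GRADES).all():
            raise ParameterError("grade must be 2 or 3")
        k = self.data["ki67"].to_numpy(dtype=float)
        if ((k < 0) | (k > 100)).any():
            raise ParameterError("ki67 must lie in [0, 100]")
        for m in self.markers:
            if not self.data[m].isin(INTENSITY_LEVELS).all():
                raise ParameterError(f"marker {m!r} intensities must be 1, 2 or 3")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("grade", "ki67")]

    @classmethod
    def read_tsv(cls, path) -> "IHCCohort":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class SurvivalTable:
    """Per-patient follow-up time (months), event indicator and expression.

    ``data`` is indexed by patient id with columns ``time`` (> 0),
    ``event`` (0 censored / 1 event) and one real column per gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ParameterError(f"survival table missing column {col!r}")
        if (self.data["time"].to_numpy(dtype=float) <= 0).any():
            raise ParameterError("times must be > 0")
        if not self.data["event"].isin((0, 1)).all():
            raise ParameterError("event must be 0 or 1")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event", "group")]

    @classmethod
    def read_tsv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


def staining_distribution(cohort: IHCCohort, marker: str) -> pd.DataFrame:
    """Grade x intensity contingency counts for one marker.

    Rows are grades (2, 3), columns intensity levels (1, 2, 3); row sums
    equal the number of patients of each grade, and the grand total the
    cohort size.
    """
    if marker not in cohort.markers:
        raise ParameterError(f"unknown marker {marker!r}")
    table = pd.crosstab(cohort.data["grade"], cohort.data[marker])
    table = table.reindex(index=list(GRADES), columns=list(INTENSITY_LEVELS), fill_value=0)
    table.index.name, table.columns.name = "grade", "intensity"
    return table


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    method: str = "pearson"


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    p is the two-sided tail of t = r * sqrt((n-2) / (1-r^2)) on n-2
    degrees of freedom (for |r| = 1 the p-value is 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be one-dimensional and of equal length")
    n = len(x)
    if n < 3:
        raise ParameterError("at least 3 observations are required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticsError("correlation undefined for a zero-variance variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=n, p_value=float(p))


@dataclass
class SplitResult:
    """Combined-signature dichotomisation of a survival cohort."""

    labels: pd.Series  # "high" / "low" per patient
    n_median_ties: int
    degenerate: bool


def combined_split(s: SurvivalTable, genes: tuple[str, str]) -> SplitResult:
    """High/low split on the combined expression of a two-gene signature.

    Combined score = mean of per-gene z-scores; patients strictly above
    the cohort median score are ``high``, everyone else (including exact
    median ties) ``low``.  If the combined scores are essentially
    constant (e.g. perfectly anti-correlated genes of equal variance)
    the split is degenerate and a warning is emitted.
    """
    for g in genes:
        if g not in s.data.columns:
            raise ParameterError(f"gene {g!r} not present")
    if len(s.data) < 4:
        raise ParameterError("at least 4 patients are required for a split")
    zs = []
    for g in genes:
        x = s.data[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise StatisticsError(f"gene {g!r} has zero variance")
        zs.append((x - x.mean()) / sd)
    score = np.mean(zs, axis=0)

    degenerate = bool(np.ptp(score) < 1e-12 * max(1.0, np.abs(score).max()))
    if degenerate:
        warnings.warn(
            "combined z-scores are essentially constant; median split is degenerate",
            stacklevel=2,
        )
    med = np.median(score)
    labels = pd.Series(
        np.where(score > med, "high", "low"), index=s.data.index, name="group"
    )
    return SplitResult(labels=labels, n_median_ties=int((score == med).sum()), degenerate=degenerate)


@dataclass
class KMResult:
    """Kaplan-Meier curves and two-group log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step points
    chi_square: float
    p_value: float
    group_sizes: dict[str, int]


def km_logrank(s: SurvivalTable, groups: pd.Series | Sequence[str]) -> KMResult:
    """Kaplan-Meier estimation per group plus the two-group log-rank test.

    ``groups`` assigns each patient (aligned with the table) to one of
    exactly two labels.  Survival curves are product-limit estimates at
    the observed times; the log-rank statistic sums observed-minus-
    expected events over distinct event times with hypergeometric
    variance, and p comes from a chi-square with 1 df.
    """
    g = pd.Series(groups, index=s.data.index) if not isinstance(groups, pd.Series) else groups
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ParameterError(f"exactly two groups are required, got {labels}")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ParameterError(f"group {lab!r} is empty")

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for lab in labels:
        mask = (g == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(s.data["time"][mask], s.data["event"][mask], label=str(lab))
        sf = kmf.survival_function_
        curves[str(lab)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
        sizes[str(lab)] = int(mask.sum())

    mask_a = (g == labels[0]).to_numpy()
    res = logrank_test(
        s.data["time"][mask_a],
        s.data["time"][~mask_a],
        event_observed_A=s.data["event"][mask_a],
        event_observed_B=s.data["event"][~mask_a],
    )
    return KMResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
    )
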