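"""Survival and group-comparison statistics for MM-stratified cohorts.

Kaplan-Meier estimation is delegated to lifelines, log-rank tests to
lifelines.statistics, Cox proportional-hazards regression to statsmodels
PHReg (which offers both Efron and Breslow tie handling), and rank and
contingency tests to scipy.stats. This module fixes the conventions used
throughout the analysis: two-sided tests, Efron tie handling by default,
Bonferroni adjustment capped at 1, base-10 log transforms for the
right-skewed tumour markers (AFP, PIVKA-II), and a first-crossing
definition of the median survival time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .mm_core import MMClassification

__all__ = [
    "SurvivalFit",
    "CoxFit",
    "GroupComparison",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "group_compare",
    "log10_transform",
    "expression_by_mm",
    "CLINICAL_CUTOFFS",
]

#: clinically conventional dichotomisation cutoffs for Cox/contingency use
CLINICAL_CUTOFFS: Mapping[str, float] = {
    "icg_r15_percent": 20.0,     # indocyanine-green retention at 15 min
    "afp_ng_ml": 200.0,          # alpha-fetoprotein
    "pivka2_mau_ml": 100.0,      # PIVKA-II / DCP
    "tumor_size_mm": 30.0,
    "age_years": 70.0,
}

ALPHA = 0.05  # two-sided significance level used in report tables


@dataclass(frozen=True)
class SurvivalFit:
    """Kaplan-Meier product-limit fit for one group."""

    times: np.ndarray        # observed time grid (event and censor times)
    survival: np.ndarray     # S(t) at those times, non-increasing from 1
    n_at_risk: np.ndarray
    median_time: Optional[float]  # first time with S(t) <= 0.5, None if never
    n_subjects: int
    n_events: int


@dataclass(frozen=True)
class CoxCoefficient:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError(f"{self.covariate}: CI does not bracket the HR")


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: per-covariate HRs with 95% Wald CIs."""

    coefficients: tuple[CoxCoefficient, ...]
    n_subjects: int
    n_events: int
    log_likelihood: float
    ties: str

    def __getitem__(self, covariate: str) -> CoxCoefficient:
        for coef in self.coefficients:
            if coef.covariate == covariate:
                return coef
        raise KeyError(covariate)


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group or k-group comparison."""

    test: str                       # mann_whitney | chi_square | fisher_exact | anova
    statistic: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    adjustment: str = "none"
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.p_raw is not None


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalFit:
    """Kaplan-Meier product-limit estimate.

    The median is the first observed time at which the survival curve
    drops to 0.5 or below; ``None`` when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("cannot fit a survival curve to no subjects")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    # drop the t=0 anchor row unless 0 is an observed time
    if timeline.size and timeline[0] == 0.0 and 0.0 not in set(np.atleast_1d(times)):
        timeline, surv = timeline[1:], surv[1:]
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)

    below = np.nonzero(surv <= 0.5)[0]
    median = float(timeline[below[0]]) if below.size else None
    return SurvivalFit(
        times=timeline,
        survival=surv,
        n_at_risk=at_risk,
        median_time=median,
        n_subjects=int(times.size),
        n_events=int(events.sum()),
    )


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]]
) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value).

    The statistic is the standard observed-minus-expected quadratic form
    with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} has zero subjects")
        durations.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    result = multivariate_logrank_test(
        np.concatenate(durations), np.concatenate(labels), np.concatenate(events)
    )
    return float(result.test_statistic), float(result.p_value)


def cox_fit(
    design: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards regression by partial-likelihood
    maximisation, with 95% Wald CIs on the log-HR scale.

    ``design`` holds one numeric column per covariate. Constant covariates
    are rejected up front; non-convergence raises with diagnostics.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    design = design.astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(design) != times.size or times.size != events.size:
        raise ValueError("design, times and events must align")
    if len(design) <= design.shape[1]:
        raise ValueError("need more subjects than covariates")
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")

    model = PHReg(times, design, status=events, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(disp=False)
    params = np.asarray(result.params, dtype=float)
    bse = np.asarray(result.bse, dtype=float)
    if not (np.isfinite(params).all() and np.isfinite(bse).all()):
        raise RuntimeError(
            f"Cox fit did not converge: params={params}, se={bse}"
        )
    z = stats.norm.ppf(0.975)
    pvals = 2.0 * stats.norm.sf(np.abs(params / bse))
    coefs = tuple(
        CoxCoefficient(
            covariate=str(design.columns[i]),
            hazard_ratio=float(np.exp(params[i])),
            ci_low=float(np.exp(params[i] - z * bse[i])),
            ci_high=float(np.exp(params[i] + z * bse[i])),
            p_value=float(pvals[i]),
        )
        for i in range(len(params))
    )
    return CoxFit(
        coefficients=coefs,
        n_subjects=int(times.size),
        n_events=int(events.sum()),
        log_likelihood=float(model.loglike(params)),
        ties=ties,
    )


def bonferroni(p_raw: float, m_comparisons: int) -> float:
    return min(1.0, p_raw * m_comparisons)


def group_compare(
    data,
    test: str,
    m_comparisons: int = 1,
) -> GroupComparison:
    """Run one comparison and attach a Bonferroni-adjusted p-value.

    ``data`` is a list of value vectors for mann_whitney / anova, or a 2-D
    contingency table for chi_square / fisher_exact. Mann-Whitney uses the
    exact null distribution when both groups have at most 20 untied
    observations and the tie-corrected normal approximation otherwise;
    chi-square applies no continuity correction; Fisher is exact on a 2x2
    table. All tests are two-sided.
    """
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    adjustment = "bonferroni" if m_comparisons > 1 else "none"

    if test == "mann_whitney":
        if len(data) != 2:
            raise ValueError("mann_whitney needs exactly two groups")
        x, y = (np.asarray(g, dtype=float) for g in data)
        if x.size == 0 or y.size == 0:
            raise ValueError("empty group")
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "anova":
        if len(data) < 2 or any(len(g) == 0 for g in data):
            raise ValueError("anova needs >= 2 non-empty groups")
        res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in data])
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "chi_square":
        table = np.asarray(data, dtype=float)
        if table.ndim != 2 or (table < 0).any():
            raise ValueError("chi_square needs a non-negative 2-D table")
        res = stats.chi2_contingency(table, correction=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "fisher_exact":
        table = np.asarray(data, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("fisher_exact needs a 2x2 table")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        statistic = float(odds)
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        test=test,
        statistic=statistic,
        p_raw=p,
        p_adjusted=bonferroni(p, m_comparisons),
        adjustment=adjustment,
    )


def log10_transform(values: Sequence[float]) -> np.ndarray:
    """Elementwise base-10 log; rejects non-positive values by position."""
    values = np.asarray(values, dtype=float)
    bad = np.nonzero(~(values > 0))[0]
    if bad.size:
        raise ValueError(
            f"log10 transform needs positive values; offending index {int(bad[0])} "
            f"(value {values[bad[0]]!r})"
        )
    return np.log10(values)


def expression_by_mm(
    fold_changes: Mapping[str, float],
    classification: MMClassification,
    gene: str,
) -> dict[tuple[str, str], GroupComparison]:
    """Pairwise fold-change comparisons across wild_type/single/multiple.

    Tumour/normal expression fold changes are grouped by the sample's
    mutation class in ``gene`` and compared pairwise with two-sided
    Mann-Whitney tests under Bonferroni adjustment (m = 3). A pair
    involving a class with fewer than two samples is returned untestable
    (p values ``None``).
    """
    by_class: dict[str, list[float]] = {"wild_type": [], "single": [], "multiple": []}
    for sample, fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"non-positive fold change for sample {sample!r}")
        if sample in classification.per_sample:
            by_class[classification.label(sample, gene)].append(fc)

    pairs = [("wild_type", "single"), ("wild_type", "multiple"), ("single", "multiple")]
    out: dict[tuple[str, str], GroupComparison] = {}
    for a, b in pairs:
        if len(by_class[a]) < 2 or len(by_class[b]) < 2:
            out[(a, b)] = GroupComparison(
                test="mann_whitney", statistic=None, p_raw=None, p_adjusted=None,
                adjustment="bonferroni",
                note=f"untestable: <2 samples in {a if len(by_class[a]) < 2 else b}",
            )
            continue
        out[(a, b)] = group_compare(
            [by_class[a], by_class[b]], test="mann_whitney", m_comparisons=3
        )
    return out
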