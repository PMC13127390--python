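"""Agreement statistics for complete rater panels.

Three metrics are computed for a case x observer matrix of categorical
scores, mirroring standard inter-rater reliability reporting:

* **OPA** (overall percent agreement): the fraction of cases on which every
  observer assigned the identical category, with a Wilson score interval on
  the unanimous-case count.
* **Fleiss' kappa**: chance-corrected multi-rater agreement for nominal
  categories, with the Fleiss–Nee–Landis large-sample standard error.
* **ICC(A,1)**: intraclass correlation from a two-way random-effects ANOVA,
  absolute-agreement definition, single-rater unit, with the McGraw–Wong
  F-based confidence interval.  Categories enter the ANOVA as their numeric
  schema codes.

Statistics that are undefined on a given matrix (e.g. kappa when all
ratings fall in one category) raise :class:`UndefinedStatisticError`;
report builders catch it and degrade gracefully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core import CategoryCountTable, ScoreMatrix, to_count_table
from .recode import (
    BUILTIN_RECODES,
    EmptySubsetError,
    SubsetSpec,
    recode,
    select_subset,
    subset_mask,
)

__all__ = [
    "ConfInt",
    "UndefinedStatisticError",
    "ICCComponents",
    "AgreementReport",
    "StratifiedOPA",
    "opa",
    "opa_from_counts",
    "fleiss_kappa",
    "icc_a1",
    "agreement_report",
    "table1_report",
    "render_table1",
    "stratified_opa",
    "round_half_up",
]

Z_95 = stats.norm.ppf(0.975)


class UndefinedStatisticError(ValueError):
    """The statistic is undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class ConfInt:
    """A point estimate with a two-sided 95% confidence interval."""

    estimate: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12):
            raise ValueError(f"estimate {self.estimate} outside CI ({self.lower}, {self.upper})")

    def display(self, digits: int = 2) -> str:
        r = lambda x: f"{round_half_up(x, digits):.{digits}f}"
        return f"{r(self.estimate)} ({r(self.lower)}-{r(self.upper)})"


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero, as agreement tables are printed."""
    factor = 10**digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def opa_from_counts(n_unanimous: int, n_cases: int, method: str = "wilson") -> ConfInt:
    """OPA and its binomial CI from the unanimous-case count.

    ``method`` is ``"wilson"`` (default) or ``"clopper-pearson"``.
    """
    if n_cases < 1:
        raise UndefinedStatisticError("OPA undefined for an empty case set")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lower, upper = proportion_confint(n_unanimous, n_cases, alpha=0.05, method=sm_method)
    return ConfInt(
        n_unanimous / n_cases,
        float(min(max(lower, 0.0), 1.0)),
        float(min(max(upper, 0.0), 1.0)),
    )


def opa(m: ScoreMatrix, method: str = "wilson") -> ConfInt:
    """Overall percent agreement: fraction of fully unanimous cases."""
    unanimous = (m.scores == m.scores[:, [0]]).all(axis=1)
    return opa_from_counts(int(unanimous.sum()), m.n_cases, method=method)


def fleiss_kappa(table: CategoryCountTable) -> ConfInt:
    """Fleiss' kappa with its large-sample 95% CI.

    With per-case counts ``n_ij`` (R ratings per case), per-case agreement
    is ``P_i = (sum_j n_ij^2 - R) / (R (R-1))``; kappa compares the mean
    ``P`` to the chance agreement ``sum_j p_j^2`` implied by the pooled
    category proportions ``p_j``.  The standard error is the fixed-marginal
    large-sample form of Fleiss, Nee & Landis.
    """
    counts = table.counts
    n, _ = counts.shape
    r = table.n_raters
    if r < 2:
        raise UndefinedStatisticError("kappa needs at least two ratings per case")
    p_j = counts.sum(axis=0) / (n * r)
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0 - 1e-12:
        raise UndefinedStatisticError("all ratings fall in a single category; kappa undefined")
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    kappa = (p_bar - p_bar_e) / (1 - p_bar_e)

    pq = p_j * (1 - p_j)
    s = float(pq.sum())
    se = (math.sqrt(2) / (s * math.sqrt(n * r * (r - 1)))) * math.sqrt(
        s**2 - float((pq * (1 - 2 * p_j)).sum())
    )
    lower = min(max(-1.0, kappa - Z_95 * se), kappa)
    upper = max(min(1.0, kappa + Z_95 * se), kappa)
    return ConfInt(kappa, lower, upper)


@dataclass(frozen=True)
class ICCComponents:
    """Mean squares of the two-way ANOVA underlying ICC(A,1)."""

    ms_rows: float  # between-case mean square (df n-1)
    ms_cols: float  # between-observer mean square (df k-1)
    ms_error: float  # residual mean square (df (n-1)(k-1))
    n: int  # cases
    k: int  # observers


def _anova_components(values: np.ndarray) -> ICCComponents:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return ICCComponents(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=max(0.0, ss_err) / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_a1(m: ScoreMatrix, alpha: float = 0.05) -> tuple[ConfInt, ICCComponents]:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Scores are coerced to the schema's numeric codes.  The estimate is

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    and the CI follows McGraw & Wong's F-distribution method with
    Satterthwaite denominator degrees of freedom.
    """
    if m.n_cases < 2:
        raise UndefinedStatisticError("ICC needs at least two cases")
    values = m.scores.astype(float)
    comp = _anova_components(values)
    msr, msc, mse, n, k = comp.ms_rows, comp.ms_cols, comp.ms_error, comp.n, comp.k
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 1e-12:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    r = (msr - mse) / denom
    if mse <= 1e-12 and msc <= 1e-12:
        # observers identical: agreement is exact, interval degenerate
        return ConfInt(1.0, 1.0, 1.0), comp

    a = k * r / (n * (1 - r))
    b = 1 + k * r * (n - 1) / (n * (1 - r))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    # bounds are widened, never the estimate: tiny degenerate panels can put
    # the raw ICC(A,1) below -1, and the F bounds need not bracket it there
    lower = min(float(lower), r)
    upper = max(min(float(upper), 1.0), r)
    return ConfInt(r, lower, upper), comp


@dataclass
class AgreementReport:
    """One report row: OPA, Fleiss' kappa and ICC for one matrix/grouping.

    A metric that is undefined on the grouping is stored as None with the
    reason in ``notes``.
    """

    grouping_name: str
    n_cases: int
    opa: ConfInt | None = None
    fleiss_kappa: ConfInt | None = None
    icc: ConfInt | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def ci(c: ConfInt | None):
            return None if c is None else {"estimate": c.estimate, "lower": c.lower, "upper": c.upper}

        return {
            "grouping": self.grouping_name,
            "n_cases": self.n_cases,
            "opa": ci(self.opa),
            "fleiss_kappa": ci(self.fleiss_kappa),
            "icc": ci(self.icc),
            "notes": list(self.notes),
        }


def agreement_report(m: ScoreMatrix, name: str, opa_method: str = "wilson") -> AgreementReport:
    """Compute all three metrics on one matrix, degrading gracefully."""
    report = AgreementReport(grouping_name=name, n_cases=m.n_cases)
    try:
        report.opa = opa(m, method=opa_method)
    except UndefinedStatisticError as err:
        report.notes.append(f"OPA undefined: {err}")
    try:
        report.fleiss_kappa = fleiss_kappa(to_count_table(m))
    except UndefinedStatisticError as err:
        report.notes.append(f"kappa undefined: {err}")
    try:
        report.icc = icc_a1(m)[0]
    except UndefinedStatisticError as err:
        report.notes.append(f"ICC undefined: {err}")
    return report


# Row layout of the full agreement table for a 4-category matrix: the two
# scoring schemes, the five "score assigned by at least one observer"
# subsets, then the six dichotomizations.
_TABLE1_SUBSET_ANCHORS = [0, 1, 2, 3]
_TABLE1_DICHOTOMIES = [
    ("0 vs. not 0", "0_vs_not0"),
    ("1+ vs. not 1+", "1_vs_not1"),
    ("2+ vs. not 2+", "2_vs_not2"),
    ("low vs. not low", "low_vs_notlow"),
    ("3+ vs. not 3+", "3_vs_not3"),
    ("<2+ vs. >=2+", "lt2_vs_ge2"),
]


def table1_report(m: ScoreMatrix, opa_method: str = "wilson") -> list[AgreementReport]:
    """The full agreement table for a 4-category matrix.

    Rows, in order: 4-category scheme; 3-category scheme (1+ and 2+ merged
    into "low"); the "0 only" / "1+ only" / "2+ only" / "3+ only" / "low
    only" subsets on original codes; the six dichotomizations.  Rows with
    empty subsets or undefined metrics carry notes instead of aborting.
    """
    if m.schema.n_categories != 4:
        raise ValueError("the full report is defined for the 4-category schema")
    reports: list[AgreementReport] = []
    reports.append(agreement_report(m, "4-category score (0, 1+, 2+, 3+)", opa_method))
    reports.append(
        agreement_report(recode(m, BUILTIN_RECODES["three_cat"]), "3-category score (0, low, 3+)", opa_method)
    )
    for anchor in _TABLE1_SUBSET_ANCHORS:
        spec = SubsetSpec(anchor)
        name = spec.name(m.schema)
        try:
            reports.append(agreement_report(select_subset(m, spec), name, opa_method))
        except EmptySubsetError as err:
            reports.append(AgreementReport(name, 0, notes=[str(err)]))
    # "low only": at least one observer assigned 1+ or 2+ (union rule)
    low_mask = subset_mask(m, SubsetSpec(1)) | subset_mask(m, SubsetSpec(2))
    if low_mask.any():
        reports.append(agreement_report(m.select_cases(low_mask), "low only", opa_method))
    else:
        reports.append(AgreementReport("low only", 0, notes=["no qualifying cases"]))
    for row_name, map_name in _TABLE1_DICHOTOMIES:
        reports.append(agreement_report(recode(m, BUILTIN_RECODES[map_name]), row_name, opa_method))
    return reports


def render_table1(reports: list[AgreementReport], digits: int = 2, sep: str = "\t") -> str:
    """Render reports as TSV with the printed 2-decimal display rounding."""
    lines = [sep.join(["group", "n_cases", "OPA (95% CI)", "Fleiss' kappa (95% CI)", "ICC (95% CI)"])]
    for rep in reports:
        cells = [rep.grouping_name, str(rep.n_cases)]
        for metric in (rep.opa, rep.fleiss_kappa, rep.icc):
            cells.append(metric.display(digits) if metric is not None else "NA")
        lines.append(sep.join(cells))
    return "\n".join(lines) + "\n"


@dataclass
class StratifiedOPA:
    """Per-stratum OPA reports and the between-stratum difference."""

    axis: str
    reports: dict[str, AgreementReport]
    difference: float | None  # highest minus lowest stratum OPA; None if <2 strata

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "strata": {k: v.to_dict() for k, v in self.reports.items()},
            "difference": self.difference,
        }


def stratified_opa(m: ScoreMatrix, axis: str, opa_method: str = "wilson") -> StratifiedOPA:
    """OPA by observer-experience or specimen-type stratum.

    For ``axis="observer_experience"`` the panel is split by the observer
    metadata and OPA is computed among each stratum's observers over all
    cases (each stratum needs >= 2 observers).  For ``axis="specimen_type"``
    the cases are split by specimen metadata and OPA uses the full panel on
    each case stratum.  The difference is highest minus lowest stratum OPA.
    """
    reports: dict[str, AgreementReport] = {}
    if axis == "observer_experience":
        if not m.observer_meta:
            raise ValueError("observer metadata (experience sidecar) is missing")
        strata: dict[str, list[str]] = {}
        for obs in m.observer_ids:
            if obs not in m.observer_meta:
                raise ValueError(f"observer {obs!r} missing from experience metadata")
            strata.setdefault(m.observer_meta[obs], []).append(obs)
        for name, members in strata.items():
            if len(members) < 2:
                raise ValueError(f"stratum {name!r} has fewer than 2 observers")
            reports[name] = agreement_report(m.select_observers(members), name, opa_method)
    elif axis == "specimen_type":
        if not m.case_meta:
            raise ValueError("case metadata (specimen sidecar) is missing")
        strata = {}
        for case in m.case_ids:
            if case not in m.case_meta:
                raise ValueError(f"case {case!r} missing from specimen metadata")
            strata.setdefault(m.case_meta[case], []).append(case)
        keep = set()
        for name, members in strata.items():
            keep = set(members)
            mask = np.array([c in keep for c in m.case_ids])
            reports[name] = agreement_report(m.select_cases(mask), name, opa_method)
    else:
        raise ValueError(f"unknown stratification axis {axis!r}")

    defined = {k: v.opa.estimate for k, v in reports.items() if v.opa is not None}
    difference = (max(defined.values()) - min(defined.values())) if len(defined) >= 2 else None
    return StratifiedOPA(axis=axis, reports=reports, difference=difference)
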