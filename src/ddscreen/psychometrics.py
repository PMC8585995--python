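"""Diagnostic-accuracy and group-comparison statistics.

Validation of the index screen against the reference diagnostic interview:
2x2 confusion matrices per disorder, sensitivity / specificity / predictive
values with binomial confidence intervals, Pearson chi-square on contingency
tables, two-sample t tests from summary statistics, and a per-disorder
concordance report over a paired cohort.

Conventions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN); screen-positive prevalence is
(TP+FP)/n and reference prevalence (TP+FN)/n, both reported as percentages.
A metric with a zero denominator is flagged undefined, never silently 0.
Missing data are handled complete-case per disorder, with the exclusion
count reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model import DISORDERS, Disorder, DisorderFlag

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "AccuracyReport",
    "ContingencyTable",
    "ChiSquareResult",
    "TTestResult",
    "ConcordanceRow",
    "CONCORDANCE_ORDER",
    "build_confusion_matrix",
    "accuracy_metrics",
    "pearson_chi_square",
    "two_sample_t",
    "concordance_table",
    "flags_to_frame",
    "concordance_frame",
]

#: Row order of the concordance report (the published validation table's
#: order, followed by the remaining disorders in canonical order).
CONCORDANCE_ORDER: tuple[Disorder, ...] = (
    Disorder.depression,
    Disorder.gad,
    Disorder.ptsd,
    Disorder.social_phobia,
    Disorder.adhd,
    Disorder.dysthymia,
    Disorder.psychosis,
    Disorder.mania,
    Disorder.panic,
    Disorder.agoraphobia,
    Disorder.specific_phobia,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 index-vs-reference counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion matrix is empty (n = 0)")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_confusion_matrix(
    index: Sequence[bool], reference: Sequence[bool]
) -> ConfusionMatrix:
    """Tally paired index-test and reference-standard booleans.

    Inputs must be equal-length, non-empty, and aligned by patient.
    """
    if len(index) != len(reference):
        raise ValueError(
            f"index ({len(index)}) and reference ({len(reference)}) lengths differ"
        )
    if len(index) == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    idx = np.asarray(index, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(idx & ref)),
        fp=int(np.sum(idx & ~ref)),
        fn=int(np.sum(~idx & ref)),
        tn=int(np.sum(~idx & ~ref)),
    )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its CI; ``defined`` is False on a zero denominator."""

    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    defined: bool = True
    ci_clipped: bool = False


def _proportion_estimate(
    count: int, nobs: int, method: str, alpha: float
) -> MetricEstimate:
    if nobs == 0:
        return MetricEstimate(value=None, defined=False)
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    low, high = proportion_confint(count, nobs, alpha=alpha, method=sm_method)
    clipped = False
    if method == "wald":
        # statsmodels pre-clips; recover whether the raw interval left [0, 1]
        p = count / nobs
        half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(p * (1 - p) / nobs)
        clipped = bool(p - half < 0 or p + half > 1)
    return MetricEstimate(
        value=count / nobs,
        ci_low=float(min(max(low, 0.0), 1.0)),
        ci_high=float(min(max(high, 0.0), 1.0)),
        ci_clipped=clipped,
    )


@dataclass(frozen=True)
class AccuracyReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    screen_prevalence_pct: float
    reference_prevalence_pct: float
    n: int


def accuracy_metrics(
    cm: ConfusionMatrix,
    ci: str = "wald",
    alpha: float = 0.05,
    cohort_n: Optional[int] = None,
) -> AccuracyReport:
    """Derive Se/Sp/PPV/NPV and both prevalences from a confusion matrix.

    ``ci`` selects the binomial interval: ``"wald"`` (normal approximation,
    clipped to [0,1] and flagged when clipped) or ``"wilson"`` (score
    interval, contained in [0,1] by construction).  Metrics whose denominator
    is zero are returned with ``defined=False``; the others are still
    computed.

    ``cohort_n`` sets the prevalence denominator when the matrix covers only
    the complete cases of a larger cohort (prevalence is then reported over
    the full cohort, as validation studies conventionally print it); by
    default the matrix total ``cm.n`` is used.
    """
    if ci not in ("wald", "wilson"):
        raise ValueError(f"unknown CI method {ci!r}; use 'wald' or 'wilson'")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    denom = cohort_n if cohort_n is not None else cm.n
    if denom < cm.n:
        raise ValueError(f"cohort_n {denom} smaller than matrix total {cm.n}")
    return AccuracyReport(
        sensitivity=_proportion_estimate(cm.tp, cm.tp + cm.fn, ci, alpha),
        specificity=_proportion_estimate(cm.tn, cm.tn + cm.fp, ci, alpha),
        ppv=_proportion_estimate(cm.tp, cm.tp + cm.fp, ci, alpha),
        npv=_proportion_estimate(cm.tn, cm.tn + cm.fn, ci, alpha),
        screen_prevalence_pct=100.0 * (cm.tp + cm.fp) / denom,
        reference_prevalence_pct=100.0 * (cm.tp + cm.fn) / denom,
        n=cm.n,
    )


@dataclass(frozen=True)
class ContingencyTable:
    """Observed counts with row/column labels (r x c, r,c >= 2)."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        if counts.sum() == 0:
            raise ValueError("contingency table has zero grand total")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float


def pearson_chi_square(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction by default (``yates=True`` enables it for 2x2
    tables).  ``min_expected`` is reported so callers can warn when the
    smallest expected count is below 5.  A zero row or column total makes an
    expected cell zero and is rejected.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column total; expected counts degenerate")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=yates)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected=expected,
        min_expected=float(expected.min()),
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: Optional[float]
    df: Optional[float]
    p_value: Optional[float]
    variant: str
    defined: bool = True


def two_sample_t(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    variant: str = "pooled",
) -> TTestResult:
    """Two-sample t test from summary statistics (two-sided).

    ``variant="pooled"`` uses the pooled-variance statistic with
    df = n_a + n_b - 2; ``"welch"`` uses the Welch statistic with
    Satterthwaite df.  With both SDs zero the statistic is undefined and the
    result is flagged rather than raising.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        return TTestResult(None, None, None, variant, defined=False)
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df: float = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue), variant)


@dataclass(frozen=True)
class ConcordanceRow:
    disorder: Disorder
    cm: ConfusionMatrix
    report: AccuracyReport
    dropped: int = 0


def flags_to_frame(
    index_flags: Mapping[str, Iterable[DisorderFlag]],
    reference_flags: Mapping[str, Iterable[DisorderFlag]],
) -> pd.DataFrame:
    """Convert per-patient flag lists to the flat paired-cohort layout.

    Returns a DataFrame indexed by record_id with one ``<disorder>_index``
    and one ``<disorder>_reference`` column per disorder seen; cells are 0/1
    or NaN where a patient lacks that flag.
    """
    rows: dict[str, dict[str, float]] = {}
    for source, mapping in (("index", index_flags), ("reference", reference_flags)):
        for record_id, flags in mapping.items():
            row = rows.setdefault(record_id, {})
            for flag in flags:
                row[f"{flag.disorder.value}_{source}"] = float(flag.probable)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "record_id"
    return frame.sort_index()


def concordance_table(
    cohort: pd.DataFrame,
    disorders: Optional[Sequence[Disorder]] = None,
    ci: str = "wald",
    alpha: float = 0.05,
) -> list[ConcordanceRow]:
    """Per-disorder concordance of the index screen against the reference.

    ``cohort`` is the flat paired layout (``<disorder>_index`` /
    ``<disorder>_reference`` 0/1 columns, NaN = missing).  Each disorder is
    analysed complete-case: patients missing either flag are dropped from
    that disorder's row and counted in ``dropped`` (count conservation:
    tp+fp+fn+tn+dropped = n).  A disorder with an index column but no
    reference column is a configuration error.
    """
    if disorders is None:
        present = {
            c.rsplit("_index", 1)[0] for c in cohort.columns if c.endswith("_index")
        }
        disorders = [d for d in CONCORDANCE_ORDER if d.value in present]
    rows: list[ConcordanceRow] = []
    for disorder in disorders:
        icol, rcol = f"{disorder.value}_index", f"{disorder.value}_reference"
        if icol not in cohort.columns:
            raise ValueError(f"cohort has no index column for {disorder.value}")
        if rcol not in cohort.columns:
            raise ValueError(
                f"{disorder.value} is screened by the index but absent from the "
                "reference standard; cannot compute concordance"
            )
        pair = cohort[[icol, rcol]].dropna()
        dropped = len(cohort) - len(pair)
        cm = build_confusion_matrix(
            pair[icol].astype(bool).tolist(), pair[rcol].astype(bool).tolist()
        )
        rows.append(
            ConcordanceRow(
                disorder=disorder,
                cm=cm,
                report=accuracy_metrics(cm, ci=ci, alpha=alpha, cohort_n=len(cohort)),
                dropped=dropped,
            )
        )
    return rows


def concordance_frame(rows: Iterable[ConcordanceRow]) -> pd.DataFrame:
    """Tabulate concordance rows (the validation-table layout) for export."""

    def fmt(m: MetricEstimate) -> Optional[float]:
        return None if not m.defined else round(m.value, 4)

    records = []
    for row in rows:
        r = row.report
        records.append(
            {
                "disorder": row.disorder.value,
                "sensitivity": fmt(r.sensitivity),
                "specificity": fmt(r.specificity),
                "ppv": fmt(r.ppv),
                "npv": fmt(r.npv),
                "tn": row.cm.tn,
                "fn": row.cm.fn,
                "tp": row.cm.tp,
                "fp": row.cm.fp,
                "screen_prevalence_pct": round(r.screen_prevalence_pct, 1),
                "reference_prevalence_pct": round(r.reference_prevalence_pct, 1),
                "n": r.n,
                "dropped": row.dropped,
            }
        )
    return pd.DataFrame.from_records(records)
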