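"""Cohort-level analytics for scored screening cohorts.

Spreadsheet-style descriptive statistics, stratified contingency tables,
per-band FOBT positivity summaries with exact binomial intervals, and the
pooled (equal-variance) two-sample t-test used to compare the per-band
positive and negative counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .records import FOBTResult, PatientRecord
from .scoring import (
    BandScheme,
    assign_band,
    band_labels,
    classify_bmi,
    compute_score,
)

__all__ = [
    "DescriptiveStats",
    "BandSummary",
    "TTestResult",
    "BandRisk",
    "descriptive_stats",
    "band_summary",
    "pooled_two_sample_t",
    "risk_estimates",
    "crosstab",
    "cohort_frame",
    "AGE_CLASS_LABELS",
]

#: Age-range classes used throughout the cohort tables (closed integer bins).
AGE_CLASS_LABELS = ("40-49", "50-59", "60-69", ">=70")


def age_class(age: int) -> str:
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    return ">=70"


@dataclass(frozen=True)
class DescriptiveStats:
    """Spreadsheet "Descriptive Statistics" block for one numeric variable.

    ``sd`` is the sample standard deviation (n-1 denominator), ``skewness``
    the adjusted Fisher-Pearson coefficient (the spreadsheet SKEW formula),
    and ``confidence_level_95`` the half-width of the 95% t-interval for the
    mean. ``skewness`` is None for degenerate (constant) samples;
    ``multimodal`` flags ties broken by reporting the smallest mode.
    """

    mean: float
    median: float
    mode: float
    sd: float
    skewness: float | None
    range: float
    minimum: float
    maximum: float
    count: int
    confidence_level_95: float
    multimodal: bool = False


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """Compute the descriptive block for a numeric sample (n >= 2)."""
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must all be finite")

    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        skew = None
    else:
        # adjusted Fisher-Pearson: n/((n-1)(n-2)) * sum(((x-mean)/s)^3)
        if n < 3:
            skew = None
        else:
            skew = float(n / ((n - 1) * (n - 2)) * np.sum(((x - mean) / sd) ** 3))

    counts = Counter(x.tolist())
    top = max(counts.values())
    modes = sorted(v for v, c in counts.items() if c == top)
    half_width = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))

    return DescriptiveStats(
        mean=mean,
        median=float(np.median(x)),
        mode=modes[0],
        sd=sd,
        skewness=skew,
        range=float(np.max(x) - np.min(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        count=int(n),
        confidence_level_95=half_width,
        multimodal=len(modes) > 1,
    )


@dataclass(frozen=True)
class BandCounts:
    """Positive/negative FOBT counts for one risk band."""

    n_pos: int
    n_neg: int

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def pos_rate(self) -> float | None:
        """Positive rate in percent; None for an empty band."""
        return None if self.n == 0 else 100.0 * self.n_pos / self.n

    @property
    def neg_rate(self) -> float | None:
        return None if self.n == 0 else 100.0 * self.n_neg / self.n


@dataclass(frozen=True)
class BandSummary:
    """Per-band FOBT counts and rates for a scored cohort (one scheme)."""

    scheme: BandScheme
    bands: dict[str, BandCounts]

    @property
    def n(self) -> int:
        return sum(b.n for b in self.bands.values())

    @property
    def total_positives(self) -> int:
        return sum(b.n_pos for b in self.bands.values())

    def pos_counts(self) -> tuple[int, ...]:
        return tuple(self.bands[lab].n_pos for lab in band_labels(self.scheme))

    def neg_counts(self) -> tuple[int, ...]:
        return tuple(self.bands[lab].n_neg for lab in band_labels(self.scheme))


def band_summary(
    cohort: Iterable[PatientRecord], scheme: BandScheme | str = BandScheme.FOUR_BAND
) -> BandSummary:
    """Tabulate FOBT outcomes by risk band.

    Every record must carry a definite FOBT result; untested records are a
    caller error (filter them out first).
    """
    scheme = BandScheme(scheme)
    records = list(cohort)
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    counts = {lab: [0, 0] for lab in band_labels(scheme)}
    for rec in records:
        if rec.fobt is FOBTResult.MISSING:
            raise ValueError(f"record {rec.id!r} has no FOBT result")
        lab = assign_band(compute_score(rec).total, scheme)
        counts[lab][0 if rec.fobt is FOBTResult.POSITIVE else 1] += 1
    return BandSummary(
        scheme=scheme,
        bands={lab: BandCounts(n_pos=p, n_neg=q) for lab, (p, q) in counts.items()},
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_one_tailed: float
    p_two_tailed: float
    method: str = field(default="pooled two-sample (equal variance)")


def pooled_two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Equal-variance two-sample t-test with pooled standard deviation.

    df = n_a + n_b - 2. The one-tailed p is the tail probability in the
    direction of the observed difference (half the two-tailed p).
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    df = int(x.size + y.size - 2)
    pooled_var = (
        (x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1)
    ) / df
    if pooled_var == 0.0:
        if np.mean(x) == np.mean(y):
            return TTestResult(t=0.0, df=df, p_one_tailed=0.5, p_two_tailed=1.0)
        raise ValueError(
            "zero pooled variance with unequal means: t is undefined"
        )
    res = stats.ttest_ind(x, y, equal_var=True)
    t = float(res.statistic)
    p_two = float(res.pvalue)
    return TTestResult(t=t, df=df, p_one_tailed=p_two / 2.0, p_two_tailed=p_two)


@dataclass(frozen=True)
class BandRisk:
    """Per-band positive rate (percent) with a 95% binomial interval."""

    n_pos: int
    n: int
    rate: float | None
    ci_low: float | None
    ci_high: float | None
    method: str


def risk_estimates(
    summary: BandSummary, ci_method: str = "clopper-pearson"
) -> dict[str, BandRisk]:
    """Per-band positivity with 95% confidence intervals, in percent.

    ``clopper-pearson`` gives the exact (beta-quantile) interval; ``wilson``
    is accepted as an alternative. Point rates are identical to the band
    summary's. Empty bands yield undefined (None) estimates.
    """
    methods = {"clopper-pearson": "beta", "wilson": "wilson"}
    if ci_method not in methods:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    out: dict[str, BandRisk] = {}
    for lab, bc in summary.bands.items():
        if bc.n == 0:
            out[lab] = BandRisk(0, 0, None, None, None, ci_method)
            continue
        lo, hi = proportion_confint(bc.n_pos, bc.n, alpha=0.05, method=methods[ci_method])
        out[lab] = BandRisk(
            n_pos=bc.n_pos,
            n=bc.n,
            rate=bc.pos_rate,
            ci_low=100.0 * float(lo),
            ci_high=100.0 * float(hi),
            method=ci_method,
        )
    return out


# -- contingency tables ------------------------------------------------------

#: Derivable stratification factors, by name.
_FACTOR_ORDERS = {
    "gender": ["male", "female"],
    "fobt": ["positive", "negative"],
    "bmi_category": [
        "underweight",
        "normal",
        "overweight",
        "obese_I",
        "obese_II",
        "obese_III",
    ],
    "age_class": list(AGE_CLASS_LABELS),
    "n_comorbidities": [0, 1, 2, 3],
    "dm": [False, True],
    "dysl": [False, True],
    "hta": [False, True],
}


def cohort_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a dataframe with all derivable factors and scores."""
    rows = []
    for rec in cohort:
        bd = compute_score(rec)
        rows.append(
            {
                "id": rec.id,
                "gender": rec.gender.value,
                "age": rec.age,
                "bmi": rec.bmi,
                "current_smoker": rec.current_smoker,
                "dm": rec.dm,
                "dysl": rec.dysl,
                "hta": rec.hta,
                "fobt": rec.fobt.value,
                "residence": rec.residence.value,
                "bmi_category": classify_bmi(rec.bmi).value,
                "age_class": age_class(rec.age),
                "n_comorbidities": rec.n_comorbidities,
                "age_points": bd.age_points,
                "gender_points": bd.gender_points,
                "smoking_points": bd.smoking_points,
                "bmi_points": bd.bmi_points,
                "comorbidity_points": bd.comorbidity_points,
                "total": bd.total,
            }
        )
    return pd.DataFrame(rows)


def crosstab(
    cohort: Iterable[PatientRecord],
    rows: str | Sequence[str],
    cols: str | Sequence[str],
    percent: str | None = None,
) -> pd.DataFrame:
    """Counts (and optional percentages) stratified by derivable factors.

    ``rows``/``cols`` name one or more factors among gender, fobt,
    bmi_category, age_class, n_comorbidities, dm, dysl, hta. ``percent``
    selects a denominator: "cohort" (percent of the whole cohort, the
    convention of the BMI-by-FOBT table) or "row"; None returns raw counts.
    Marginal totals always sum to the cohort size.
    """
    frame = cohort_frame(cohort)
    if frame.empty:
        raise ValueError("cannot tabulate an empty cohort")

    def as_factors(spec: str | Sequence[str]) -> list[str]:
        names = [spec] if isinstance(spec, str) else list(spec)
        for name in names:
            if name not in _FACTOR_ORDERS:
                raise ValueError(
                    f"unknown factor {name!r}; available: {sorted(_FACTOR_ORDERS)}"
                )
        return names

    row_names, col_names = as_factors(rows), as_factors(cols)

    def categorical(name: str) -> pd.Categorical:
        order = _FACTOR_ORDERS[name]
        return pd.Categorical(frame[name], categories=order, ordered=True)

    table = pd.crosstab(
        index=[pd.Series(categorical(n), name=n) for n in row_names],
        columns=[pd.Series(categorical(n), name=n) for n in col_names],
        dropna=False,
    )
    if percent is None:
        return table
    if percent == "cohort":
        return 100.0 * table / len(frame)
    if percent == "row":
        return 100.0 * table.div(table.sum(axis=1), axis=0)
    raise ValueError(f"percent must be None, 'cohort' or 'row', got {percent!r}")
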