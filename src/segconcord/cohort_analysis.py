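"""Cohort-level aggregation of per-case agreement metrics.

Metric distributions over segmentation cohorts are typically skewed
(most cases agree well, a tail does not), so central tendency is
summarised by the median with the interquartile range, and uncertainty
by a seeded percentile bootstrap of the median.  Low-agreement cases are
triaged into fixed Dice bins for manual review, and stratum effects
(scanner, anatomy) are screened with an ordinary linear-model ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSummary",
    "TriageReport",
    "summarize",
    "summarize_by_stratum",
    "compare_strata",
    "triage_discordant",
    "TRIAGE_BIN_EDGES",
]

# Interior bin edges for discordance triage; the top bin closes at the
# triage threshold itself.
TRIAGE_BIN_EDGES = (0.2, 0.4, 0.6)


@dataclass(frozen=True)
class CohortSummary:
    """Median / IQR / bootstrap CI of one metric over a case set."""

    metric_name: str
    n: int
    median: float
    iqr: float
    ci_low: float
    ci_high: float
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.iqr < 0:
            raise ValueError("IQR cannot be negative")
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"median {self.median}"
            )


@dataclass(frozen=True)
class TriageReport:
    """Cases below the Dice triage threshold, binned for review.

    ``bin_counts`` covers [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,threshold);
    ``flagged_cases`` maps each flagged case id to its bin index.
    """

    threshold: float
    bin_counts: tuple[int, int, int, int]
    flagged_cases: dict[str, int]
    n_total: int

    @property
    def n_flagged(self) -> int:
        return sum(self.bin_counts)


def summarize(
    values: Iterable[float],
    metric_name: str = "metric",
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    stratum: str | None = None,
) -> CohortSummary:
    """Median, IQR (Q3-Q1) and bootstrap percentile CI of the median.

    Quantiles use linear interpolation between order statistics.  The
    bootstrap resamples with replacement under ``seed``; with a single
    observation the CI degenerates to the value itself.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    med = float(np.median(arr))
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation default
    if arr.size >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
        boot_medians = np.median(arr[idx], axis=1)
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boot_medians, [alpha / 2, 1 - alpha / 2])
        # Percentile intervals of a median can exclude the point estimate
        # on tiny/degenerate samples; widen to bracket it.
        lo, hi = min(float(lo), med), max(float(hi), med)
    else:
        lo = hi = med
    return CohortSummary(
        metric_name=metric_name,
        n=int(arr.size),
        median=med,
        iqr=float(q3 - q1),
        ci_low=lo,
        ci_high=hi,
        stratum=stratum,
    )


def summarize_by_stratum(
    metrics: pd.DataFrame,
    value_col: str,
    covariate: str,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[CohortSummary]:
    """Pooled summary followed by one summary per stratum level.

    Levels are processed in sorted order; each stratum must be nonempty
    (guaranteed by grouping on observed values).
    """
    if covariate not in metrics.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    if value_col not in metrics.columns:
        raise KeyError(f"unknown value column {value_col!r}")
    out = [
        summarize(
            metrics[value_col], metric_name=value_col, ci_level=ci_level,
            n_boot=n_boot, seed=seed, stratum=None,
        )
    ]
    for level in sorted(metrics[covariate].unique(), key=str):
        sub = metrics.loc[metrics[covariate] == level, value_col]
        out.append(
            summarize(
                sub, metric_name=value_col, ci_level=ci_level,
                n_boot=n_boot, seed=seed, stratum=f"{covariate}={level}",
            )
        )
    return out


def compare_strata(
    metrics: pd.DataFrame,
    value_col: str,
    factors: Sequence[str],
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen factor effects on a metric with a linear-model ANOVA.

    Fits ``value ~ factor_1 + ... [+ covariates]`` by OLS and reports a
    type-II F statistic and p-value per factor, flagging significance at
    ``alpha``.  Continuous covariates (e.g. age, volume) enter the model
    as adjustment terms and are reported too.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    covariates = list(covariates or [])
    for name in [value_col, *factors, *covariates]:
        if name not in metrics.columns:
            raise KeyError(f"column {name!r} not in metrics table")
    if not factors:
        raise ValueError("need at least one factor")
    for f in factors:
        levels = metrics[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        counts = metrics.groupby(f, observed=True)[value_col].count()
        if (counts < 2).any():
            raise ValueError(f"factor {f!r} has a cell with fewer than 2 cases")
    labels = {f"C(Q('{f}'))": f for f in factors}
    labels.update({f"Q('{c}')": c for c in covariates})
    y = metrics[value_col].to_numpy(dtype=float)
    total_ss = float(((y - y.mean()) ** 2).sum())
    if total_ss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2 * len(y)):
        # Constant response in every cell: no effect anywhere.
        return pd.DataFrame(
            [
                {
                    "term": name,
                    "kind": "factor" if name in factors else "covariate",
                    "F": 0.0,
                    "p_value": 1.0,
                    "significant": False,
                }
                for name in labels.values()
            ]
        )
    formula = f"Q('{value_col}') ~ " + " + ".join(labels.keys())
    model = smf.ols(formula, data=metrics).fit()
    table = anova_lm(model, typ=2)
    rows = []
    for term, name in labels.items():
        ss = float(table.loc[term, "sum_sq"])
        fstat = float(table.loc[term, "F"])
        pval = float(table.loc[term, "PR(>F)"])
        if not np.isfinite(fstat):
            # Zero residual variance with a nonzero effect: report as a
            # certain effect rather than NaN.
            fstat, pval = ((0.0, 1.0) if ss <= 1e-12 * total_ss else (np.inf, 0.0))
        rows.append(
            {
                "term": name,
                "kind": "factor" if name in factors else "covariate",
                "F": fstat,
                "p_value": pval,
                "significant": bool(pval < alpha),
            }
        )
    return pd.DataFrame(rows)


def triage_discordant(
    dsc_by_case: Mapping[str, float] | pd.DataFrame | pd.Series,
    threshold: float = 0.8,
) -> TriageReport:
    """Flag cases with DSC below ``threshold`` into four review bins.

    Bins are half-open on the left edge: [0,0.2), [0.2,0.4), [0.4,0.6)
    and [0.6,threshold).  Counts are conserved: flagged + unflagged
    equals the number of cases.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(dsc_by_case, pd.DataFrame):
        series = dsc_by_case.set_index("case_id")["dsc"]
    elif isinstance(dsc_by_case, pd.Series):
        series = dsc_by_case
    else:
        series = pd.Series(dict(dsc_by_case), dtype=float)
    vals = series.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("DSC values must lie in [0, 1]")
    counts = [0, 0, 0, 0]
    flagged: dict[str, int] = {}
    for case_id, v in series.items():
        if v >= threshold:
            continue
        b = int(np.digitize(v, TRIAGE_BIN_EDGES, right=False))
        counts[b] += 1
        flagged[str(case_id)] = b
    return TriageReport(
        threshold=float(threshold),
        bin_counts=tuple(counts),  # type: ignore[arg-type]
        flagged_cases=flagged,
        n_total=int(series.size),
    )
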