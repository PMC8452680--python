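"""Cohort-level statistics: Fisher exact, t-tests, survival, differential
expression and alteration-frequency summaries.

Statistical machinery comes from the standard stack (scipy, statsmodels,
lifelines); this module pins the exact variants used — two-sided Fisher
by the point-probability rule, Welch t-test by default, product-limit
survival with "not reached" medians, one-way ANOVA with
Benjamini-Hochberg correction — and shapes their outputs for cohort
reports and oncoplot-style summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import classify

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact_2x2",
    "t_test_two_sided",
    "km_curve",
    "log_rank",
    "anova_de",
    "alteration_frequencies",
    "KMResult",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the classical point-probability definition: the sum of
    probabilities, over all tables with the observed margins, of tables
    whose point probability does not exceed the observed one (with a
    tiny relative slack for floating-point ties).  A table with a zero
    margin carries no information; p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1")
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


def t_test_two_sided(x, y, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (default) or pooled Student.

    Returns (t, p).  If both groups have zero variance and equal means
    the statistic is 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class KMResult:
    """Product-limit estimate with a step table and risk counts."""

    table: pd.DataFrame          # time, at_risk, events, censored, survival
    median: float | None         # None when never reaching S <= 0.5

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


def km_curve(times, events) -> KMResult:
    """Kaplan-Meier product-limit survival curve with risk table.

    S(t) is the product over event times <= t of (1 - d_i / n_i);
    censored subjects leave the risk set without dropping the curve.
    The median is the first time with S <= 0.5, or None ("not reached").
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ev = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    table = pd.DataFrame({
        "time": ev["time"],
        "at_risk": ev["at_risk"].astype(int),
        "events": ev["observed"].astype(int),
        "censored": ev["censored"].astype(int),
        "survival": surv,
    })
    med = kmf.median_survival_time_
    return KMResult(table=table, median=None if np.isinf(med) else float(med))


def log_rank(times, events, groups) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi2, p).

    Standard observed-minus-expected statistic over the pooled event
    times, chi-square with (groups - 1) degrees of freedom.  With no
    events at all, p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 groups")
    if not events.any():
        return 0.0, 1.0
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def anova_de(expression: pd.DataFrame, group_labels: pd.Series,
             n_top: int = 100) -> tuple[pd.DataFrame, pd.DataFrame, tuple]:
    """One-way ANOVA differential expression with FDR correction.

    ``expression`` is samples x genes.  Per gene: F statistic and
    p-value across groups, Benjamini-Hochberg q-value; genes with zero
    variance everywhere are excluded with a warning.  Returns the
    ranked gene table (sorted by q then p), the per-gene z-scored
    samples x top-n submatrix, and the Ward sample clustering of that
    submatrix (linkage matrix, leaf order).
    """
    labels = group_labels.loc[expression.index]
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    X = expression.to_numpy(dtype=float)
    group_arrays = [X[(labels == g).to_numpy()] for g in counts.index]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*group_arrays, axis=0)
    valid = np.isfinite(F) & np.isfinite(p)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} zero-variance gene(s) excluded from ANOVA")
    genes = expression.columns[valid]
    _, q, _, _ = multipletests(p[valid], method="fdr_bh")
    ranked = pd.DataFrame({"gene": genes, "F": F[valid], "p": p[valid], "q": q})
    ranked = ranked.sort_values(["q", "p", "gene"], kind="stable")
    ranked = ranked.reset_index(drop=True)

    top = ranked["gene"].head(n_top).tolist()
    sub = expression.loc[:, top]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    linkage = classify.ward_cluster(z)
    return ranked, z, linkage


def alteration_frequencies(calls: pd.DataFrame, groups: pd.Series,
                           altered_codes: tuple[str, ...] = (
                               "high_amplification", "gain", "loss",
                               "homozygous_deletion"),
                           co_occurrence: list[tuple[str, str]] | None = None,
                           ) -> dict:
    """Oncoplot-style frequency report for a samples x alterations matrix.

    ``calls`` holds status codes; a sample counts as altered for a
    column when its status is in ``altered_codes``; "not_assessable" /
    missing samples drop out of the denominator.  Returns per-group and
    pooled counts, denominators and percents (raw fraction plus
    round-half-even integer percent), declared co-occurrence counts,
    and a memo-sorted matrix for display (alterations by descending
    frequency, samples lexicographically by alteration presence).
    """
    groups = groups.loc[calls.index]
    assessable = calls.notna() & (calls != "not_assessable")
    altered = calls.isin(altered_codes) & assessable

    freq: dict[str, dict] = {}
    for alt in calls.columns:
        denom = int(assessable[alt].sum())
        count = int(altered[alt].sum())
        entry = {
            "count": count, "denominator": denom,
            "fraction": count / denom if denom else np.nan,
            "percent": _round_percent(count, denom),
            "by_group": {},
        }
        for g in sorted(groups.unique()):
            gi = groups == g
            gd = int(assessable.loc[gi, alt].sum())
            gc = int(altered.loc[gi, alt].sum())
            entry["by_group"][g] = {"count": gc, "denominator": gd,
                                    "percent": _round_percent(gc, gd)}
        freq[alt] = entry

    co = {}
    for a, b in (co_occurrence or []):
        both = int((altered[a] & altered[b]).sum())
        denom = int((assessable[a] & assessable[b]).sum())
        co[f"{a}+{b}"] = {"count": both, "denominator": denom,
                          "percent": _round_percent(both, denom)}

    # memo-sort: alterations by descending frequency, samples by their
    # presence pattern read most-frequent-alteration-first
    alt_order = sorted(calls.columns,
                       key=lambda a: (-freq[a]["count"], a))
    pattern = altered[alt_order].astype(int)
    sample_order = sorted(calls.index,
                          key=lambda s: (tuple(-pattern.loc[s]), s))
    ordered = calls.loc[sample_order, alt_order]
    return {"frequencies": freq, "co_occurrence": co, "ordered_matrix": ordered}


def _round_percent(count: int, denom: int) -> float | None:
    """Round-half-even integer percent (raw fractions travel alongside)."""
    if not denom:
        return None
    return float(np.round(100.0 * count / denom))
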