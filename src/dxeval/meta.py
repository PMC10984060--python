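"""Meta-evaluation statistics: how well do automated metrics track human
judgment?

The alignment question is answered with rank and linear correlations
(Spearman ρ, Pearson r, Kendall τ_b) between each metric and the human
composite score, a paired Wilcoxon signed-rank test of location, a test
for *comparing* two metrics' correlations with the same human score
(overlapping dependent correlations), and interrater agreement (Cohen's
kappa against a 0.70 threshold).

Confidence intervals: Pearson uses the Fisher z transform.  For the rank
correlations no finite-sample interval is standard; both a seeded
percentile bootstrap (default) and a Fisher-z interval with an adjusted
variance (Bonett–Wright for ρ, Fieller for τ) are provided, tagged with
the method used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "CorrelationResult",
    "CorrelationReport",
    "AgreementReport",
    "pearson_r",
    "spearman_rho",
    "kendall_tau_b",
    "wilcoxon_signed_rank",
    "compare_dependent_correlations",
    "cohen_kappa",
    "correlation_table",
]

CIMethod = Literal["fisher", "bootstrap", "fisher-adjusted"]


@dataclass(frozen=True)
class PairedSeries:
    """Human and metric values aligned by record identifier."""

    ids: tuple[str, ...]
    human: np.ndarray
    metric: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.human, dtype=float)
        m = np.asarray(self.metric, dtype=float)
        if not (len(self.ids) == len(h) == len(m)):
            raise ValueError("ids, human and metric must have equal length")
        if len(h) < 3:
            raise ValueError("paired series needs at least 3 observations")
        if np.isnan(h).any() or np.isnan(m).any():
            raise ValueError("paired series must be aligned with no missing "
                             "values; drop incomplete records first")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "human", h)
        object.__setattr__(self, "metric", m)

    @property
    def n(self) -> int:
        return len(self.human)


@dataclass(frozen=True)
class CorrelationResult:
    """One coefficient with its CI, p-value and CI-method tag."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    ci_method: str
    degenerate: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    rescaled: bool
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    """All alignment statistics for one metric/target pairing."""

    spearman: CorrelationResult
    pearson: CorrelationResult
    kendall: CorrelationResult
    wilcoxon: WilcoxonResult
    n: int


@dataclass(frozen=True)
class AgreementReport:
    kappa: float
    weights: str
    threshold: float
    passed: bool
    n: int
    degenerate: bool = False
    per_component: dict[str, float] = field(default_factory=dict)


def _fisher_ci(
    r: float, n: int, se: float, alpha: float = 0.05
) -> tuple[float, float]:
    """CI on a correlation via Fisher's z with the given SE of z."""
    r = min(max(r, -0.999999), 0.999999)
    z = math.atanh(r)
    zc = stats.norm.ppf(1 - alpha / 2)
    return math.tanh(z - zc * se), math.tanh(z + zc * se)


def _bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    stat,
    n_resamples: int,
    seed: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile bootstrap over paired resamples."""
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_resamples, n))
    vals = np.empty(n_resamples)
    for b in range(n_resamples):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            vals[b] = np.nan  # degenerate resample carries no information
        else:
            vals[b] = stat(xb, yb)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    return (
        float(np.quantile(vals, alpha / 2)),
        float(np.quantile(vals, 1 - alpha / 2)),
    )


def _degenerate(name: str, n: int, method: str) -> CorrelationResult:
    logger.warning("%s undefined on constant series (n=%d)", name, n)
    nan = float("nan")
    return CorrelationResult(name, nan, nan, nan, nan, n, method, True)


def pearson_r(series: PairedSeries, alpha: float = 0.05) -> CorrelationResult:
    """Product-moment correlation with a Fisher-z CI."""
    x, y = series.human, series.metric
    if series.n < 4:
        raise ValueError("pearson_r requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _degenerate("pearson_r", series.n, "fisher")
    res = stats.pearsonr(x, y)
    lo, hi = _fisher_ci(
        res.statistic, series.n, 1 / math.sqrt(series.n - 3), alpha
    )
    return CorrelationResult(
        "pearson_r", float(res.statistic), lo, hi, float(res.pvalue),
        series.n, "fisher",
    )


def spearman_rho(
    series: PairedSeries,
    ci_method: CIMethod = "bootstrap",
    n_resamples: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Rank correlation (Pearson on midranks, average ranks for ties).

    CI: seeded percentile bootstrap by default, or Fisher z with the
    Bonett–Wright adjusted variance (1 + ρ²/2)/(n − 3).
    """
    x, y = series.human, series.metric
    if series.n < 4:
        raise ValueError("spearman_rho requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _degenerate("spearman_rho", series.n, ci_method)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(
            x, y, lambda a, b: stats.spearmanr(a, b).statistic,
            n_resamples, seed, alpha,
        )
    else:
        se = math.sqrt((1 + rho**2 / 2) / (series.n - 3))
        lo, hi = _fisher_ci(rho, series.n, se, alpha)
        ci_method = "fisher-adjusted"
    return CorrelationResult(
        "spearman_rho", rho, lo, hi, float(res.pvalue), series.n, ci_method
    )


def kendall_tau_b(
    series: PairedSeries,
    ci_method: CIMethod = "bootstrap",
    n_resamples: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Kendall's τ_b with tie correction.

    τ_b = (C − D) / sqrt((n0 − n1)(n0 − n2)) with C/D the concordant and
    discordant pair counts and n1, n2 the tie corrections per series.
    CI: seeded bootstrap (default) or Fisher z with Fieller's variance
    0.437/(n − 4).
    """
    x, y = series.human, series.metric
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _degenerate("kendall_tau_b", series.n, ci_method)
    res = stats.kendalltau(x, y, variant="b")
    tau = float(res.statistic)
    if ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(
            x, y, lambda a, b: stats.kendalltau(a, b, variant="b").statistic,
            n_resamples, seed, alpha,
        )
    else:
        if series.n < 5:
            raise ValueError("fisher-adjusted CI for tau requires n >= 5")
        se = math.sqrt(0.437 / (series.n - 4))
        lo, hi = _fisher_ci(tau, series.n, se, alpha)
        ci_method = "fisher-adjusted"
    return CorrelationResult(
        "kendall_tau_b", tau, lo, hi, float(res.pvalue), series.n, ci_method
    )


EXACT_WILCOXON_MAX_N = 12


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks of |d|."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all 2^n sign assignments.

    Under the null each difference is independently positive or negative
    with probability 1/2, with the observed |d| midranks held fixed.
    Two-sided p doubles the smaller tail (capped at 1).
    """
    w_obs, ranks = _signed_rank_statistic(d)
    n = len(d)
    # distribution of W+ over all sign vectors via subset-sum convolution
    # on the midranks (doubled to stay integral with .5 ranks)
    scaled = np.round(ranks * 2).astype(int)
    total = scaled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= counts.sum()
    w_scaled = int(round(w_obs * 2))
    p_le = counts[: w_scaled + 1].sum()
    p_ge = counts[w_scaled:].sum()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    series: PairedSeries, rescale: bool = True
) -> WilcoxonResult:
    """Paired signed-rank test on human − metric differences.

    Zero differences are discarded (the classic convention).  For n ≤ 12
    effective pairs the exact null distribution is enumerated over sign
    assignments; above that a normal approximation with continuity and
    tie corrections is used.  By default the metric is min-max rescaled
    to [0, 1] first so that unbounded metrics (log-probabilities) face
    the bounded human score on a common scale; pass ``rescale=False`` for
    raw pairing.
    """
    metric = series.metric
    rescaled = False
    if rescale:
        span = metric.max() - metric.min()
        if span > 0:
            metric = (metric - metric.min()) / span
            rescaled = True
    d = series.human - metric
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        logger.warning("wilcoxon: all paired differences are zero")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", rescaled, True)
    if n_eff < 5:
        logger.warning(
            "wilcoxon: only %d nonzero differences; exact p reported but "
            "resolution is limited", n_eff,
        )
    if n_eff <= EXACT_WILCOXON_MAX_N:
        w, p = _exact_signed_rank_p(d)
        return WilcoxonResult(w, p, n_eff, "exact", rescaled)
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, method="approx"
    )
    return WilcoxonResult(
        float(res.statistic), float(res.pvalue), n_eff, "normal-approx",
        rescaled,
    )


def compare_dependent_correlations(
    human: np.ndarray,
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    method: Literal["steiger", "bootstrap"] = "steiger",
    n_resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided test of ρ(human, A) = ρ(human, B) with A, B observed on
    the same records (overlapping dependent correlations).

    Default is Steiger's z (Williams-type, using the back-transformed
    mean correlation); the bootstrap alternative resamples records and
    reads the p-value off the percentile distribution of the difference.
    Returns ``(z, p)`` for Steiger and ``(difference, p)`` for bootstrap.
    """
    h = np.asarray(human, dtype=float)
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    n = len(h)
    if not (len(a) == len(b) == n):
        raise ValueError("all three series must be aligned")
    if n < 10:
        raise ValueError("dependent-correlation comparison requires n >= 10")
    for s, name in ((h, "human"), (a, "metric_a"), (b, "metric_b")):
        if np.all(s == s[0]):
            logger.warning("%s is constant; comparison undefined", name)
            return float("nan"), float("nan")

    r_ha = float(stats.pearsonr(h, a).statistic)
    r_hb = float(stats.pearsonr(h, b).statistic)
    r_ab = float(stats.pearsonr(a, b).statistic)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        diff_obs = r_ha - r_hb
        idx = rng.integers(0, n, size=(n_resamples, n))
        diffs = np.empty(n_resamples)
        for i in range(n_resamples):
            hh, aa, bb = h[idx[i]], a[idx[i]], b[idx[i]]
            if np.all(hh == hh[0]) or np.all(aa == aa[0]) or np.all(bb == bb[0]):
                diffs[i] = np.nan
                continue
            diffs[i] = (
                stats.pearsonr(hh, aa).statistic
                - stats.pearsonr(hh, bb).statistic
            )
        diffs = diffs[~np.isnan(diffs)]
        # percentile p: how far 0 sits in the bootstrap distribution
        p_lo = np.mean(diffs <= 0)
        p_hi = np.mean(diffs >= 0)
        p = min(1.0, 2 * min(p_lo, p_hi))
        return float(diff_obs), float(p)

    if abs(r_ha - r_hb) < 1e-15:
        return 0.0, 1.0
    # Steiger / Williams: z on Fisher-transformed r_ha, r_hb with the
    # covariance induced by the shared variable
    rm2 = ((r_ha + r_hb) / 2) ** 2
    det_term = r_ab * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r_ab**2)
    cov = det_term / (1 - rm2) ** 2
    z_ha = math.atanh(min(max(r_ha, -0.999999), 0.999999))
    z_hb = math.atanh(min(max(r_hb, -0.999999), 0.999999))
    z = (z_ha - z_hb) * math.sqrt((n - 3) / (2 - 2 * cov))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def cohen_kappa(
    rater_a: Sequence,
    rater_b: Sequence,
    weights: Literal["none", "linear", "quadratic"] = "none",
    threshold: float = 0.70,
    per_component: dict[str, tuple[Sequence, Sequence]] | None = None,
) -> AgreementReport:
    """Cohen's kappa = (p_o − p_e)/(1 − p_e), optionally weighted.

    ``per_component`` maps component names to label-vector pairs for a
    breakdown; the headline kappa is computed on the full vectors.  When
    both raters are constant and identical, chance agreement p_e = 1 and
    kappa is undefined; it is reported as 1 with a degenerate flag (the
    raters do agree perfectly).
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if len(a) != len(b):
        raise ValueError("rater label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty label vectors")

    def _kappa(u, v) -> tuple[float, bool]:
        if len(set(u) | set(v)) == 1:
            return 1.0, True
        w = None if weights == "none" else weights
        return float(cohen_kappa_score(u, v, weights=w)), False

    kappa, degenerate = _kappa(a, b)
    breakdown = {}
    if per_component:
        for name, (u, v) in per_component.items():
            breakdown[name], _ = _kappa(np.asarray(u), np.asarray(v))
    return AgreementReport(
        kappa=kappa, weights=weights, threshold=threshold,
        passed=kappa >= threshold, n=len(a), degenerate=degenerate,
        per_component=breakdown,
    )


DEFAULT_COMPONENTS = ("D",)
COMPONENT_COLUMNS = {
    "D": "D",
    "plausibility": "p_bar",
    "specificity": "s_bar",
    "omission": "o_bar",
}


def correlation_table(
    human_scores: pd.DataFrame,
    metric_scores: pd.DataFrame,
    components: Sequence[str] = DEFAULT_COMPONENTS,
    seed: int = 0,
    ci_method: CIMethod = "bootstrap",
    n_resamples: int = 2000,
    max_join_loss: float = 0.1,
    holm: bool = False,
) -> pd.DataFrame:
    """Alignment report: one row per (metric, human component).

    ``human_scores`` is the scored-record table (record_id, p_bar, …, D);
    ``metric_scores`` the long metric table (pair_id, metric_name, value).
    Rows carry ρ, r and τ_b with CIs, and the Wilcoxon p.  An error is
    raised when the record_id join loses more than ``max_join_loss`` of
    the records.  ``holm`` applies a Holm step-down adjustment to the
    correlation p-values within each component (off by default: raw
    p-values are the field's reporting convention for this analysis).
    """
    bad = set(components) - set(COMPONENT_COLUMNS)
    if bad:
        raise KeyError(
            f"unknown component(s) {sorted(bad)}; "
            f"choose from {sorted(COMPONENT_COLUMNS)}"
        )
    wide = metric_scores.pivot_table(
        index="pair_id", columns="metric_name", values="value"
    )
    joined = human_scores.set_index("record_id").join(wide, how="inner")
    lost = 1 - len(joined) / max(len(human_scores), 1)
    if lost > max_join_loss:
        raise ValueError(
            f"record_id join lost {lost:.0%} of records "
            f"(limit {max_join_loss:.0%}); check identifier alignment"
        )

    rows = []
    for component in components:
        col = COMPONENT_COLUMNS[component]
        for metric_name in wide.columns:
            sub = joined[[col, metric_name]].dropna()
            series = PairedSeries(
                ids=tuple(sub.index.astype(str)),
                human=sub[col].to_numpy(),
                metric=sub[metric_name].to_numpy(),
            )
            rho = spearman_rho(series, ci_method, n_resamples, seed)
            r = pearson_r(series)
            tau = kendall_tau_b(series, ci_method, n_resamples, seed)
            wil = wilcoxon_signed_rank(series)
            rows.append(
                {
                    "component": component,
                    "metric_name": metric_name,
                    "n": series.n,
                    "spearman_rho": rho.estimate,
                    "spearman_ci_low": rho.ci_low,
                    "spearman_ci_high": rho.ci_high,
                    "spearman_p": rho.p_value,
                    "pearson_r": r.estimate,
                    "pearson_ci_low": r.ci_low,
                    "pearson_ci_high": r.ci_high,
                    "pearson_p": r.p_value,
                    "kendall_tau_b": tau.estimate,
                    "kendall_ci_low": tau.ci_low,
                    "kendall_ci_high": tau.ci_high,
                    "kendall_p": tau.p_value,
                    "wilcoxon_stat": wil.statistic,
                    "wilcoxon_p": wil.p_value,
                    "ci_method": rho.ci_method,
                }
            )
    table = pd.DataFrame(rows)
    if holm and not table.empty:
        for pcol in ("spearman_p", "pearson_p", "kendall_p"):
            for comp, grp in table.groupby("component"):
                adj = _holm(grp[pcol].to_numpy())
                table.loc[grp.index, pcol.replace("_p", "_p_holm")] = adj
    return table


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
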