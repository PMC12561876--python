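"""Paired-cohort statistical battery for pre/post stent metrics.

Each patient contributes one metric value at insertion (pre) and one at
follow-up (post); every test operates on the within-patient differences
``d = post - pre``:

* Shapiro-Wilk normality of the differences (a gate that is reported, not
  enforced: both the parametric and the rank test always run).
* Paired (dependent-sample) t-test, two-tailed.
* Wilcoxon signed-rank test, two-tailed; zero differences dropped, tied
  absolute differences mid-ranked, exact null distribution up to an effective
  n of 25 and a continuity- and tie-corrected normal approximation above.
* Cohen's d for paired samples, d = mean(diff) / sd(diff).
* Post hoc power of the two-tailed paired t-test via the noncentral t
  distribution with noncentrality d * sqrt(n) — the same computation G*Power
  performs for "difference between two dependent means".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedCohort",
    "CohortReport",
    "shapiro_wilk",
    "paired_t",
    "wilcoxon_signed_rank",
    "cohens_d_paired",
    "posthoc_power_paired_t",
    "analyze_cohort",
]

WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedCohort:
    """Paired pre/post values of one metric across patients."""

    patient_ids: list[str]
    pre_values: np.ndarray = field(repr=False)
    post_values: np.ndarray = field(repr=False)
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre_values, dtype=float)
        post = np.asarray(self.post_values, dtype=float)
        if pre.ndim != 1 or pre.shape != post.shape or len(self.patient_ids) != pre.size:
            raise ValueError("patient_ids, pre_values and post_values must have equal length")
        if pre.size < 2:
            raise ValueError("paired cohort needs at least 2 patients")
        if not (np.isfinite(pre).all() and np.isfinite(post).all()):
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "pre_values", pre)
        object.__setattr__(self, "post_values", post)

    @property
    def n(self) -> int:
        return int(self.pre_values.size)

    def differences(self) -> np.ndarray:
        return self.post_values - self.pre_values


@dataclass(frozen=True)
class CohortReport:
    """Full statistical report for one metric on one paired cohort.

    ``cohens_d`` is the unsigned magnitude (the form effect sizes are quoted
    in); ``cohens_d_signed`` keeps the direction (negative = decrease at
    follow-up).  ``degenerate`` flags a cohort whose differences have zero
    variance, for which the inferential fields are NaN.
    """

    metric_name: str
    n: int
    alpha: float
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    shapiro_W: float = float("nan")
    shapiro_p: float = float("nan")
    t_stat: float = float("nan")
    t_p: float = float("nan")
    df: int = 0
    wilcoxon_stat: float = float("nan")
    wilcoxon_p: float = float("nan")
    cohens_d: float = float("nan")
    cohens_d_signed: float = float("nan")
    power: float = float("nan")
    degenerate: bool = False


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={values.size}")
    if np.ptp(values) == 0:
        raise ValueError("zero variance")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, int]:
    """Two-tailed paired t-test on differences post - pre.

    Returns ``(t, p_two_tailed, df)`` with t = mean(d) / (sd(d) / sqrt(n)),
    df = n - 1, sd using the n-1 denominator.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return t, p, n - 1


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p for the signed-rank statistic with mid-ranked ties.

    Enumerates the null distribution of W+ over all 2^n equiprobable sign
    assignments by dynamic programming over doubled ranks (mid-ranks are
    half-integers, so doubling makes them exact integers).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    target = int(round(2.0 * w_plus))
    p_low = counts[: target + 1].sum()
    p_high = counts[target:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _signed_rank_normal_p(d: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = d.size
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("zero variance in signed ranks")
    z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def wilcoxon_signed_rank(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on differences post - pre.

    Zero differences are dropped before ranking (the dominant textbook
    convention, rather than Pratt's zero-rank method); tied absolute
    differences receive mid-ranks.  The reported statistic is
    W = min(W+, W-).  The null distribution is exact (full enumeration via
    dynamic programming) for effective n <= 25 and a continuity- and
    tie-corrected normal approximation above.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    w = min(w_plus, w_minus)
    if d.size <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        p = _signed_rank_normal_p(d, w_plus)
    return w, p


def cohens_d_paired(pre: np.ndarray, post: np.ndarray) -> float:
    """Cohen's d for paired samples: mean(diff) / sd(diff), n-1 denominator.

    The sign is retained (negative = decrease at follow-up); report the
    magnitude when quoting effect sizes.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return float(d.mean() / sd)


def posthoc_power_paired_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Post hoc power of the two-tailed paired t-test at effect size ``d``.

    The paired design reduces to a one-sample t-test on the differences, so
    power is computed from the noncentral t distribution with df = n - 1 and
    noncentrality delta = d * sqrt(n):

        power = P(T' > t*) + P(T' < -t*),   t* = t_{1 - alpha/2, n-1}.

    At d = 0 this equals alpha exactly.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if d < 0:
        raise ValueError(f"effect size magnitude must be >= 0, got {d}")
    df = n - 1
    ncp = d * np.sqrt(n)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def analyze_cohort(cohort: PairedCohort, alpha: float = 0.05) -> CohortReport:
    """Run the full battery on one paired cohort.

    Shapiro-Wilk is evaluated on the differences, then both the paired t-test
    and the Wilcoxon signed-rank test are run regardless of the normality
    outcome, followed by paired Cohen's d and post hoc power at ``alpha``.
    A cohort with zero-variance differences is returned flagged degenerate
    instead of raising, with the inferential fields NaN.
    """
    pre, post = cohort.pre_values, cohort.post_values
    base = dict(
        metric_name=cohort.metric_name,
        n=cohort.n,
        alpha=alpha,
        pre_mean=float(pre.mean()),
        pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()),
        post_sd=float(post.std(ddof=1)),
    )
    diffs = cohort.differences()
    if diffs.std(ddof=1) == 0:
        return CohortReport(degenerate=True, **base)

    shapiro_W, shapiro_p = (float("nan"), float("nan"))
    if 3 <= cohort.n <= 5000:
        shapiro_W, shapiro_p = shapiro_wilk(diffs)
    t_stat, t_p, df = paired_t(pre, post)
    w_stat, w_p = wilcoxon_signed_rank(pre, post)
    d_signed = cohens_d_paired(pre, post)
    power = posthoc_power_paired_t(abs(d_signed), cohort.n, alpha)
    return CohortReport(
        shapiro_W=shapiro_W,
        shapiro_p=shapiro_p,
        t_stat=t_stat,
        t_p=t_p,
        df=df,
        wilcoxon_stat=w_stat,
        wilcoxon_p=w_p,
        cohens_d=abs(d_signed),
        cohens_d_signed=d_signed,
        power=power,
        degenerate=False,
        **base,
    )
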