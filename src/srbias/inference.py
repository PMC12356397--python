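"""Group-level statistics for the noise-ladder design.

Implements the analysis stack applied to the per-participant x noise-level
summaries: one-way repeated-measures ANOVA across noise levels, one-tailed
paired post-hoc tests against the zero-noise baseline with Benjamini-
Hochberg FDR adjustment, one-sample t-tests of the criterion against zero,
default (JZS) Bayes factors for the one-sample test and for a Pearson
correlation, and a-priori sample-size computation from the noncentral t
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = ["StatResult", "BayesResult", "PowerSpec", "rm_anova_oneway",
           "posthoc_vs_baseline", "fdr_bh", "one_sample_t",
           "jzs_bf_one_sample", "jzs_bf_correlation", "power_sample_size"]


@dataclass(frozen=True)
class StatResult:
    statistic: str                  # "F" or "t"
    value: float
    df: tuple[float, float] | float
    p_raw: float
    direction: str = "two-sided"    # "greater", "less" or "two-sided"
    p_corr: float | None = None
    cohens_d: float | None = None
    label: str | None = None        # e.g. the noise level of a post-hoc


@dataclass(frozen=True)
class BayesResult:
    ln_bf10: float
    prior_scale: float
    model: str                      # "one-sample-t" or "correlation"


@dataclass(frozen=True)
class PowerSpec:
    effect_size: float
    alpha: float
    power: float
    tails: int
    required_n: int
    achieved_power: float


def _as_matrix(data) -> np.ndarray:
    m = np.asarray(data, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a participants x levels matrix")
    if not np.isfinite(m).all():
        raise ValueError("matrix contains missing or non-finite cells")
    return m


def rm_anova_oneway(data) -> StatResult:
    """Classical within-subject one-way ANOVA (no sphericity correction).

    F = MS_levels / MS_(levels x subjects), df = (k-1, (k-1)(n-1)), for an
    n-participant x k-level complete matrix.
    """
    m = _as_matrix(data)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 levels")
    grand = m.mean()
    ss_levels = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_error = ss_total - ss_levels - ss_subjects
    df_levels, df_error = k - 1, (k - 1) * (n - 1)
    ms_levels = ss_levels / df_levels
    ms_error = ss_error / df_error
    # guard float-noise-level sums of squares in (near-)degenerate matrices
    tiny = 1e-12 * max(1.0, float(np.abs(m).max()) ** 2)
    if ms_error <= tiny:
        f = 0.0 if ms_levels <= tiny else np.inf
    else:
        f = ms_levels / ms_error
    p = float(stats.f.sf(f, df_levels, df_error))
    return StatResult("F", float(f), (float(df_levels), float(df_error)), p)


def one_sample_t(values, mu0: float = 0.0, tails: int = 2,
                 direction: str = "greater") -> StatResult:
    """t = (mean - mu0) / (sd/sqrt(n)); Cohen's d = (mean - mu0)/sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate variance: all observations identical")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tails == 2:
        p, dirn = 2.0 * stats.t.sf(abs(t), df), "two-sided"
    elif direction == "greater":
        p, dirn = stats.t.sf(t, df), "greater"
    else:
        p, dirn = stats.t.cdf(t, df), "less"
    return StatResult("t", float(t), float(df), float(p), direction=dirn,
                      cohens_d=float((x.mean() - mu0) / sd))


def posthoc_vs_baseline(data, baseline_level: int = 0,
                        direction: str = "greater",
                        labels=None) -> list[StatResult]:
    """One-tailed paired t-tests of each level against the baseline column.

    ``direction`` is the tested alternative for level minus baseline:
    "greater" for accuracy/d' (noise improves), "less" for criterion (noise
    reduces the bias).  Raw p values are BH-FDR adjusted across the k-1
    contrasts; Cohen's d is mean(diff)/sd(diff).
    """
    m = _as_matrix(data)
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if not 0 <= baseline_level < k:
        raise ValueError("baseline level not present")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    labels = list(labels) if labels is not None else list(range(k))
    results = []
    for j in range(k):
        if j == baseline_level:
            continue
        diff = m[:, j] - m[:, baseline_level]
        sd = diff.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"degenerate variance in contrast {labels[j]}")
        t = diff.mean() / (sd / np.sqrt(n))
        p = stats.t.sf(t, n - 1) if direction == "greater" \
            else stats.t.cdf(t, n - 1)
        results.append(StatResult("t", float(t), float(n - 1), float(p),
                                  direction=direction,
                                  cohens_d=float(diff.mean() / sd),
                                  label=str(labels[j])))
    adj = fdr_bh([r.p_raw for r in results])
    return [StatResult(r.statistic, r.value, r.df, r.p_raw, r.direction,
                       p_corr=float(a), cohens_d=r.cohens_d, label=r.label)
            for r, a in zip(results, adj)]


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def jzs_bf_one_sample(t: float, n: int, prior_scale: float = 0.707) -> BayesResult:
    """Default (JZS) Bayes factor for a one-sample t statistic.

    BF10 is the ratio of the marginal likelihood of t under a Cauchy(0, r)
    prior on the standardized effect (equivalently a mixture over the
    variance parameter g with an inverse-chi-square(1) weight) to the
    point-null likelihood; the integral over g is evaluated numerically.
    Returns the natural log of BF10.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    v = n - 1
    r2 = prior_scale ** 2

    def log_integrand(g):
        a = 1.0 + n * g * r2
        return (-0.5 * np.log(a)
                - 0.5 * (v + 1) * np.log1p(t * t / (a * v))
                - 0.5 * np.log(2 * np.pi) - 1.5 * np.log(g) - 1.0 / (2 * g))

    # peak-referenced integration keeps the quadrature stable for large |t|
    num, err = integrate.quad(lambda g: np.exp(log_integrand(g)),
                              0.0, np.inf, limit=300)
    if not np.isfinite(num) or num <= 0 or (err / num) > 1e-4:
        raise ArithmeticError(
            f"marginal-likelihood integration failed (value={num}, err={err})")
    log_den = -0.5 * (v + 1) * np.log1p(t * t / v)
    return BayesResult(float(np.log(num) - log_den), prior_scale,
                       "one-sample-t")


def _log_corr_density(r: float, rho: float, n: int) -> float:
    """Exact log density of the sample correlation r given rho (Hotelling)."""
    lg = special.gammaln
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (np.log(n - 2) + lg(n - 1) - 0.5 * np.log(2 * np.pi)
            - lg(n - 0.5)
            + 0.5 * (n - 1) * np.log1p(-rho * rho)
            + 0.5 * (n - 4) * np.log1p(-r * r)
            - (n - 1.5) * np.log1p(-rho * r) + np.log(hyp))


def jzs_bf_correlation(x, y, prior_width: float = 1.0) -> BayesResult:
    """Jeffreys-style Bayes factor for a Pearson correlation vs the null.

    The alternative places a stretched symmetric beta(1/k, 1/k) prior of
    width k on rho (k = 1 is uniform on (-1, 1)); the marginal likelihood of
    the observed sample correlation is evaluated by numerical integration of
    the exact sampling density of r.  Returns ln BF10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need paired 1-D samples with n >= 4")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("degenerate input: constant sample")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))
    a = 1.0 / prior_width

    def log_prior(rho):  # stretched beta on (-1, 1)
        return stats.beta.logpdf((rho + 1.0) / 2.0, a, a) - np.log(2.0)

    def log_integrand(rho):
        return _log_corr_density(r, rho, n) + log_prior(rho)

    # log-offset quadrature: near-perfect correlations concentrate the
    # integrand in an extremely sharp peak near rho = r
    grid = np.clip(np.concatenate([np.linspace(-1, 1, 2001), [r]]),
                   -1 + 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore"):
        offset = float(np.max(log_integrand(grid)))
    num, _ = integrate.quad(lambda rho: np.exp(log_integrand(rho) - offset),
                            -1.0, 1.0, limit=300, points=[r])
    log_den = _log_corr_density(r, 0.0, n)
    if not np.isfinite(num) or num <= 0:
        raise ArithmeticError("correlation marginal likelihood failed")
    return BayesResult(float(np.log(num) + offset - log_den), prior_width,
                       "correlation")


def _t_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = d * np.sqrt(n)
    if tails == 1:
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def power_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                      tails: int = 1, n_max: int = 100000) -> PowerSpec:
    """Smallest n whose one-sample/paired t-test reaches the target power.

    Exact noncentral-t tail probabilities with noncentrality d*sqrt(n),
    scanned upward from n = 2.
    """
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("need d > 0 and alpha, power in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        achieved = _t_power(n, d, alpha, tails)
        if achieved >= power:
            return PowerSpec(d, alpha, power, tails, n, achieved)
    raise ValueError(f"target power not reachable with n <= {n_max}")
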