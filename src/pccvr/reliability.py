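"""Reliability and group statistics for session-repeated CVR metrics.

Implements the statistics a test-retest physiological-imaging study needs:
single-measure one-way random-effects ICC for absolute agreement, one-way
ANOVA variance components (inter-subject vs inter-session SD), exact paired
Wilcoxon signed-rank tests, Bonferroni-corrected phase comparisons, Pearson
correlations, and a random-intercept mixed model for coefficients of
determination between CVR metrics measured on the same subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError

EXACT_WILCOXON_MAX_N = 25


# ---------------------------------------------------------------------------
# one-way ANOVA machinery
# ---------------------------------------------------------------------------


def _oneway_anova(groups):
    """(MSB, MSW, dfb, dfw, grand_mean) from a list of 1-D arrays."""
    sizes = np.array([len(g) for g in groups])
    if len(groups) < 2 or np.any(sizes < 1):
        raise DataError("one-way ANOVA needs >= 2 groups")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    dfb = len(groups) - 1
    dfw = int(sizes.sum()) - len(groups)
    if dfw < 1:
        raise DataError("one-way ANOVA needs > 1 observation per group "
                        "somewhere")
    return ssb / dfb, ssw / dfw, dfb, dfw, float(grand)


def icc_oneway(matrix, variant: str = "single") -> float:
    """One-way random-effects ICC for absolute agreement.

    ``matrix`` is subjects x sessions; rows with any missing value are
    dropped (complete-cases convention).  ``single`` returns ICC(1) =
    (MSB - MSW) / (MSB + (k-1) MSW); ``average`` returns the k-measurement
    average variant ICC(1,k) = (MSB - MSW) / MSB.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise DataError("ICC needs a 2-D matrix with >= 2 sessions")
    complete = m[~np.isnan(m).any(axis=1)]
    if complete.shape[0] < 2:
        raise DataError("ICC needs >= 2 complete subject rows")
    k = complete.shape[1]
    msb, msw, *_ = _oneway_anova(list(complete))
    if variant == "single":
        return float((msb - msw) / (msb + (k - 1) * msw))
    if variant == "average":
        return float((msb - msw) / msb)
    raise DataError(f"unknown ICC variant {variant!r}")


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components from one-way ANOVA."""

    inter_subject_sd: float
    inter_session_sd: float
    grand_mean: float
    n_subjects: int
    n_observations: int
    truncated: bool   # a negative subject-variance estimate was set to 0


def variance_components(values: pd.DataFrame, value_col: str = "value",
                        subject_col: str = "subject") -> VarianceComponents:
    """Inter-subject and inter-session (residual) SDs of repeated measures.

    Uses the one-way ANOVA moment estimator with the harmonic-adjusted group
    size k0 = (N - sum(n_i^2)/N) / (G - 1), which reduces to the common
    session count for balanced data.  A negative subject-variance estimate is
    truncated to zero and flagged.
    """
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in values.groupby(subject_col)]
    sizes = np.array([len(g) for g in groups])
    if len(groups) < 2 or not np.any(sizes >= 2):
        raise DataError("variance components need >= 2 subjects and repeated "
                        "observations")
    msb, msw, _, _, grand = _oneway_anova(groups)
    n_total = int(sizes.sum())
    k0 = (n_total - float(np.sum(sizes ** 2)) / n_total) / (len(groups) - 1)
    var_subject = (msb - msw) / k0
    truncated = var_subject < 0
    var_subject = max(var_subject, 0.0)
    return VarianceComponents(
        inter_subject_sd=math.sqrt(var_subject),
        inter_session_sd=math.sqrt(msw),
        grand_mean=grand, n_subjects=len(groups),
        n_observations=n_total, truncated=bool(truncated))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def _signed_rank_distribution(doubled_ranks):
    """Exact null distribution of 2*W+ by subset-sum dynamic programming.

    Equivalent to enumerating all 2^n sign assignments: every assignment
    contributes its positive-rank sum once, and the DP counts assignments by
    achievable sum (midranks are doubled so sums are integers).
    """
    total = int(np.sum(doubled_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    return counts  # counts[s] = number of sign patterns with 2*W+ == s


def wilcoxon_signed_rank(diffs, method: str = "auto") -> tuple:
    """Paired two-sided Wilcoxon signed-rank test; (W+, p).

    Zero differences are dropped; ties receive midranks.  The p-value is
    exact (full enumeration of sign assignments) for n <= 25 and a normal
    approximation with continuity and tie corrections above; ``method`` can
    force either branch.
    """
    if method not in ("auto", "exact", "approx"):
        raise DataError(f"unknown Wilcoxon method {method!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DataError("all paired differences are zero; Wilcoxon test "
                        "undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    if method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N):
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()
        w2 = int(round(2.0 * w_plus))
        p_le = counts[:w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if var == 0:
        raise DataError("zero variance in Wilcoxon approximation (all ties)")
    correction = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - correction) / math.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# phase comparisons
# ---------------------------------------------------------------------------

BONFERRONI_FAMILY_SIZE = 18  # 6 variables x 3 phases compared with baseline


def bonferroni_threshold(alpha: float = 0.05,
                         n_comparisons: int = BONFERRONI_FAMILY_SIZE) -> float:
    return alpha / n_comparisons


def phase_comparisons(phase_values: pd.DataFrame, variables,
                      alpha: float = 0.05,
                      n_comparisons: int = BONFERRONI_FAMILY_SIZE
                      ) -> pd.DataFrame:
    """Paired tests of each stimulus phase against baseline, per variable.

    ``phase_values`` is long-format with columns subject, session, phase and
    one column per variable.  Each (subject, session) contributes one paired
    observation.  HX, RBL and HC are each compared with the initial baseline,
    and HC additionally with the recovery baseline; significance flags use
    the family-wise Bonferroni threshold alpha / n_comparisons.
    """
    required = {"subject", "session", "phase"}
    if not required.issubset(phase_values.columns):
        raise DataError("phase_values needs subject, session and phase "
                        "columns")
    wide = phase_values.pivot_table(index=["subject", "session"],
                                    columns="phase", aggfunc="mean")
    threshold = bonferroni_threshold(alpha, n_comparisons)
    rows = []
    comparisons = [("HX", "BL"), ("RBL", "BL"), ("HC", "BL"), ("HC", "RBL")]
    for var in variables:
        for phase, ref in comparisons:
            try:
                paired = wide[var][[phase, ref]].dropna()
            except KeyError:
                continue
            if paired.empty:
                raise DataError(
                    f"no paired sessions for {var}: {phase} vs {ref}")
            d = (paired[phase] - paired[ref]).to_numpy()
            if np.all(d == 0):
                stat_val, p = 0.0, 1.0
            else:
                stat_val, p = wilcoxon_signed_rank(d)
            rows.append({"variable": var, "phase": phase, "reference": ref,
                         "n_pairs": len(d), "statistic": stat_val,
                         "p_value": p, "significant": p < threshold})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# correlations and mixed-model R^2
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> tuple:
    """Pearson product-moment r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("Pearson correlation needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("Pearson correlation undefined for zero-variance "
                        "input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _profile_negloglik(log_lambda: float, y, x_design, group_index,
                       group_sizes):
    """-2 x profiled ML log-likelihood of the random-intercept model."""
    lam = math.exp(log_lambda)
    n = y.size
    rows_y, rows_x = [], []
    for g, m in enumerate(group_sizes):
        idx = group_index[g]
        yg = y[idx]
        xg = x_design[idx]
        ybar, xbar = yg.mean(), xg.mean(axis=0)
        rows_y.append(yg - ybar)
        rows_x.append(xg - xbar)
        w = math.sqrt(m / (1.0 + lam * m))
        rows_y.append(np.array([w * ybar]))
        rows_x.append((w * xbar)[np.newaxis, :])
    yy = np.concatenate(rows_y)
    xx = np.vstack(rows_x)
    beta, *_ = np.linalg.lstsq(xx, yy, rcond=None)
    rss = float(np.sum((yy - xx @ beta) ** 2))
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(lam * np.asarray(group_sizes))))
    return n * math.log(max(sigma2, 1e-300)) + logdet, beta, sigma2


def r_squared_mixed(x, y, subjects) -> float:
    """Marginal R^2 of a random-intercept regression of y on x.

    Fits y = a + b*x + u_subject + e by maximum likelihood, profiling the
    variance ratio lambda = var(u)/var(e) (closed-form GLS at each lambda,
    1-D likelihood search), and returns the proportion of total variance
    carried by the fixed slope::

        R^2 = b^2 Var(x) / (b^2 Var(x) + var(u) + var(e))

    With zero subject variance this collapses to the OLS R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (x.size == y.size == subjects.size):
        raise DataError("x, y and subjects must have equal length")
    if np.unique(subjects).size < 3 or x.size < 6:
        raise DataError("mixed-model R^2 needs >= 3 subjects and >= 6 points")
    if np.ptp(x) == 0:
        raise DataError("mixed-model R^2 undefined for zero-variance x")
    labels, inverse = np.unique(subjects, return_inverse=True)
    group_index = [np.flatnonzero(inverse == g) for g in range(labels.size)]
    group_sizes = [idx.size for idx in group_index]
    design = np.column_stack([np.ones_like(x), x])

    def objective(u):
        return _profile_negloglik(u, y, design, group_index, group_sizes)[0]

    grid = np.linspace(math.log(1e-8), math.log(1e4), 60)
    values = [objective(u) for u in grid]
    best = grid[int(np.argmin(values))]
    res = optimize.minimize_scalar(
        objective, bounds=(best - 2.0, best + 2.0), method="bounded",
        options={"xatol": 1e-8})
    _, beta, sigma2_e = _profile_negloglik(res.x, y, design, group_index,
                                           group_sizes)
    lam = math.exp(res.x)
    sigma2_b = lam * sigma2_e
    slope = float(beta[1])
    var_x = float(np.var(x))
    fixed_var = slope ** 2 * var_x
    return float(fixed_var / (fixed_var + sigma2_b + sigma2_e))
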