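"""Within-subject statistics for the session-level outcome measures.

Implements the inferential layer applied to per-day and per-block outcome
tables: one-way repeated-measures ANOVA with Mauchly's sphericity test and
the Greenhouse–Geisser correction, Bonferroni-corrected post-hoc paired
t-tests with Cohen's d, Pearson correlations, a Wilcoxon signed-rank
comparison of normalized improvements, and the block-1-minus-block-5
learning rate.

The rmANOVA is the classical two-way (subject x condition) decomposition
without replication:

    SS_total  = SS_subject + SS_condition + SS_error
    F = MS_condition / MS_error,  df = (k-1), (n-1)(k-1)
    partial eta^2 = SS_condition / (SS_condition + SS_error)

Sphericity is assessed with Mauchly's W on the orthonormal-contrast
covariance; when the test rejects at alpha = .05, both degrees of freedom
are multiplied by the Greenhouse–Geisser epsilon and the p-value is
recomputed.  With only two conditions sphericity is vacuous (epsilon = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats


@dataclass
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    corrected: bool
    p_uncorrected: float


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float
    alpha_adjusted: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class SignedRankResult:
    z: float
    p: float
    d: float
    n: int


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the k x k condition covariance."""
    k = cov.shape[0]
    centered = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) + cov.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * np.sum(centered**2)
    if den == 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _mauchly(cov: np.ndarray, n: int) -> tuple[float, float]:
    """Mauchly's sphericity test: (W, p) from the condition covariance."""
    k = cov.shape[0]
    if k < 3:
        return 1.0, 1.0
    # orthonormal contrasts: orthonormal basis of the space orthogonal to 1
    ones = np.ones((k, 1)) / np.sqrt(k)
    q, _ = np.linalg.qr(np.eye(k) - ones @ ones.T)
    contrasts = q[:, : k - 1]
    s = contrasts.T @ cov @ contrasts
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        return 0.0, float("nan")
    d = k - 1
    W = float(np.prod(eig) / (eig.mean() ** d))
    # chi-square approximation with the standard second-order term
    # (the convention of SPSS / R's ezANOVA)
    f = 1 - (2 * d**2 + d + 2) / (6 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288 * ((n - 1) * d * f) ** 2)
    )
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) / 2 - 1
    p1 = sp_stats.chi2.sf(chi2, df)
    p2 = sp_stats.chi2.sf(chi2, df + 4)
    return W, float(p1 + w2 * (p2 - p1))


def rm_anova(data: np.ndarray, sphericity_alpha: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an (n subjects x k conditions) matrix.

    Complete cases only; missing cells raise rather than impute.  When
    Mauchly's test rejects at *sphericity_alpha* (and k >= 3), degrees of
    freedom are multiplied by the Greenhouse–Geisser epsilon and the
    p-value recomputed; the uncorrected p is kept alongside.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite cells; rm_anova requires complete cases")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_subject = k * np.sum((subj_means - grand) ** 2)
    ss_condition = n * np.sum((cond_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_condition
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_condition = ss_condition / df1
    ms_error = ss_error / df2
    F = float(ms_condition / ms_error) if ms_error > 0 else float("inf") if ms_condition > 0 else 0.0
    denom = ss_condition + ss_error
    partial_eta_sq = float(ss_condition / denom) if denom > 0 else 0.0

    cov = np.cov(data, rowvar=False)
    W, mauchly_p = _mauchly(np.atleast_2d(cov), n)
    eps = _gg_epsilon(np.atleast_2d(cov)) if k >= 3 else 1.0

    corrected = bool(k >= 3 and np.isfinite(mauchly_p) and mauchly_p < sphericity_alpha)
    p_unc = float(sp_stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if corrected:
        adj1, adj2 = eps * df1, eps * df2
        p = float(sp_stats.f.sf(F, adj1, adj2)) if np.isfinite(F) else 0.0
        return RmAnovaResult(F, adj1, adj2, p, partial_eta_sq, W, mauchly_p, eps, True, p_unc)
    return RmAnovaResult(F, float(df1), float(df2), p_unc, partial_eta_sq, W, mauchly_p, eps, False, p_unc)


def paired_t(
    a,
    b,
    family_m: int = 1,
    family_alpha: float = 0.05,
    d_variant: str = "diff_sd",
) -> PairedTestResult:
    """Paired t-test with Bonferroni-adjusted alpha and Cohen's d.

    ``d_variant='diff_sd'`` (default) uses mean(a-b)/sd(a-b), the common
    paired-design convention; ``'avg_sd'`` divides by the RMS of the two
    condition standard deviations instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples of size >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sp_stats.ttest_rel(a, b)
    if d_variant == "diff_sd":
        d = float(diff.mean() / sd)
    elif d_variant == "avg_sd":
        pooled = np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2)
        d = float(diff.mean() / pooled)
    else:
        raise ValueError(f"unknown d_variant {d_variant!r}")
    return PairedTestResult(
        t=float(res.statistic),
        df=a.size - 1,
        p=float(res.pvalue),
        d=d,
        alpha_adjusted=family_alpha / family_m,
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = sp_stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def signed_rank(a, b) -> SignedRankResult:
    """Wilcoxon signed-rank test (normal approximation) on paired samples.

    Zero differences are dropped; ties are mid-ranked with the variance
    tie correction; z = (T+ - mu) / sigma without continuity correction,
    so z > 0 means a tends to exceed b.  Effect size d is the matched-pairs
    Cohen's d, mean(a-b)/sd(a-b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signed_rank needs two equal-length 1-D samples")
    diff = a - b
    nz = diff[diff != 0]
    n = nz.size
    if n == 0:
        raise ValueError("all differences are zero: signed-rank test undefined")
    ranks = sp_stats.rankdata(np.abs(nz))
    t_plus = float(ranks[nz > 0].sum())
    mu = n * (n + 1) / 4
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
    z = float((t_plus - mu) / sigma)
    p = float(2 * sp_stats.norm.sf(abs(z)))
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else float("inf") * np.sign(diff.mean())
    return SignedRankResult(z=z, p=p, d=d, n=n)


def normalized_improvement(block1, block5, method: str = "proportional") -> np.ndarray:
    """Per-participant normalized improvement from block 1 to block 5.

    ``proportional`` (default): (block1 - block5) / block1, so a measure
    that halves scores 0.5 regardless of its units.  ``zscore``: raw
    improvements standardized across participants.
    """
    b1 = np.asarray(block1, dtype=float)
    b5 = np.asarray(block5, dtype=float)
    if b1.shape != b5.shape:
        raise ValueError("block1 and block5 must align per participant")
    raw = b1 - b5
    if method == "proportional":
        if np.any(b1 == 0):
            raise ValueError("block-1 value of zero: proportional improvement undefined")
        return raw / b1
    if method == "zscore":
        sd = raw.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance improvements: z-score undefined")
        return (raw - raw.mean()) / sd
    raise ValueError(f"unknown normalization {method!r}")


def normalized_improvement_compare(
    metric_a_blocks: tuple,
    metric_b_blocks: tuple,
    method: str = "proportional",
) -> SignedRankResult:
    """Compare two measures' normalized block-1-to-block-5 improvements.

    Each argument is a (block1_values, block5_values) pair aligned by
    participant.  Improvements are normalized per measure (so a time in
    seconds and a dimensionless phase difference become comparable) and
    contrasted with the signed-rank test; z > 0 means measure A improved
    more.
    """
    imp_a = normalized_improvement(*metric_a_blocks, method=method)
    imp_b = normalized_improvement(*metric_b_blocks, method=method)
    if imp_a.shape != imp_b.shape:
        raise ValueError("the two measures must cover the same participants")
    return signed_rank(imp_a, imp_b)


def learning_rate(block_values) -> float:
    """Within-day learning rate: block-1 value minus block-5 value.

    Accepts either the ordered sequence of the five per-block values or a
    mapping from block number to value.
    """
    try:
        vals = {int(k): float(v) for k, v in dict(block_values).items()}
    except (TypeError, ValueError):
        seq = [float(v) for v in block_values]
        vals = {i + 1: v for i, v in enumerate(seq)}
    if 1 not in vals or 5 not in vals:
        raise ValueError("learning_rate needs blocks 1 and 5")
    return vals[1] - vals[5]
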