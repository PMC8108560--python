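"""Paired within-subject statistics for stimulation-versus-sham contrasts.

Every contrast in the study design is a two-condition repeated-measures
comparison over the same subjects, so the RM-ANOVA collapses to the square
of the paired t statistic, F(1, n-1) = t². The nonparametric companion is a
Wilcoxon signed-rank test reported as T = min(W+, W−), with zero differences
dropped and tied |differences| given average ranks; the p-value is exact
(full enumeration of sign assignments) for small samples without ties and a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedStatResult",
    "paired_rm_anova",
    "wilcoxon_signed_rank",
    "pearson_r",
    "diff_se",
    "paired_contrast",
]

EXACT_MAX_N = 12


@dataclass
class PairedSample:
    """Matched condition-A / condition-B values for n ≥ 2 subjects."""

    x: np.ndarray
    y: np.ndarray
    subjects: list | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if self.x.size < 2:
            raise ValueError("paired statistics need at least 2 subjects")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("paired sample must be pairwise complete")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def diffs(self) -> np.ndarray:
        return self.x - self.y


@dataclass
class PairedStatResult:
    """Bundle of the parametric and nonparametric paired contrasts."""

    F: float
    df: tuple[int, int]
    p_anova: float
    T: float
    p_wilcoxon: float
    alternative: str
    mean_diff: float
    sd_diff: float
    se_diff: float
    n: int


def paired_rm_anova(sample: PairedSample) -> tuple[float, tuple[int, int], float]:
    """Two-condition repeated-measures ANOVA: F = t², df = (1, n−1)."""
    d = sample.diffs
    n = sample.n
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; F undefined")
    t = d.mean() / (sd / np.sqrt(n))
    F = float(t * t)
    df = (1, n - 1)
    p = float(sps.f.sf(F, *df))
    return F, df, p


def _signed_rank_sums(d: np.ndarray) -> tuple[float, float, np.ndarray]:
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return w_pos, w_neg, ranks


def _exact_sf(ranks: np.ndarray, w: float) -> float:
    """P(W+ >= w) under the null, by full enumeration of sign assignments."""
    total = 0
    hits = 0
    for signs in product((0, 1), repeat=len(ranks)):
        total += 1
        if float(np.dot(signs, ranks)) >= w - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_signed_rank(sample: PairedSample, alternative: str = "two-sided"
                         ) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences x − y.

    Returns (T, p) with T = min(W+, W−). ``alternative`` is 'two-sided',
    'greater' (x > y) or 'less'. Zero differences are dropped before
    ranking; ties in |d| get average ranks. The p-value is exact when the
    effective n ≤ 12 and there are no ties, otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = sample.diffs
    w_pos, w_neg, ranks = _signed_rank_sums(d)
    T = min(w_pos, w_neg)
    n = len(ranks)
    has_ties = len(np.unique(np.abs(d[d != 0]))) != n

    if n <= EXACT_MAX_N and not has_ties:
        sf_pos = _exact_sf(ranks, w_pos)          # P(W+ >= w_pos)
        cdf_pos = _exact_sf(-ranks, -w_pos)       # P(W+ <= w_pos) via reflection
        if alternative == "greater":
            p = sf_pos
        elif alternative == "less":
            p = cdf_pos
        else:
            p = min(1.0, 2.0 * min(sf_pos, cdf_pos))
        return T, float(p)

    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(sps.rankdata(np.abs(d[d != 0])), return_counts=True)[1]
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if alternative == "greater":
        z = (w_pos - mu - 0.5) / sigma
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (w_pos - mu + 0.5) / sigma
        p = sps.norm.cdf(z)
    else:
        z = (w_pos - mu - np.sign(w_pos - mu) * 0.5) / sigma
        p = 2 * sps.norm.sf(abs(z))
    return T, float(min(1.0, p))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-tailed p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def diff_se(sample: PairedSample) -> float:
    """Standard error of the difference scores: sd(x−y)/√n."""
    return float(sample.diffs.std(ddof=1) / np.sqrt(sample.n))


def paired_contrast(sample: PairedSample, alternative: str = "greater"
                    ) -> PairedStatResult:
    """Run both paired contrasts (ANOVA two-sided, Wilcoxon as requested)."""
    F, df, p_a = paired_rm_anova(sample)
    T, p_w = wilcoxon_signed_rank(sample, alternative)
    d = sample.diffs
    return PairedStatResult(
        F=F, df=df, p_anova=p_a, T=T, p_wilcoxon=p_w, alternative=alternative,
        mean_diff=float(d.mean()), sd_diff=float(d.std(ddof=1)),
        se_diff=diff_se(sample), n=sample.n,
    )
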