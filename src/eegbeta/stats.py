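"""Univariate group comparisons and pre/post consistency analyses.

The rank-sum test uses midranks for ties, exact enumeration of all rank
assignments for combined n <= 20, and a tie- and continuity-corrected
normal approximation otherwise. The same implementation serves both the
"Wilcoxon two-sample" and "Mann-Whitney" call sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import AlignmentError, DegenerateInputError

EXACT_N_LIMIT = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    test: str
    p_adjusted: float | None = None

    def adjusted(self, m: int) -> "TestResult":
        return TestResult(
            statistic=self.statistic, p_value=self.p_value,
            n_x=self.n_x, n_y=self.n_y, test=self.test,
            p_adjusted=float(min(1.0, m * self.p_value)),
        )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sstats.rankdata(values, method="average")


def wilcoxon_ranksum(x, y, exact_limit: int = EXACT_N_LIMIT) -> TestResult:
    """Two-sided rank-sum test of two independent samples.

    The statistic is the rank sum of ``x`` in the pooled midranked sample.
    Exact two-sided p (doubled smaller tail, capped at 1) when the combined
    size is at most ``exact_limit``; otherwise normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= exact_limit:
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float
        )
        total = len(sums)
        p_lo = np.count_nonzero(sums <= w + 1e-9) / total
        p_hi = np.count_nonzero(sums >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return TestResult(w, p, n1, n2, "wilcoxon-ranksum-exact")
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1.0)))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return TestResult(w, 1.0, n1, n2, "wilcoxon-ranksum-normal")
    diff = w - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    return TestResult(w, p, n1, n2, "wilcoxon-ranksum-normal")


def ranksum_u(result: TestResult) -> float:
    """Mann-Whitney U of the first sample, derived from the rank-sum statistic."""
    return result.statistic - result.n_x * (result.n_x + 1) / 2.0


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Adjusted p-values: ``min(1, m * p)``."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must cover all p-values")
    return np.minimum(1.0, m * p)


def electrodewise_sex_tests(
    table: pd.DataFrame, session: str, family_size: int | None = None
) -> pd.DataFrame:
    """Per-channel rank-sum tests of relative beta between sexes.

    Bonferroni family defaults to the number of channels within the session
    (before/after treated as separate families); pass ``family_size`` to use
    a different family (e.g. channels x sessions).
    """
    sub = table[table["session"] == session].dropna(subset=["mean_rel_beta"])
    channels = [c for c in table.columns if c.startswith("rb_")]
    if not channels:
        raise ValueError("no per-channel feature columns (rb_*) in table")
    f = sub[sub["sex"] == "female"]
    m_ = sub[sub["sex"] == "male"]
    if f.empty or m_.empty:
        raise DegenerateInputError("both sexes must be present in the session")
    m = family_size if family_size is not None else len(channels)
    rows = []
    for ch in channels:
        res = wilcoxon_ranksum(f[ch].to_numpy(), m_[ch].to_numpy())
        res = res.adjusted(m)
        rows.append({
            "channel": ch.removeprefix("rb_"),
            "statistic": res.statistic,
            "p_value": res.p_value,
            "p_adjusted": res.p_adjusted,
            "direction": "female>male" if f[ch].mean() > m_[ch].mean() else "male>female",
            "n_female": res.n_x,
            "n_male": res.n_y,
        })
    return pd.DataFrame(rows)


def paired_ttest(pre, post) -> TestResult:
    """Two-sided paired t-test on per-subject differences."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise AlignmentError("pre and post must have equal length")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        raise DegenerateInputError("zero-variance differences")
    t, p = sstats.ttest_rel(post, pre)
    return TestResult(float(t), float(p), len(pre), len(post), "paired-t")


def session_correlation(pre, post) -> tuple[float, float]:
    """Pearson correlation of a feature across sessions, with two-sided p."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise AlignmentError("pre and post must have equal length")
    if len(pre) < 3:
        raise DegenerateInputError("need at least 3 pairs")
    if np.std(pre) == 0 or np.std(post) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    r, p = sstats.pearsonr(pre, post)
    return float(r), float(p)


def session_correlation_channels(table: pd.DataFrame) -> dict:
    """Per-channel pre/post correlations plus their mean and std.

    Subjects missing either session are dropped.
    """
    channels = [c for c in table.columns if c.startswith("rb_")]
    wide = table.pivot(index="subject_id", columns="session",
                       values=channels + ["mean_rel_beta"]).dropna()
    rs = {}
    for ch in channels:
        r, _ = session_correlation(wide[(ch, "pre")], wide[(ch, "post")])
        rs[ch.removeprefix("rb_")] = r
    mean_r, mean_p = session_correlation(
        wide[("mean_rel_beta", "pre")], wide[("mean_rel_beta", "post")]
    )
    vals = np.array(list(rs.values()))
    return {
        "per_channel_r": rs,
        "channel_r_mean": float(vals.mean()),
        "channel_r_std": float(vals.std(ddof=1)),
        "mean_feature_r": mean_r,
        "mean_feature_p": mean_p,
    }


def misclassification_overlap(pred_pre, pred_post, labels) -> tuple[int, int]:
    """Subjects misclassified before treatment, and how many remain so after."""
    pred_pre = np.asarray(pred_pre)
    pred_post = np.asarray(pred_post)
    labels = np.asarray(labels)
    if not (len(pred_pre) == len(pred_post) == len(labels)):
        raise AlignmentError("predictions and labels must be aligned per subject")
    wrong_pre = pred_pre != labels
    wrong_post = pred_post != labels
    return int(wrong_pre.sum()), int((wrong_pre & wrong_post).sum())
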