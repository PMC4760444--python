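"""Group statistics: paired/one-sample t tests, 2x2 RM-ANOVA, median/IQR.

The 2x2 repeated-measures ANOVA (session x hemisphere, or session x
positive/negative CVR compartment) is computed from within-subject sums of
squares, each effect tested against its own subject-interaction error term
with (1, n-1) degrees of freedom.  Tukey's HSD compares the four cell
means using the highest-order interaction error mean square and the
studentized-range distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "RmAnova2x2Result",
    "paired_t",
    "one_sample_t",
    "rm_anova_2x2",
    "median_iqr",
    "mean_se",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    dof: int
    p: float
    mean: float  # mean difference (paired) or mean - reference (one-sample)
    degenerate: bool = False  # zero variance with nonzero mean


def _t_from_values(d: np.ndarray) -> TTestResult:
    n = len(d)
    if n < 2:
        raise ValueError("need at least two observations")
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    if sd == 0:
        if m == 0:
            return TTestResult(0.0, dof, 1.0, 0.0)
        return TTestResult(float(np.inf) * np.sign(m), dof, 0.0, m, degenerate=True)
    t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), dof)
    return TTestResult(float(t), dof, float(p), m)


def paired_t(pre, post) -> TTestResult:
    """Two-sided paired t test on post - pre differences."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be matched samples")
    return _t_from_values(post - pre)


def one_sample_t(values, reference: float = 0.0) -> TTestResult:
    """Two-sided one-sample t test against a reference value."""
    return _t_from_values(np.asarray(values, float) - reference)


@dataclass
class RmAnova2x2Result:
    cell_means: pd.DataFrame  # index a-level, columns b-level
    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_ab: float
    p_ab: float
    dof: tuple[int, int]  # (1, n-1) for every effect
    n_subjects: int
    excluded_subjects: list
    tukey: pd.DataFrame | None = None

    @property
    def any_significant(self) -> bool:
        return min(self.p_a, self.p_b, self.p_ab) < 0.05


def rm_anova_2x2(
    data: pd.DataFrame,
    subject: str = "subject",
    factor_a: str = "a",
    factor_b: str = "b",
    value: str = "value",
    tukey_alpha: float = 0.05,
) -> RmAnova2x2Result:
    """Fully within-subject 2x2 ANOVA from a long-format table.

    Each subject must contribute exactly one value per cell; subjects with
    incomplete cells are excluded listwise.  Tukey HSD on the four cell
    means (computed whenever any F is significant at ``tukey_alpha``) uses
    the A x B x subject error mean square with n-1 degrees of freedom.
    """
    df = data[[subject, factor_a, factor_b, value]].copy()
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("both factors must have exactly two levels")

    counts = df.groupby(subject).size()
    complete = counts[counts == 4].index
    excluded = sorted(set(counts.index) - set(complete))
    df = df[df[subject].isin(complete)]
    n = df[subject].nunique()
    if n < 2:
        raise ValueError("need at least two subjects with complete cells")
    if len(df) != 4 * n:
        raise ValueError("each subject must contribute exactly one value per cell")

    y = df.pivot_table(index=subject, columns=[factor_a, factor_b], values=value)
    y = y.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    Y = y.to_numpy()  # (n, 4) ordered a0b0 a0b1 a1b0 a1b1
    Yc = Y.reshape(n, 2, 2)

    grand = Yc.mean()
    m_s = Yc.mean(axis=(1, 2))
    m_a = Yc.mean(axis=(0, 2))
    m_b = Yc.mean(axis=(0, 1))
    m_ab = Yc.mean(axis=0)
    m_as = Yc.mean(axis=2)
    m_bs = Yc.mean(axis=1)

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_total = ((Yc - grand) ** 2).sum()
    ss_subj = 4 * ((m_s - grand) ** 2).sum()
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    dfe = n - 1

    def ftest(ss_eff, ss_err):
        if ss_err <= 1e-300:
            return (np.inf, 0.0) if ss_eff > 1e-300 else (0.0, 1.0)
        f = (ss_eff / 1.0) / (ss_err / dfe)
        return float(f), float(sps.f.sf(f, 1, dfe))

    f_a, p_a = ftest(ss_a, ss_as)
    f_b, p_b = ftest(ss_b, ss_bs)
    f_ab, p_ab = ftest(ss_ab, ss_abs)

    cells = pd.DataFrame(m_ab, index=a_levels, columns=b_levels)
    result = RmAnova2x2Result(
        cell_means=cells,
        f_a=f_a, p_a=p_a, f_b=f_b, p_b=p_b, f_ab=f_ab, p_ab=p_ab,
        dof=(1, dfe), n_subjects=n, excluded_subjects=excluded,
    )

    if min(p_a, p_b, p_ab) < tukey_alpha:
        mse = ss_abs / dfe
        se = np.sqrt(max(mse, 1e-300) / n)
        labels = [f"{a}:{b}" for a in a_levels for b in b_levels]
        means = m_ab.ravel()
        rows = []
        for i in range(4):
            for j in range(i + 1, 4):
                diff = means[i] - means[j]
                q = abs(diff) / se if se > 0 else np.inf
                p = float(sps.studentized_range.sf(q, 4, dfe)) if np.isfinite(q) else 0.0
                rows.append(
                    {"cell_1": labels[i], "cell_2": labels[j],
                     "diff": float(diff), "q": float(q), "p": p}
                )
        result.tukey = pd.DataFrame(rows)
    return result


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range with inclusive (Tukey-hinge) quartiles.

    Each half of the sorted data includes the overall median when n is odd,
    so e.g. (0, 1, 3, 3, 38) -> median 3, IQR 3 - 1 = 2.
    """
    x = np.sort(np.asarray(values, float))
    n = len(x)
    if n == 0:
        raise ValueError("need at least one value")
    med = float(np.median(x))
    if n == 1:
        return med, 0.0
    half = (n + 1) // 2
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return med, q3 - q1


def mean_se(values) -> tuple[float, float]:
    """Arithmetic mean and its standard error."""
    x = np.asarray(values, float)
    if len(x) < 2:
        return float(x.mean()), 0.0
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))
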