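"""Cohort-level statistics: chi-square family, trend test, t-tests,
rank tests, odd/even intraclass correlation, handedness quotients,
language-status classification and the principal-component language
composite.

All p-values are two-tailed; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "ContingencyTable",
    "SubjectOutcome",
    "HandednessRecord",
    "pearson_chi2",
    "linear_by_linear",
    "one_sample_t",
    "two_sample_t",
    "oneway_anova",
    "mann_whitney",
    "pearson_r",
    "spearman_rho",
    "icc_oddeven",
    "ehi_quotient",
    "qhp_lq",
    "classify_language_status",
    "subgroup_label",
    "composite_language_score",
]

SUBGROUPS = ("typical", "late_bloomer", "plateau", "persistent_sli")


@dataclass
class ContingencyTable:
    """r x c table of non-negative counts with row/column labels.

    Counts may be non-integral when the table holds model-expected counts.
    """

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("table total must be positive")
        if self.row_labels and len(self.row_labels) != self.counts.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels and len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("col_labels length mismatch")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass
class HandednessRecord:
    """Edinburgh inventory item counts and reaching-task tallies."""

    ehi_right_items: int = 0
    ehi_left_items: int = 0
    qhp_right_reaches: int = 0
    qhp_total_reaches: int = 0

    def __post_init__(self) -> None:
        if self.ehi_right_items < 0 or self.ehi_left_items < 0:
            raise ValueError("item counts must be non-negative")
        if self.ehi_right_items + self.ehi_left_items > 9:
            raise ValueError("at most 9 inventory items")
        if not 0 <= self.qhp_right_reaches <= self.qhp_total_reaches:
            raise ValueError("0 <= right reaches <= total reaches")


@dataclass
class SubjectOutcome:
    """Per-subject cohort row: language history, z-scores, laterality."""

    subject_id: str
    late_talker_20m: bool
    impaired_4y: bool
    subgroup: str
    language_zscores: dict[str, float] = field(default_factory=dict)
    laterality_category: Optional[str] = None
    li: Optional[float] = None
    handedness: Optional[HandednessRecord] = None

    def __post_init__(self) -> None:
        expected = subgroup_label(self.late_talker_20m, self.impaired_4y)
        if self.subgroup != expected:
            raise ValueError(
                f"subgroup {self.subgroup!r} inconsistent with flags "
                f"(expected {expected!r})"
            )


def pearson_chi2(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence: sum (O-E)^2/E, df=(r-1)(c-1)."""
    obs = t.counts
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate margin: a row or column sums to zero")
    expected = np.outer(rows, cols) / t.n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_st.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def linear_by_linear(t: ContingencyTable,
                     row_scores: Sequence[float] | None = None,
                     col_scores: Sequence[float] | None = None
                     ) -> tuple[float, int, float]:
    """Linear-by-linear (Mantel-Haenszel trend) statistic M^2 = (N-1) r^2.

    ``r`` is the Pearson correlation between row and column scores over
    the N individuals in the table; df = 1.  Default scores are 1..r and
    1..c.  Invariant to affine rescaling of either score set.
    """
    w = t.counts
    r, c = w.shape
    xs = np.asarray(row_scores if row_scores is not None else np.arange(1, r + 1),
                    dtype=float)
    ys = np.asarray(col_scores if col_scores is not None else np.arange(1, c + 1),
                    dtype=float)
    if xs.size != r or ys.size != c:
        raise ValueError("score length must match table shape")
    n = t.n
    mx = float((w.sum(axis=1) * xs).sum() / n)
    my = float((w.sum(axis=0) * ys).sum() / n)
    vx = float((w.sum(axis=1) * (xs - mx) ** 2).sum() / n)
    vy = float((w.sum(axis=0) * (ys - my) ** 2).sum() / n)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in scores")
    cov = float((w * np.outer(xs - mx, ys - my)).sum() / n)
    corr = cov / np.sqrt(vx * vy)
    stat = (n - 1) * corr ** 2
    return float(stat), 1, float(_st.chi2.sf(stat, 1))


def one_sample_t(values: Sequence[float] | None = None, *,
                 mean: float | None = None, sd: float | None = None,
                 n: int | None = None, mu0: float = 0.0
                 ) -> tuple[float, int, float]:
    """One-sample t against ``mu0`` from raw values or (mean, sd, n)."""
    if values is not None:
        x = np.asarray(values, dtype=float)
        n = x.size
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if n > 1 else 0.0
    if mean is None or sd is None or n is None:
        raise ValueError("provide values or all of mean, sd, n")
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        if mean == mu0:
            return 0.0, n - 1, 1.0
        raise ValueError("infinite t: sd is zero with mean != mu0")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(_st.t.sf(abs(t), df))
    return float(t), df, p


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 equal_var: bool = True) -> tuple[float, float, float]:
    """Independent-samples t (pooled variance by default; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    res = _st.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def oneway_anova(*groups: Sequence[float]) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns (F, df_between, df_within, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need n >= 2 per group")
    res = _st.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    return float(res.statistic), df1, df2, float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum test; returns (W, p) where W is the rank-sum of ``x``.

    p uses the normal approximation with tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _st.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise ValueError("all observations tied; rank test undefined")
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = 2.0 * float(_st.norm.sf(abs(z)))
    return w, min(p, 1.0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    res = _st.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    res = _st.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def icc_oddeven(pairs: Sequence[tuple[float, float]]
                ) -> tuple[float, tuple[float, float]]:
    """Split-half reliability of the LI across subjects.

    Single-measures two-way absolute-agreement intraclass correlation
    (ICC(A,1) of McGraw & Wong) of the (odd, even) LI pairs, with the
    F-based 95% confidence interval.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 pairs")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse and denom <= 0:
        raise ValueError("zero between-subject variance")
    icc = (msr - mse) / denom

    alpha = 0.05
    # Satterthwaite df for the ICC(A,1) confidence bounds
    r = icc
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = _st.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = _st.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def ehi_quotient(h: HandednessRecord) -> float:
    """Edinburgh handedness quotient 100*(R-L)/(R+L); positive = right."""
    r, l = h.ehi_right_items, h.ehi_left_items
    if r + l == 0:
        raise ValueError("no lateralized inventory responses")
    return 100.0 * (r - l) / (r + l)


def qhp_lq(h: HandednessRecord) -> float:
    """Reaching-task laterality quotient: proportion right reaches - 0.50."""
    if h.qhp_total_reaches == 0:
        raise ValueError("zero total reaches")
    return h.qhp_right_reaches / h.qhp_total_reaches - 0.5


def classify_language_status(zscores: dict[str, float], threshold: float = -1.0,
                             min_failures: int = 2) -> bool:
    """Impaired iff strictly more than ``|threshold|`` SD below the mean on
    at least ``min_failures`` measures (z < threshold, strict)."""
    if not zscores:
        raise ValueError("no language measures supplied")
    if len(zscores) < min_failures:
        raise ValueError("fewer measures than min_failures")
    return sum(z < threshold for z in zscores.values()) >= min_failures


def subgroup_label(late_talker: bool, impaired_4y: bool) -> str:
    if late_talker and impaired_4y:
        return "persistent_sli"
    if late_talker:
        return "late_bloomer"
    if impaired_4y:
        return "plateau"
    return "typical"


def composite_language_score(measures: np.ndarray) -> np.ndarray:
    """First-principal-component factor score scaled to mean 100, SD 15.

    Columns are standardized internally; the component sign is oriented so
    the composite correlates positively with the per-subject column mean.
    """
    x = np.asarray(measures, dtype=float)
    if x.ndim != 2:
        raise ValueError("measures must be a 2-D matrix")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects than measures ({n} <= {p})")
    sd = x.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("rank-deficient input: zero-variance column")
    z = (x - x.mean(axis=0)) / sd
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("rank-deficient input")
    scores = z @ vt[0]
    if np.corrcoef(scores, z.mean(axis=1))[0, 1] < 0:
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return scores * 15.0 + 100.0
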