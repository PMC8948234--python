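"""Statistical primitives shared by every pipeline stage.

Enrichment testing (Fisher's exact test with a conditional-MLE odds ratio,
chi-square association), two-group differential expression with
fold-change/FDR thresholds, Benjamini–Hochberg correction, plug-in mutual
information, and the small linear models used for dose-response and
tumor-burden comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln
from sklearn.metrics import mutual_info_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "DEResult",
    "fisher_exact",
    "chi_square",
    "bh_fdr",
    "differential_expression",
    "mutual_information",
    "gene_set_enrichment",
    "fit_interaction_model",
]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2x2 table of non-negative counts.

    Rows index the first classification, columns the second::

        [[a, b],
         [c, d]]
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
        return cls(*(int(x) for x in arr.ravel()))

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) sums."""
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """Result of a 2x2 association test."""

    odds_ratio_cmle: float
    p_two_sided: float
    method: str  # fisher | chisq | chisq_yates
    statistic: float = float("nan")  # chi-square statistic where applicable
    table: ContingencyTable2x2 | None = None
    or_defined: bool = True


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    return ContingencyTable2x2.from_array(table)


def _cmle_odds_ratio(t: ContingencyTable2x2, tol: float = 1e-8) -> float:
    """Conditional MLE of the odds ratio under the noncentral hypergeometric
    distribution with all margins fixed.

    Solves E[a | psi, margins] = a by bisection on log(psi); the conditional
    expectation is strictly increasing in psi. Probability terms are handled
    in log space.
    """
    r1, _, c1, _ = t.margins
    n = t.a + t.b + t.c + t.d
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    a = t.a
    if lo == hi:
        return float("nan")  # support is a point; psi not identifiable
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0

    support = np.arange(lo, hi + 1)
    # log of the central hypergeometric weights C(r1,u) C(n-r1, c1-u)
    r2 = n - r1
    logw = (gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
            + gammaln(r2 + 1) - gammaln(c1 - support + 1)
            - gammaln(r2 - (c1 - support) + 1))

    def mean_minus_a(logpsi: float) -> float:
        logterms = logw + support * logpsi
        logterms -= logterms.max()
        w = np.exp(logterms)
        return float((support * w).sum() / w.sum()) - a

    left, right = -1.0, 1.0
    while mean_minus_a(left) > 0:
        left *= 2.0
    while mean_minus_a(right) < 0:
        right *= 2.0
    while right - left > tol:
        mid = 0.5 * (left + right)
        if mean_minus_a(mid) < 0:
            left = mid
        else:
            right = mid
    return math.exp(0.5 * (left + right))


def fisher_exact(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test with the conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities no larger than that of the
    observed table (fixed margins); the odds ratio is the conditional MLE
    under the noncentral hypergeometric likelihood, the convention used when
    an odds ratio is reported alongside an exact test.
    """
    t = _as_table(table)
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        return EnrichmentResult(float("nan"), 1.0, "fisher",
                                table=t, or_defined=False)
    _, p = sps.fisher_exact(t.to_array(), alternative="two-sided")
    return EnrichmentResult(_cmle_odds_ratio(t), float(p), "fisher", table=t)


def chi_square(table, yates: bool = True) -> EnrichmentResult:
    """Pearson chi-square test of association on a 2x2 table (df = 1).

    ``yates`` applies the continuity correction. The odds ratio reported is
    the same conditional MLE as :func:`fisher_exact`.
    """
    t = _as_table(table)
    if min(t.margins) == 0:
        raise ValueError("chi-square undefined for a zero row/column margin")
    stat, p, _, _ = sps.chi2_contingency(t.to_array(), correction=yates)
    return EnrichmentResult(_cmle_odds_ratio(t), float(p),
                            "chisq_yates" if yates else "chisq",
                            statistic=float(stat), table=t)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene Welch t-test results between two sample groups.

    ``table`` columns: t, p, q, fc (linear fold-change, folded so fc >= 1),
    log2fc (signed, group1 minus group0), direction (up/down/none; "up"
    means higher in group 1). Zero-variance genes are excluded and listed
    in ``excluded``.
    """

    table: pd.DataFrame
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


def differential_expression(expr: pd.DataFrame, labels,
                            fc_thresh: float = 1.5,
                            fdr_thresh: float = 0.01) -> DEResult:
    """Welch t-test per gene between two groups with FC/FDR flagging.

    ``expr`` is genes x samples on the log2 scale; ``labels`` is a binary
    vector over samples (0/1 or two distinct values; the larger/second sorted
    value is "group 1"). Fold-change is 2**(difference of group means of
    log2 expression); a gene is flagged up/down only when the folded FC
    exceeds ``fc_thresh`` and the BH q-value is below ``fdr_thresh``.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != expr.shape[1]:
        raise ValueError("labels length must match number of samples")
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("labels must have exactly two levels")
    g0 = expr.loc[:, labels == levels[0]]
    g1 = expr.loc[:, labels == levels[1]]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    x0, x1 = g0.to_numpy(float), g1.to_numpy(float)
    var0, var1 = x0.var(axis=1, ddof=1), x1.var(axis=1, ddof=1)
    degenerate = (var0 == 0) & (var1 == 0)
    excluded = list(expr.index[degenerate])
    if excluded:
        warnings.warn(f"{len(excluded)} zero-variance genes excluded from "
                      "differential expression")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(x1, x0, axis=1, equal_var=False)
    keep = ~degenerate
    idx = expr.index[keep]
    log2fc = x1.mean(axis=1) - x0.mean(axis=1)
    q = bh_fdr(p[keep])
    tab = pd.DataFrame({
        "t": t[keep],
        "p": p[keep],
        "q": q,
        "log2fc": log2fc[keep],
        "fc": 2.0 ** np.abs(log2fc[keep]),
    }, index=idx)
    sig = (tab["fc"] > fc_thresh) & (tab["q"] < fdr_thresh)
    tab["direction"] = "none"
    tab.loc[sig & (tab["log2fc"] > 0), "direction"] = "up"
    tab.loc[sig & (tab["log2fc"] < 0), "direction"] = "down"
    return DEResult(table=tab,
                    up=list(tab.index[tab["direction"] == "up"]),
                    down=list(tab.index[tab["direction"] == "down"]),
                    excluded=excluded)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mutual_information(x, y) -> float:
    """Plug-in mutual information (nats) of two discrete vectors."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    return float(mutual_info_score(x, y))


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def gene_set_enrichment(query, reference, universe) -> EnrichmentResult:
    """Fisher enrichment of ``query`` against ``reference`` in ``universe``.

    Builds [[|Q∩R|, |Q\\R|], [|R\\Q|, |U\\(Q∪R)|]] and delegates to
    :func:`fisher_exact`.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    reference = set(reference) & universe
    a = len(query & reference)
    b = len(query - reference)
    c = len(reference - query)
    d = len(universe) - a - b - c
    return fisher_exact([[a, b], [c, d]])


# ---------------------------------------------------------------------------
# small linear models
# ---------------------------------------------------------------------------

def fit_interaction_model(y, time, group=None) -> dict:
    """OLS of ``y`` on time and, when a two-level group is given, time:group.

    Fits ``y ~ time + time:group`` and reports the interaction coefficient's
    t statistic and two-sided p. With a constant (or absent) group the model
    reduces to the simple dose-response regression ``y ~ time`` and the slope
    term is reported instead.
    """
    y = np.asarray(y, float)
    time = np.asarray(time, float)
    if group is None:
        group = np.zeros_like(time)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size > 2:
        raise ValueError("group must be binary")

    if levels.size == 1:
        X = sm.add_constant(time)
        term = 1
    else:
        for lev in levels:
            if np.unique(time[group == lev]).size < 3:
                raise ValueError("need >= 3 distinct time points per group")
        g = (group == levels[1]).astype(float)
        X = sm.add_constant(np.column_stack([time, time * g]))
        term = 2
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params[term])
    t_val = float(fit.tvalues[term])
    p_val = float(fit.pvalues[term])
    # exact fit: residual variance ~ 0 makes the t ratio 0/0; report a
    # machine-zero coefficient as t = 0 rather than amplified noise
    scale = float(np.abs(y).max()) + 1.0
    if fit.ssr < 1e-18 * len(y) * scale ** 2 and abs(coef) < 1e-8 * scale:
        t_val, p_val = 0.0, 1.0
    return {"t_value": t_val, "p": p_val, "coef": coef, "model": fit}
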