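"""Elastic-net Invasiveness Score (IVS): training, scoring, trichotomization,
and survival association.

The IVS is the predicted probability, in [0, 1], that a tumor belongs to the
invasive expression cluster. A penalized regression on z-transformed
signature-gene expression is trained against the binary cluster labels
(elastic-net mixing alpha = 0.02, penalty weight lambda = 0.1 in the glmnet
parameterization). Scored cohorts are split into indolent / intermediate /
invasive by the local minima of a 40-bin score histogram, and the classes
are related to patient survival by Cox regression and log-rank testing with
administrative censoring at five years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.special import expit
from sklearn.linear_model import ElasticNet, LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "IVSModel",
    "IVSResult",
    "ztransform",
    "train_ivs_model",
    "score_ivs",
    "trichotomize",
    "survival_association",
]

CLASS_NAMES = ("indolent", "intermediate", "invasive")


def ztransform(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, sd 1 within this matrix.

    Each cohort is standardized independently, which absorbs platform
    differences between training and test datasets. Population-sd
    (``ddof=0``) is the default; pass ``ddof=1`` for the sample-sd
    convention. Zero-variance genes become all-zero rows with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-transform")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance genes set to 0 "
                      "in z-transform")
        sd = sd.mask(zero, 1.0)
    return expr.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class IVSModel:
    """Fitted penalized-regression invasiveness classifier.

    ``alpha`` is the elastic-net mixing weight and ``lam`` the overall
    penalty weight, both in the glmnet convention (the objective is the mean
    loss plus ``lam * sum((1-alpha)/2 * b_j**2 + alpha * |b_j|)``).
    """

    intercept: float
    coef: pd.Series  # indexed by training gene
    alpha: float
    lam: float
    loss_family: str  # "logistic" or "squared"

    @property
    def genes(self) -> list[str]:
        return list(self.coef.index)

    def nonzero_genes(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])


def train_ivs_model(expr_z: pd.DataFrame, labels, alpha: float = 0.02,
                    lam: float = 0.1,
                    loss_family: str = "logistic") -> IVSModel:
    """Fit the elastic net of class labels on z-scored signature expression.

    ``expr_z`` is genes x samples (already restricted to the signature genes
    and z-transformed); ``labels`` is 0 = non-invasive, 1 = invasive. The
    logistic family is the default because the score is used as a predicted
    probability; the squared family fits the same penalty on a linear model
    and its predictions are clipped into [0, 1] at scoring time.

    The glmnet (alpha, lam) pair is mapped onto scikit-learn's solvers:
    ``l1_ratio = alpha`` and, for the logistic family,
    ``C = 1 / (n_samples * lam)``; for the squared family the ElasticNet
    ``alpha`` parameter is ``lam`` directly.
    """
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain both classes")
    X = expr_z.to_numpy(float).T  # samples x genes
    n = X.shape[0]
    if loss_family == "logistic":
        clf = LogisticRegression(solver="saga", l1_ratio=alpha,
                                 C=1.0 / (n * lam), max_iter=20000, tol=1e-8)
        clf.fit(X, y)
        intercept = float(clf.intercept_[0])
        coef = clf.coef_[0]
    elif loss_family == "squared":
        reg = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=50000, tol=1e-8)
        reg.fit(X, y.astype(float))
        intercept = float(reg.intercept_)
        coef = reg.coef_
    else:
        raise ValueError(f"unknown loss family: {loss_family}")
    return IVSModel(intercept=intercept,
                    coef=pd.Series(coef, index=expr_z.index),
                    alpha=alpha, lam=lam, loss_family=loss_family)


def score_ivs(model: IVSModel, expr_z: pd.DataFrame,
              min_overlap: float = 0.5) -> pd.Series:
    """Score samples of a z-transformed cohort with a trained model.

    Genes are matched by identifier; model genes absent from the cohort are
    dropped from the linear predictor (count logged). If fewer than
    ``min_overlap`` of the model genes are present, scoring is refused.
    """
    present = [g for g in model.genes if g in expr_z.index]
    overlap = len(present) / len(model.genes)
    if overlap < min_overlap:
        missing = sorted(set(model.genes) - set(present))
        raise ValueError(
            f"only {overlap:.0%} of model genes present (need "
            f">= {min_overlap:.0%}); missing e.g. {missing[:10]}")
    dropped = len(model.genes) - len(present)
    if dropped:
        logger.info("score_ivs: %d model genes absent from cohort, dropped",
                    dropped)
    eta = model.intercept + expr_z.loc[present].T.to_numpy(float) @ \
        model.coef.loc[present].to_numpy(float)
    if model.loss_family == "logistic":
        scores = expit(eta)
    else:
        scores = np.clip(eta, 0.0, 1.0)
    return pd.Series(scores, index=expr_z.columns, name="ivs")


@dataclass
class IVSResult:
    """Trichotomized invasiveness scores."""

    scores: pd.Series
    classes: pd.Series  # indolent | intermediate | invasive
    bin_edges: np.ndarray  # 41 edges over [0, 1]
    minima_bins: list[int]  # bin indices of detected local minima
    lower: float  # scores < lower -> indolent
    upper: float  # scores > upper -> invasive
    fallback: bool = False

    def class_counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(CLASS_NAMES, fill_value=0)


def _local_minima(counts: np.ndarray) -> list[int]:
    """Indices of local-minimum bins; plateaus collapse to their leftmost bin.

    A run of equal counts is a minimum when both flanking counts are >= the
    run's count with at least one strictly greater; runs touching either end
    of the histogram have no flank there and are not minima.
    """
    n = len(counts)
    minima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        if i > 0 and j < n - 1:
            left, right, c = counts[i - 1], counts[j + 1], counts[i]
            if left >= c and right >= c and (left > c or right > c):
                minima.append(i)
        i = j + 1
    return minima


def trichotomize(scores, n_bins: int = 40) -> IVSResult:
    """Split IVS values into indolent / intermediate / invasive classes.

    The scores are histogrammed on [0, 1] with ``n_bins`` equal bins (width
    0.025 by default). The smallest- and largest-position local minima of
    the histogram define the cut points: scores strictly below the left edge
    of the first minimum are indolent, strictly above the right edge of the
    last minimum are invasive, and everything between is intermediate.

    If the histogram has no interior local minimum (or fewer than three
    non-empty bins), fixed cutoffs at 1/3 and 2/3 are used with a warning.
    """
    scores = pd.Series(scores).astype(float)
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(scores.to_numpy(), bins=edges)
    minima = _local_minima(counts)
    fallback = False
    if (counts > 0).sum() < 3 or not minima:
        warnings.warn("no interior local minimum in the score histogram; "
                      "falling back to fixed cutoffs 1/3 and 2/3")
        lower, upper = 1.0 / 3.0, 2.0 / 3.0
        minima, fallback = [], True
    else:
        lower = float(edges[minima[0]])        # left edge of first minimum
        upper = float(edges[minima[-1] + 1])   # right edge of last minimum
    classes = pd.Series("intermediate", index=scores.index, name="ivs_class")
    classes[scores < lower] = "indolent"
    classes[scores > upper] = "invasive"
    return IVSResult(scores=scores, classes=classes, bin_edges=edges,
                     minima_bins=minima, lower=lower, upper=upper,
                     fallback=fallback)


def survival_association(scores, survival: pd.DataFrame,
                         covariates=("age", "sex", "stage"),
                         time_col: str = "time", event_col: str = "event",
                         censor_at: float | None = 60.0) -> dict:
    """Cox and log-rank association of the IVS with patient survival.

    ``scores`` may be a raw score vector or an :class:`IVSResult`; with a
    result, a log-rank test across the three classes is added. ``survival``
    is indexed by sample with a duration column, an event indicator, and the
    adjustment covariates (``Survival ~ age + sex + stage + IVS`` by
    default; pass e.g. ``("age", "sex", "histology")`` for marker-group
    analyses). Follow-up is administratively censored at ``censor_at``
    (same units as ``time_col``; 60 months = 5 years by default).
    """
    result = scores if isinstance(scores, IVSResult) else None
    s = result.scores if result is not None else pd.Series(scores)
    common = [i for i in s.index if i in survival.index]
    if not common:
        raise ValueError("no shared samples between scores and survival")
    df = survival.loc[common, [time_col, event_col, *covariates]].copy()
    df["ivs"] = s.loc[common]
    if censor_at is not None:
        over = df[time_col] > censor_at
        df.loc[over, event_col] = 0
        df.loc[over, time_col] = censor_at
    if int(df[event_col].sum()) == 0:
        raise ValueError("no events after censoring")

    # non-numeric covariates (sex, stage, histology) -> dummies
    model_df = pd.get_dummies(df, drop_first=True, dtype=float)
    cph = CoxPHFitter()
    cph.fit(model_df, duration_col=time_col, event_col=event_col)
    out = {
        "hr_ivs": float(np.exp(cph.params_["ivs"])),
        "log_hr_ivs": float(cph.params_["ivs"]),
        "ci_log_hr": (float(cph.confidence_intervals_.loc["ivs"].iloc[0]),
                      float(cph.confidence_intervals_.loc["ivs"].iloc[1])),
        "p_ivs": float(cph.summary.loc["ivs", "p"]),
        "lrt_p": float(cph.log_likelihood_ratio_test().p_value),
        "cox": cph,
    }
    if result is not None:
        classes = result.classes.loc[common]
        present = classes.unique()
        if len(present) > 1:
            lr = multivariate_logrank_test(df[time_col], classes,
                                           df[event_col])
            out["logrank_p"] = float(lr.p_value)
        km = {}
        for cls in present:
            mask = classes == cls
            f = KaplanMeierFitter(label=str(cls))
            f.fit(df.loc[mask, time_col], df.loc[mask, event_col])
            km[str(cls)] = f
        out["km"] = km
    return out
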