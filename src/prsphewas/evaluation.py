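"""Train/test evaluation of a PRS on one case-control study.

A logistic model with the standardized PRS as the only covariate is fit on a
stratified 1/3 training split; the remaining 2/3 test split feeds four
metrics: AUC (Mann-Whitney, DeLong 95% CI), Hosmer-Lemeshow calibration,
Brier score, and Nagelkerke's pseudo-R^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import firth_fit
from .errors import EstimationError
from .phenome import MatchedStudy
from .prs_engine import ScoreVector, ztransform

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMetrics",
    "split_train_test",
    "evaluate_prs",
    "auc_ci",
    "hosmer_lemeshow",
    "brier",
    "nagelkerke",
]


@dataclass
class EvalMetrics:
    auc: float
    auc_lower: float
    auc_upper: float
    hl_chi2: float
    hl_p: float
    hl_groups: int
    brier: float
    nagelkerke_r2: float
    n_train: int
    n_test: int
    warnings: tuple = ()


def split_train_test(study: MatchedStudy, train_frac: float = 1 / 3, seed: int = 0):
    """Case-status-stratified random split; returns (train_ids, test_ids)."""
    if study.n_cases == 0 or study.n_controls == 0:
        raise EstimationError("study must contain both cases and controls")
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        train, test = [], []
        for group in (list(study.case_ids), list(study.control_ids)):
            perm = rng.permutation(len(group))
            n_train = int(round(train_frac * len(group)))
            idx = set(perm[:n_train].tolist())
            train += [group[i] for i in range(len(group)) if i in idx]
            test += [group[i] for i in range(len(group)) if i not in idx]
        case_set = set(study.case_ids)
        ok = any(t in case_set for t in train) and any(t not in case_set for t in train) \
            and any(t in case_set for t in test) and any(t not in case_set for t in test)
        if ok:
            return train, test
        logger.warning("degenerate split (a class missing); reshuffling once")
    raise EstimationError("could not produce a split containing both classes")


def auc_ci(scores, labels, level: float = 0.95):
    """Mann-Whitney AUC with a DeLong-variance confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise EstimationError("AUC needs both classes present")
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values (DeLong)
    v10 = (stats.rankdata(np.concatenate([pos, neg]))[:m] -
           stats.rankdata(pos)) / n
    v01 = 1.0 - (stats.rankdata(np.concatenate([neg, pos]))[:n] -
                 stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    zc = stats.norm.ppf(0.5 + level / 2.0)
    half = zc * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def hosmer_lemeshow(pred, labels, groups: int = 10):
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    chi2 = sum (O - E)^2 / (E (1 - E/n_g)), df = groups - 2. Empty deciles
    (ties in predictions) are merged with their neighbor and df adjusted.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if groups < 2:
        raise ValueError("need at least 2 groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bins = pd.qcut(pred, groups, labels=False, duplicates="drop")
    actual_groups = int(bins.max()) + 1
    if actual_groups < 3:
        # heavy ties collapsed the deciles; group by distinct predicted values
        bins, uniques = pd.factorize(pred, sort=True)
        actual_groups = len(uniques)
    if actual_groups < groups:
        logger.info("HL: %d empty decile(s) merged; df adjusted", groups - actual_groups)
    if actual_groups < 3:
        raise EstimationError("too few distinct prediction groups for the HL test")
    chi2 = 0.0
    for g in range(actual_groups):
        sel = bins == g
        ng = int(sel.sum())
        obs = labels[sel].sum()
        exp = pred[sel].sum()
        denom = exp * (1.0 - exp / ng)
        if denom <= 0:
            denom = np.finfo(float).tiny
        chi2 += (obs - exp) ** 2 / denom
    df = actual_groups - 2
    return float(chi2), float(stats.chi2.sf(chi2, df)), actual_groups


def brier(pred, labels) -> float:
    """Mean squared error of predicted probabilities."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    return float(np.mean((pred - labels) ** 2))


def nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    """Cox-Snell R^2 rescaled by its maximum 1 - exp(2 ll_null / n)."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def _binary_loglik(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    """PRS-only logistic fit; falls back to the Firth fit on separation."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise np.linalg.LinAlgError
        return np.asarray(res.params)
    except Exception:
        logger.info("logistic MLE unstable (separation?); using Firth fallback")
        fit = firth_fit(np.column_stack([np.ones_like(x), x]), y)
        return fit.coef


def evaluate_prs(
    study: MatchedStudy,
    prs: ScoreVector | pd.Series,
    seed: int = 0,
    train_frac: float = 1 / 3,
) -> EvalMetrics:
    """Fit PRS-only logistic model on the training third, evaluate on the rest.

    The PRS is standardized over the study's analytical set. No additional
    covariates enter the evaluation model.
    """
    raw = prs.raw if isinstance(prs, ScoreVector) else prs
    z = ztransform(raw, study.analytic_ids)
    case_set = set(study.case_ids)
    train, test = split_train_test(study, train_frac, seed)
    x_tr = z.loc[train].to_numpy()
    y_tr = np.array([1.0 if t in case_set else 0.0 for t in train])
    x_te = z.loc[test].to_numpy()
    y_te = np.array([1.0 if t in case_set else 0.0 for t in test])
    coef = _fit_logistic(x_tr, y_tr)
    pred = 1.0 / (1.0 + np.exp(-(coef[0] + coef[1] * x_te)))
    warns = []
    if np.ptp(pred) < 1e-12:
        warns.append("degenerate test predictions (constant)")
    auc, lo, hi = auc_ci(x_te, y_te)
    try:
        hl_chi2, hl_p, hl_groups = hosmer_lemeshow(pred, y_te)
    except EstimationError as exc:
        warns.append(str(exc))
        hl_chi2, hl_p, hl_groups = np.nan, np.nan, 0
    ll_model = _binary_loglik(y_te, pred)
    ll_null = _binary_loglik(y_te, np.full_like(y_te, y_te.mean()))
    return EvalMetrics(
        auc=auc,
        auc_lower=lo,
        auc_upper=hi,
        hl_chi2=hl_chi2,
        hl_p=hl_p,
        hl_groups=hl_groups,
        brier=brier(pred, y_te),
        nagelkerke_r2=nagelkerke(ll_model, ll_null, len(y_te)),
        n_train=len(train),
        n_test=len(test),
        warnings=tuple(warns),
    )


def metrics_table(rows: list) -> pd.DataFrame:
    """rows: list of (trait, method_tag, EvalMetrics)."""
    recs = [
        (t, m, e.auc, e.auc_lower, e.auc_upper, e.hl_chi2, e.hl_p, e.brier,
         e.nagelkerke_r2, e.n_train, e.n_test)
        for t, m, e in rows
    ]
    return pd.DataFrame(
        recs,
        columns=["TRAIT", "PRS_METHOD", "AUC", "AUC_L", "AUC_U", "HL_CHI2", "HL_P",
                 "BRIER", "NAGELKERKE_R2", "N_TRAIN", "N_TEST"],
    )
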