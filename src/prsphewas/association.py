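"""Firth bias-reduced logistic regression and the PheWAS modes built on it.

The Firth fit maximizes the Jeffreys-prior-penalized log-likelihood
l(beta) + 0.5 log det I(beta), which yields finite estimates under complete
separation. ``run_phewas`` fits, per matched case-control study, the model

    logit P(case) = b0 + b_PRS * PRS + b_Age Age + b_Sex Sex + b_Array Array
                    + b_PC1..4 PC1..4

with the PRS standardized within the study's analytical set, and applies the
phenome-wide Bonferroni correction over the studies actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError
from .phenome import MatchedStudy
from .prs_engine import ScoreVector, ztransform

logger = logging.getLogger(__name__)

__all__ = [
    "FirthFit",
    "PhewasResult",
    "firth_fit",
    "run_phewas",
    "exclusion_phewas",
    "secondary_predictor_model",
    "build_design",
]


@dataclass
class FirthFit:
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    converged: bool
    iterations: int
    loglik: float  # penalized log-likelihood at the optimum
    names: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p": self.p_values},
            index=self.names or range(len(self.coef)),
        )

    def wald_ci(self, idx: int, level: float = 0.95) -> tuple:
        zc = stats.norm.ppf(0.5 + level / 2.0)
        return self.coef[idx] - zc * self.se[idx], self.coef[idx] + zc * self.se[idx]


def _penalized_loglik(X, y, w, beta):
    eta = X @ beta
    # numerically stable log-likelihood
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    if info.shape[0] == 2:  # closed form avoids LAPACK overhead in hot loops
        det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
        if det <= 0:
            return -np.inf
        return ll + 0.5 * np.log(det)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    names: list | None = None,
    pl_pvalues: bool = False,
) -> FirthFit:
    """Firth-penalized logistic regression via modified-score Newton iterations.

    ``X`` must include the intercept column and be full rank (rank deficiency
    raises, naming the aliased columns). ``weights`` are optional frequency
    weights. Wald p-values from the penalized-likelihood information matrix by
    default; ``pl_pvalues=True`` replaces them with penalized-likelihood-ratio
    p-values (each coefficient refit at zero). Non-convergence after
    ``max_iter`` is flagged on the result, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, k = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = 1e-8 * max(1.0, diag.max(initial=1.0))
    if (diag < scale).any() or len(diag) < k:
        aliased = [names[i] for i in range(min(k, len(diag))) if diag[i] < scale]
        aliased += names[len(diag):]
        raise EstimationError(f"design matrix is rank deficient; aliased columns: {aliased}")

    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, w, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1.0 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        if k == 2:
            det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
            info_inv = (
                np.array([[info[1, 1], -info[0, 1]], [-info[1, 0], info[0, 0]]]) / det
                if det > 0
                else np.linalg.pinv(info)
            )
        else:
            try:
                info_inv = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                info_inv = np.linalg.pinv(info)
        # leverages of the weighted design: diag of W^1/2 X info^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (w * (y - p) + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving on the penalized likelihood
        new_ll = -np.inf
        for half in range(16):
            cand = beta + step
            new_ll = _penalized_loglik(X, y, w, cand)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if new_ll < ll - 1e-6:
            break  # cannot improve; report flagged result
        beta = cand
        ll = new_ll
        # convergence is linear (the step uses the unpenalized information);
        # a vanishing accepted step means the optimum is resolved
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    if not converged:
        # the modified-score direction can crawl on flat penalized surfaces
        # (near-separation with nuisance covariates); polish with BFGS on the
        # exact penalized likelihood and gradient
        def neg(betav):
            etav = X @ betav
            llv = float(np.sum(w * (y * etav - np.logaddexp(0.0, etav))))
            pv = 1.0 / (1.0 + np.exp(-etav))
            Wv = w * pv * (1.0 - pv)
            XWv = X * Wv[:, None]
            infov = X.T @ XWv
            sign, logdet = np.linalg.slogdet(infov)
            if sign <= 0:
                return np.inf, np.zeros_like(betav)
            try:
                infov_inv = np.linalg.inv(infov)
            except np.linalg.LinAlgError:
                infov_inv = np.linalg.pinv(infov)
            hv = np.einsum("ij,jk,ik->i", X, infov_inv, XWv)
            grad = X.T @ (w * (y - pv) + hv * (0.5 - pv))
            return -(llv + 0.5 * logdet), -grad

        res = optimize.minimize(neg, beta, jac=True, method="BFGS",
                                options={"gtol": tol, "maxiter": 500})
        if np.isfinite(res.fun) and -res.fun >= ll - 1e-9:
            beta = res.x
            ll = -res.fun
            converged = bool(np.max(np.abs(res.jac)) < 100 * tol)
            it += res.nit
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    from scipy.special import ndtr

    pvals = np.clip(2.0 * ndtr(-np.abs(z)), np.finfo(float).tiny, 1.0)
    if pl_pvalues:
        pvals = _pl_pvalues(X, y, w, beta, ll, tol, max_iter)
    if not converged:
        logger.warning("Firth fit did not converge after %d iterations", it)
    return FirthFit(coef=beta, se=se, p_values=pvals, converged=converged,
                    iterations=it, loglik=ll, names=names)


def _constrained_pen_loglik(X, y, w, j, tol, max_iter):
    """Maximize the full-model penalized likelihood with coefficient j fixed at 0."""
    n, k = X.shape
    free = [i for i in range(k) if i != j]
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, w, beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = w * p * (1.0 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (w * (y - p) + h * (0.5 - p))
        if np.max(np.abs(score[free])) < tol:
            break
        step_free = np.linalg.solve(info[np.ix_(free, free)], score[free])
        step = np.zeros(k)
        step[free] = step_free
        for _half in range(16):
            cand = beta + step
            new_ll = _penalized_loglik(X, y, w, cand)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if new_ll < ll - 1e-6:
            break
        beta = cand
        ll = new_ll
    return ll


def _pl_pvalues(X, y, w, beta_full, ll_full, tol, max_iter):
    """Penalized-likelihood-ratio p-values: each coefficient profiled to zero
    inside the full model (the penalty keeps its full dimension)."""
    k = X.shape[1]
    pvals = np.ones(k)
    for j in range(k):
        ll0 = _constrained_pen_loglik(X, y, w, j, tol, max_iter)
        lr = 2.0 * (ll_full - ll0)
        pvals[j] = float(np.clip(stats.chi2.sf(max(lr, 0.0), df=1), np.finfo(float).tiny, 1.0))
    return pvals


@dataclass
class PhewasResult:
    phecode: str
    n_case: int
    n_control: int
    beta_prs: float
    se: float
    p: float
    direction: str  # up | down
    bonferroni_significant: bool
    converged: bool = True
    description: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_prs))


def build_design(
    subjects: pd.DataFrame,
    ids: list,
    prs_z: pd.Series | None,
    extra: dict | None = None,
):
    """Design matrix [1, PRS?, extra?, AGE, SEX, ARRAY dummies, PC1-4].

    Zero-variance covariates within the analytical set are dropped with a log
    entry (this also handles single-sex phenotypes). Categorical columns with
    more than two levels become dummy indicators.
    """
    sub = subjects.set_index("SUBJECT_ID").loc[ids]
    cols: dict = {"const": np.ones(len(ids))}
    if prs_z is not None:
        cols["PRS"] = prs_z.loc[ids].to_numpy()
    for name, vals in (extra or {}).items():
        cols[name] = np.asarray(vals, dtype=float)
    cols["AGE"] = sub["AGE"].to_numpy(dtype=float)
    sex_levels = sorted(sub["SEX"].unique())
    if len(sex_levels) > 1:
        for lev in sex_levels[1:]:
            cols[f"SEX[{lev}]"] = (sub["SEX"] == lev).to_numpy(dtype=float)
    else:
        logger.info("single-sex analytical set; SEX dropped")
    array_levels = sorted(sub["ARRAY"].unique())
    for lev in array_levels[1:]:
        cols[f"ARRAY[{lev}]"] = (sub["ARRAY"] == lev).to_numpy(dtype=float)
    for pc in ("PC1", "PC2", "PC3", "PC4"):
        cols[pc] = sub[pc].to_numpy(dtype=float)
    names, mats = [], []
    for name, v in cols.items():
        if name != "const" and np.std(v) == 0.0:
            logger.info("covariate %s has zero variance; dropped", name)
            continue
        names.append(name)
        mats.append(v)
    return np.column_stack(mats), names


def _fit_study(study: MatchedStudy, prs_raw: pd.Series, subjects: pd.DataFrame,
               pl_pvalues: bool = False) -> tuple:
    ids = study.analytic_ids
    z = ztransform(prs_raw, ids)
    X, names = build_design(subjects, ids, z)
    y = np.zeros(len(ids))
    y[: study.n_cases] = 1.0
    fit = firth_fit(X, y, names=names, pl_pvalues=pl_pvalues)
    j = names.index("PRS")
    return fit, j


def run_phewas(
    prs: ScoreVector | pd.Series,
    studies: list,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    pl_pvalues: bool = False,
    descriptions: dict | None = None,
) -> list:
    """One Firth fit per study; Bonferroni threshold alpha / n tested."""
    raw = prs.raw if isinstance(prs, ScoreVector) else prs
    results = []
    for study in studies:
        fit, j = _fit_study(study, raw, subjects, pl_pvalues)
        beta = float(fit.coef[j])
        results.append(
            PhewasResult(
                phecode=study.phecode,
                n_case=study.n_cases,
                n_control=study.n_controls,
                beta_prs=beta,
                se=float(fit.se[j]),
                p=float(fit.p_values[j]),
                direction="up" if beta > 0 else "down",
                bonferroni_significant=False,
                converged=fit.converged,
                description=(descriptions or {}).get(study.phecode, ""),
            )
        )
    n_tested = len(results)
    if n_tested:
        cut = alpha / n_tested
        for r in results:
            r.bonferroni_significant = r.p < cut
    return results


def exclusion_phewas(
    prs: ScoreVector | pd.Series,
    studies: list,
    exclusion_phecodes: list,
    incidence: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    min_cases: int = 50,
    pl_pvalues: bool = False,
) -> list:
    """PheWAS after removing every subject carrying an exclusion phecode.

    Studies for the excluded phecodes themselves are dropped, as are studies
    whose case count falls to ``min_cases`` or below; the Bonferroni
    denominator is the number of studies actually tested.
    """
    if not exclusion_phecodes:
        return run_phewas(prs, studies, subjects, alpha, pl_pvalues)
    excl_set = set(map(str, exclusion_phecodes))
    excluded_subjects = set(
        incidence.loc[incidence["PHECODE"].astype(str).isin(excl_set), "SUBJECT_ID"]
    )
    reduced = []
    for study in studies:
        if str(study.phecode) in excl_set:
            continue
        cases = [c for c in study.case_ids if c not in excluded_subjects]
        controls = [c for c in study.control_ids if c not in excluded_subjects]
        if len(cases) <= min_cases or not controls:
            continue
        reduced.append(
            MatchedStudy(
                phecode=study.phecode,
                case_ids=cases,
                control_ids=controls,
                achieved_ratio=len(controls) / len(cases),
                matching_mode=study.matching_mode,
            )
        )
    return run_phewas(prs, reduced, subjects, alpha, pl_pvalues)


def secondary_predictor_model(
    incidence: pd.DataFrame,
    secondary_phecode: str,
    primary_phecode: str,
    subjects: pd.DataFrame,
    lag_days: int = 365,
    pl_pvalues: bool = False,
) -> FirthFit:
    """Does prior presence of a secondary diagnosis predict the primary one?

    The binary predictor is 1 for subjects whose first primary diagnosis came
    at least ``lag_days`` after their first secondary diagnosis, or who have
    the secondary diagnosis and never the primary; subjects whose primary
    followed the secondary within the lag (or preceded it) are excluded;
    subjects without the secondary diagnosis are the reference (predictor 0).
    Outcome: primary phenotype status. Firth fit with the standard covariates.
    """
    inc = incidence.copy()
    inc["PHECODE"] = inc["PHECODE"].astype(str)
    sec = inc[inc["PHECODE"] == str(secondary_phecode)].set_index("SUBJECT_ID")["FIRST_DATE"]
    pri = inc[inc["PHECODE"] == str(primary_phecode)].set_index("SUBJECT_ID")["FIRST_DATE"]
    rows = []
    for sid in subjects["SUBJECT_ID"]:
        has_sec, has_pri = sid in sec.index, sid in pri.index
        if not has_sec:
            rows.append((sid, 0, int(has_pri)))
            continue
        if not has_pri:
            rows.append((sid, 1, 0))
            continue
        delta = (pd.Timestamp(pri[sid]) - pd.Timestamp(sec[sid])).days
        if delta >= lag_days:
            rows.append((sid, 1, 1))
        # else: primary within the lag window (or before) -> excluded
    if not rows:
        raise EstimationError("no qualifying subjects for the secondary-predictor model")
    frame = pd.DataFrame(rows, columns=["SUBJECT_ID", "PREDICTOR", "OUTCOME"])
    if frame["OUTCOME"].nunique() < 2:
        raise EstimationError("primary outcome is constant among qualifying subjects")
    X, names = build_design(
        subjects, list(frame["SUBJECT_ID"]), None, extra={"PREDICTOR": frame["PREDICTOR"]}
    )
    return firth_fit(X, frame["OUTCOME"].to_numpy(dtype=float), names=names,
                     pl_pvalues=pl_pvalues)


def phewas_table(results: list, prs_tag: str = "", phenome_id: str = "") -> pd.DataFrame:
    rows = [
        (r.phecode, r.description, r.n_case, r.n_control, r.beta_prs, r.se, r.p,
         r.direction, r.bonferroni_significant, r.converged, prs_tag, phenome_id,
         len(results))
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["PHECODE", "DESCRIPTION", "N_CASE", "N_CONTROL", "BETA_PRS", "SE", "P",
                 "DIRECTION", "BONFERRONI_SIGNIFICANT", "CONVERGED", "PRS_METHOD",
                 "PHENOME_ID", "N_STUDIES"],
    )
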