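"""PheCode phenome construction: ICD event aggregation, case/control
definition with hierarchy exclusion, and matched analytical datasets.

PheCodes are hierarchical decimal strings ("172" -> "172.1" -> "172.11").
A subject carries a phecode when at least one ICD event maps to it or to a
descendant. Controls for a phecode exclude subjects carrying the phecode or
any hierarchical relative. Up to ``ratio`` controls are matched to each case
by Mahalanobis nearest neighbor on age and PC1-4 (per-covariate caliper of
0.25 SD) with exact matching on sex and genotyping array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "PhecodeDefinition",
    "MatchedStudy",
    "read_phecode_map",
    "phecode_parent",
    "phecode_ancestors",
    "map_codes_to_phecodes",
    "define_case_control",
    "match_controls",
    "build_phenome_studies",
]

DEFAULT_EXACT = ("SEX", "ARRAY")
DEFAULT_NN_VARS = ("AGE", "PC1", "PC2", "PC3", "PC4")


@dataclass(frozen=True)
class PhecodeDefinition:
    phecode: str
    description: str = ""
    icd9_codes: frozenset = frozenset()
    icd10_codes: frozenset = frozenset()


@dataclass
class MatchedStudy:
    """One phecode's case IDs and (matched) control IDs."""

    phecode: str
    case_ids: list
    control_ids: list
    match_map: dict = field(default_factory=dict)  # case -> list of controls
    achieved_ratio: float = 0.0
    matching_mode: str = "matched"
    dropped_cases: list = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)

    @property
    def analytic_ids(self) -> list:
        return list(self.case_ids) + list(self.control_ids)


def phecode_parent(phecode: str) -> str | None:
    """'172.11' -> '172.1' -> '172' -> None."""
    if "." not in phecode:
        return None
    head, tail = phecode.split(".", 1)
    if len(tail) == 1:
        return head
    return f"{head}.{tail[:-1]}"


def phecode_ancestors(phecode: str) -> list:
    out = []
    p = phecode_parent(phecode)
    while p is not None:
        out.append(p)
        p = phecode_parent(p)
    return out


def _is_descendant(code: str, of: str) -> bool:
    return of in phecode_ancestors(code)


def read_phecode_map(path_or_df) -> dict:
    """Parse a mapping table (PHECODE, DESCRIPTION, VOCAB, CODE) into
    :class:`PhecodeDefinition` objects keyed by phecode."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep="\t", dtype=str
    )
    required = {"PHECODE", "VOCAB", "CODE"}
    if not required.issubset(df.columns):
        raise ParseError(f"mapping table needs columns {sorted(required)}")
    bad = ~df["VOCAB"].isin(["ICD9", "ICD10"])
    if bad.any():
        raise ParseError(f"unknown vocabulary in mapping rows: {df.loc[bad, 'VOCAB'].unique()}")
    defs = {}
    for phecode, grp in df.groupby("PHECODE", sort=True):
        desc = str(grp["DESCRIPTION"].iloc[0]) if "DESCRIPTION" in grp.columns else ""
        defs[str(phecode)] = PhecodeDefinition(
            phecode=str(phecode),
            description=desc,
            icd9_codes=frozenset(grp.loc[grp["VOCAB"] == "ICD9", "CODE"]),
            icd10_codes=frozenset(grp.loc[grp["VOCAB"] == "ICD10", "CODE"]),
        )
    return defs


def map_codes_to_phecodes(events: pd.DataFrame, definitions: dict) -> pd.DataFrame:
    """Aggregate ICD events to a subject x phecode incidence table.

    Returns a DataFrame (SUBJECT_ID, PHECODE, FIRST_DATE): a subject carries a
    phecode when any event maps to it or to a descendant (ancestors of mapped
    codes are added by the hierarchy), FIRST_DATE is the earliest mapping
    event. Unmapped codes are counted and logged.
    """
    lookup = {}
    for d in definitions.values():
        for c in d.icd9_codes:
            lookup.setdefault(("ICD9", c), []).append(d.phecode)
        for c in d.icd10_codes:
            lookup.setdefault(("ICD10", c), []).append(d.phecode)
    ev = events.copy()
    ev["DATE"] = pd.to_datetime(ev["DATE"])
    keys = list(zip(ev["VOCAB"], ev["CODE"]))
    mapped_rows = []
    unmapped: dict = {}
    for (sid, date), key in zip(zip(ev["SUBJECT_ID"], ev["DATE"]), keys):
        phecodes = lookup.get(key)
        if not phecodes:
            unmapped[key] = unmapped.get(key, 0) + 1
            continue
        for pc in phecodes:
            mapped_rows.append((sid, pc, date))
            for anc in phecode_ancestors(pc):
                mapped_rows.append((sid, anc, date))
    if unmapped:
        logger.info("unmapped codes: %s", dict(sorted(unmapped.items())))
    if not mapped_rows:
        return pd.DataFrame(columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"])
    inc = pd.DataFrame(mapped_rows, columns=["SUBJECT_ID", "PHECODE", "FIRST_DATE"])
    inc = inc.groupby(["SUBJECT_ID", "PHECODE"], as_index=False)["FIRST_DATE"].min()
    return inc


def define_case_control(incidence: pd.DataFrame, phecode: str, all_subject_ids):
    """Cases carry the phecode; the control pool excludes subjects carrying the
    phecode or any hierarchical ancestor/descendant of it."""
    carriers = set(incidence.loc[incidence["PHECODE"] == phecode, "SUBJECT_ID"])
    related_codes = set(phecode_ancestors(phecode))
    related_codes |= {
        c for c in incidence["PHECODE"].unique() if _is_descendant(str(c), phecode)
    }
    related = set(
        incidence.loc[incidence["PHECODE"].isin(related_codes), "SUBJECT_ID"]
    )
    pool = [s for s in all_subject_ids if s not in carriers and s not in related]
    cases = sorted(carriers & set(all_subject_ids))
    return cases, pool


def match_controls(
    cases: list,
    pool: list,
    covariates: pd.DataFrame,
    ratio: int = 10,
    caliper_sd: float = 0.25,
    exact: tuple = DEFAULT_EXACT,
    nn_vars: tuple = DEFAULT_NN_VARS,
    phecode: str = "",
) -> MatchedStudy:
    """Nearest-neighbor Mahalanobis matching without replacement.

    For each case in input order, up to ``ratio`` controls are taken from the
    pool members that are equal on the exact variables and within
    ``caliper_sd`` standard deviations on every nearest-neighbor covariate,
    closest first by Mahalanobis distance on the standardized covariates.
    Cases with no eligible control are dropped (logged).
    """
    if not pool:
        raise ValueError("empty control pool")
    cov = covariates.set_index("SUBJECT_ID") if "SUBJECT_ID" in covariates.columns else covariates
    analytic = cov.loc[list(cases) + list(pool)]
    X = analytic[list(nn_vars)].astype(float)
    mu, sd = X.mean(), X.std(ddof=1).replace(0.0, 1.0)
    Z = (X - mu) / sd
    S = np.cov(Z.to_numpy().T)
    S_inv = np.linalg.pinv(np.atleast_2d(S))

    z_case = Z.loc[cases].to_numpy()
    z_pool = Z.loc[pool].to_numpy()
    e_case = analytic.loc[cases, list(exact)].to_numpy(dtype=object)
    e_pool = analytic.loc[pool, list(exact)].to_numpy(dtype=object)
    pool_arr = np.asarray(pool, dtype=object)
    used = np.zeros(len(pool), dtype=bool)

    match_map: dict = {}
    dropped = []
    for ci, case in enumerate(cases):
        ok = ~used
        for k in range(len(exact)):
            ok &= e_pool[:, k] == e_case[ci, k]
        diff = z_pool - z_case[ci]
        ok &= (np.abs(diff) <= caliper_sd).all(axis=1)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            dropped.append(case)
            continue
        d2 = np.einsum("ij,jk,ik->i", diff[cand], S_inv, diff[cand])
        take = cand[np.argsort(d2, kind="stable")[:ratio]]
        used[take] = True
        match_map[case] = list(pool_arr[take])
    if dropped:
        logger.info("phecode %s: %d case(s) with no eligible control dropped", phecode, len(dropped))
    kept_cases = [c for c in cases if c in match_map]
    controls = [c for case in kept_cases for c in match_map[case]]
    achieved = len(controls) / len(kept_cases) if kept_cases else 0.0
    return MatchedStudy(
        phecode=phecode,
        case_ids=kept_cases,
        control_ids=controls,
        match_map=match_map,
        achieved_ratio=achieved,
        matching_mode="matched",
        dropped_cases=dropped,
    )


def build_phenome_studies(
    incidence: pd.DataFrame,
    subjects: pd.DataFrame,
    min_cases: int = 50,
    mode: str = "matched",
    ratio: int = 10,
    caliper_sd: float = 0.25,
    exact: tuple = DEFAULT_EXACT,
    nn_vars: tuple = DEFAULT_NN_VARS,
    hierarchy_exclusion: bool = True,
    phecodes: list | None = None,
) -> list:
    """One study per phecode with case count strictly above ``min_cases``.

    ``mode='matched'`` runs nearest-neighbor matching; ``mode='unmatched'``
    keeps the full eligible control pool (sensitivity-analysis configuration).
    """
    all_ids = list(subjects["SUBJECT_ID"])
    counts = incidence.groupby("PHECODE")["SUBJECT_ID"].nunique()
    todo = phecodes if phecodes is not None else sorted(counts.index[counts > min_cases])
    studies = []
    for pc in todo:
        if counts.get(pc, 0) <= min_cases:
            continue
        if hierarchy_exclusion:
            cases, pool = define_case_control(incidence, pc, all_ids)
        else:
            carriers = set(incidence.loc[incidence["PHECODE"] == pc, "SUBJECT_ID"])
            cases = sorted(carriers)
            pool = [s for s in all_ids if s not in carriers]
        if len(cases) <= min_cases or not pool:
            continue
        if mode == "unmatched":
            studies.append(
                MatchedStudy(
                    phecode=pc,
                    case_ids=cases,
                    control_ids=list(pool),
                    achieved_ratio=len(pool) / len(cases),
                    matching_mode="unmatched",
                )
            )
        else:
            study = match_controls(cases, pool, subjects, ratio=ratio, caliper_sd=caliper_sd,
                                   exact=exact, nn_vars=nn_vars, phecode=pc)
            if study.n_cases <= min_cases:
                logger.info(
                    "phecode %s: only %d matchable case(s) after the caliper; study dropped",
                    pc, study.n_cases,
                )
                continue
            studies.append(study)
    return studies


def study_manifest(studies: list) -> pd.DataFrame:
    rows = [
        (s.phecode, s.n_cases, s.n_controls, round(s.achieved_ratio, 3), s.matching_mode)
        for s in studies
    ]
    return pd.DataFrame(rows, columns=["PHECODE", "N_CASES", "N_CONTROLS", "ACHIEVED_RATIO", "MODE"])
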