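"""Point-normal posterior reweighting of GWAS summary statistics under LD.

Marginal effects are standardized to the genotype-SD scale (beta_std = z /
sqrt(N)), reweighted under either the infinitesimal closed form or a Gibbs
sampler with a point-normal prior (causal fraction f, per-causal-variant
variance h2 / (M f)), and back-transformed to the per-allele scale. LD enters
through a sliding window of ``radius_snps`` variants on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clump_threshold import LdPanel
from .errors import EstimationError, LdpredDivergenceError
from .prs_engine import PrsModel
from .synthetic_data import is_ambiguous

logger = logging.getLogger(__name__)

__all__ = [
    "LdpredConfig",
    "MarginalEffects",
    "filter_ldpred_input",
    "estimate_h2_aggregate",
    "ldpred_inf",
    "ldpred_gibbs",
    "GibbsResult",
    "ldpred_model",
]

DEFAULT_FRACTIONS = (1.0, 0.1, 0.01, 0.001, 0.0001, 0.00001)


@dataclass(frozen=True)
class LdpredConfig:
    causal_fractions: tuple = DEFAULT_FRACTIONS
    radius_snps: int = 2800
    n_gwas: int = 0
    h2: float | str = "auto"
    burn_in: int = 100
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 < f <= 1.0) for f in self.causal_fractions):
            raise ValueError("causal fractions must be in (0, 1]")
        if self.radius_snps < 1:
            raise ValueError("radius_snps must be >= 1")


@dataclass
class MarginalEffects:
    """Standardized marginal effects aligned to an LD panel index.

    ``table`` columns: ID, CHROM, POS, EFFECT_ALLELE, OTHER_ALLELE, BETA
    (per-allele), SE, P, EAF, N, BETA_STD (z/sqrt(N) on the genotype-SD scale).
    Row order matches the LD panel's variant order.
    """

    table: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["BETA_STD"]).all():
            raise ValueError("non-finite standardized effects")

    def __len__(self) -> int:
        return len(self.table)


def filter_ldpred_input(stats_df: pd.DataFrame, panel: LdPanel, maf_min: float = 0.01,
                        target_ids=None) -> MarginalEffects:
    """Apply the default input filters: SNPs only, overlap between summary
    statistics / LD reference panel (/ target panel when given), MAF above
    ``maf_min``, non-ambiguous allele combinations."""
    df = stats_df.copy()
    single_base = df["EFFECT_ALLELE"].astype(str).str.fullmatch("[ACGT]") & df[
        "OTHER_ALLELE"
    ].astype(str).str.fullmatch("[ACGT]")
    df = df[single_base]
    amb = df.apply(lambda r: is_ambiguous(str(r["EFFECT_ALLELE"]), str(r["OTHER_ALLELE"])), axis=1)
    df = df[~amb.to_numpy()] if len(df) else df
    keep_ids = set(panel._index)
    if target_ids is not None:
        keep_ids &= set(target_ids)
    df = df[df["ID"].isin(keep_ids)]
    if "EAF" in df.columns:
        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
        df = df[maf > maf_min]
    if df.empty:
        raise EstimationError("no variants survive the input filters")
    pvar = panel.variants
    if {"A1", "A2"} <= set(pvar.columns):
        # align to the panel's forward strand (flipped rows are complemented;
        # rows matching neither orientation are dropped)
        from .synthetic_data import COMPLEMENT

        al = pvar.set_index("ID")[["A1", "A2"]]
        keep_rows, eas, oas = [], [], []
        for row in df.itertuples(index=False):
            a1, a2 = al.at[row.ID, "A1"], al.at[row.ID, "A2"]
            ea, oa = str(row.EFFECT_ALLELE), str(row.OTHER_ALLELE)
            if {ea, oa} == {a1, a2}:
                keep_rows.append(True); eas.append(ea); oas.append(oa)
            elif {COMPLEMENT[ea], COMPLEMENT[oa]} == {a1, a2}:
                keep_rows.append(True)
                eas.append(COMPLEMENT[ea]); oas.append(COMPLEMENT[oa])
            else:
                keep_rows.append(False); eas.append(ea); oas.append(oa)
        df = df.assign(EFFECT_ALLELE=eas, OTHER_ALLELE=oas).loc[keep_rows]
        if df.empty:
            raise EstimationError("no variants align to the panel alleles")
    order = panel.variants.set_index("ID").index.get_indexer(df["ID"])
    df = df.iloc[np.argsort(order)].reset_index(drop=True)
    n = int(df["N"].median())
    z = df["BETA"] / df["SE"]
    df["BETA_STD"] = (z / np.sqrt(df["N"])).astype(float)
    return MarginalEffects(table=df, n=n)


def _aligned_ld(effects: MarginalEffects, ld: LdPanel) -> np.ndarray:
    idx = [ld._index[v] for v in effects.table["ID"]]
    return ld.r_matrix[np.ix_(idx, idx)]


def estimate_h2_aggregate(effects: MarginalEffects, ld: LdPanel, n: int | None = None) -> float:
    """Aggregate heritability estimate from mean chi-square and mean LD score.

    h2 = M (mean chi2 - 1) / (N * mean ld score); clamped to [0.01, 0.99].
    """
    if len(effects) < 100:
        raise EstimationError("need >= 100 variants for the aggregate h2 estimator")
    n = n or effects.n
    D = _aligned_ld(effects, ld)
    ld_score = (D ** 2).sum(axis=1)
    mean_l = float(ld_score.mean())
    if not np.isfinite(mean_l) or mean_l <= 0:
        raise EstimationError("degenerate LD scores")
    chi2 = (effects.table["BETA_STD"].to_numpy() ** 2) * n
    m = len(effects)
    h2 = m * (float(chi2.mean()) - 1.0) / (n * mean_l)
    if not (0.01 <= h2 <= 0.99):
        logger.warning("aggregate h2 estimate %.4f outside [0.01, 0.99]; clamped", h2)
        h2 = float(np.clip(h2, 0.01, 0.99))
    return h2


def _resolve_h2(effects: MarginalEffects, ld: LdPanel, h2, n: int) -> float:
    if h2 == "auto":
        return estimate_h2_aggregate(effects, ld, n)
    return float(h2)


def ldpred_inf(effects: MarginalEffects, ld: LdPanel, h2: float | str = "auto",
               n: int | None = None, radius_snps: int = 2800) -> np.ndarray:
    """Infinitesimal-prior posterior mean weights (standardized scale).

    Solves (M/(N h2) I + D) w = beta_hat per chromosome, with D the windowed
    LD matrix restricted to ``radius_snps`` on each side. A singular system
    gets a small ridge jitter (logged).
    """
    n = n or effects.n
    h2 = _resolve_h2(effects, ld, h2, n)
    tab = effects.table
    beta = tab["BETA_STD"].to_numpy()
    m = len(tab)
    out = np.empty(m)
    D_full = _aligned_ld(effects, ld)
    offsets = np.arange(m)
    band = np.abs(offsets[:, None] - offsets[None, :]) <= radius_snps
    chroms = tab["CHROM"].to_numpy()
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        D = D_full[np.ix_(sel, sel)] * band[np.ix_(sel, sel)]
        np.fill_diagonal(D, 1.0)
        A = (m / (n * h2)) * np.eye(len(sel)) + D
        try:
            out[sel] = np.linalg.solve(A, beta[sel])
        except np.linalg.LinAlgError:
            logger.warning("singular LD system on chrom %s; applying ridge jitter", c)
            out[sel] = np.linalg.solve(A + 1e-6 * np.eye(len(sel)), beta[sel])
    return out


@dataclass
class GibbsResult:
    """Posterior-mean weights from the point-normal Gibbs chain."""

    weights: np.ndarray  # standardized scale, Rao-Blackwellized posterior means
    mc_se: np.ndarray  # per-variant Monte-Carlo SE (batch means)
    fraction: float
    h2: float
    iterations: int
    burn_in: int


def ldpred_gibbs(
    effects: MarginalEffects,
    ld: LdPanel,
    cfg: LdpredConfig,
    fraction: float,
) -> GibbsResult:
    """Point-normal Gibbs sampler over the marginal effects.

    Each sweep residualizes beta_hat against the current sampled effects of
    neighbors within the radius, computes the posterior inclusion probability
    under the point-normal prior with the given causal fraction, samples
    inclusion and effect, and accumulates Rao-Blackwellized posterior means
    post burn-in. Deterministic given ``cfg.seed``. Aborts when the running
    heritability of sampled effects exceeds 1.5x the prior h2.
    """
    if fraction not in cfg.causal_fractions:
        raise ValueError(f"fraction {fraction} not in configured causal fractions")
    n = cfg.n_gwas or effects.n
    h2 = _resolve_h2(effects, ld, cfg.h2, n)
    beta_hat = effects.table["BETA_STD"].to_numpy()
    m = len(beta_hat)
    D = _aligned_ld(effects, ld)
    offsets = np.arange(m)
    D = D * (np.abs(offsets[:, None] - offsets[None, :]) <= cfg.radius_snps)
    chroms = effects.table["CHROM"].to_numpy()
    D[chroms[:, None] != chroms[None, :]] = 0.0
    np.fill_diagonal(D, 1.0)

    rng = np.random.default_rng(cfg.seed)
    sigma2 = h2 / (m * fraction)  # per-causal-variant prior variance
    s2_post = sigma2 / (1.0 + n * sigma2)  # posterior variance if causal
    shrink = n * s2_post  # = sigma2/(sigma2 + 1/n)
    log_prior_odds = np.log(fraction) - np.log1p(-fraction) if fraction < 1.0 else np.inf

    b = np.zeros(m)  # sampled effects (chain state)
    total = np.zeros(m)
    n_batches = max(2, min(10, cfg.iterations // 20))
    batch_len = cfg.iterations // n_batches
    batch_sums = np.zeros((n_batches, m))
    kept = 0
    for it in range(cfg.burn_in + cfg.iterations):
        for j in range(m):
            resid = beta_hat[j] - (D[j] @ b - b[j])
            mean_j = shrink * resid
            if fraction >= 1.0:
                p_incl = 1.0
            else:
                # log Bayes factor causal vs null for the residualized estimate
                log_bf = 0.5 * (np.log(1.0 / n) - np.log(sigma2 + 1.0 / n)) + \
                    0.5 * resid * resid * (1.0 / (1.0 / n) - 1.0 / (sigma2 + 1.0 / n))
                odds = log_prior_odds + log_bf
                p_incl = 1.0 / (1.0 + np.exp(-odds)) if odds < 35 else 1.0
            if rng.random() < p_incl:
                b[j] = mean_j + np.sqrt(s2_post) * rng.standard_normal()
            else:
                b[j] = 0.0
            if it >= cfg.burn_in:
                rb = p_incl * mean_j
                total[j] += rb
                bi = min((it - cfg.burn_in) // batch_len, n_batches - 1)
                batch_sums[bi, j] += rb
        sampled_h2 = float(b @ b)
        if sampled_h2 > 1.5 * max(h2, 1e-6) + 0.05:
            raise LdpredDivergenceError(
                f"sampled heritability {sampled_h2:.3f} exceeded 1.5x prior h2 {h2:.3f} "
                f"at iteration {it}"
            )
        if it >= cfg.burn_in:
            kept += 1
    weights = total / kept
    lens = np.full(n_batches, batch_len, dtype=float)
    lens[-1] = cfg.iterations - batch_len * (n_batches - 1)
    batch_means = batch_sums / lens[:, None]
    mc_se = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return GibbsResult(weights=weights, mc_se=mc_se, fraction=fraction, h2=h2,
                       iterations=cfg.iterations, burn_in=cfg.burn_in)


def to_per_allele(effects: MarginalEffects, std_weights: np.ndarray) -> np.ndarray:
    """Back-transform standardized weights to the per-allele scale."""
    f = effects.table["EAF"].to_numpy()
    sd = np.sqrt(2.0 * f * (1.0 - f))
    sd[sd == 0] = np.inf
    return std_weights / sd


def ldpred_model(
    effects: MarginalEffects,
    std_weights: np.ndarray,
    fraction: float,
    trait_label: str = "",
) -> PrsModel:
    """Package reweighted effects as a scoreable PRS model (per-allele weights)."""
    tab = effects.table
    entries = pd.DataFrame(
        {
            "ID": tab["ID"],
            "CHROM": tab["CHROM"].astype(str),
            "POS": tab["POS"].astype(int),
            "EFFECT_ALLELE": tab["EFFECT_ALLELE"],
            "OTHER_ALLELE": tab["OTHER_ALLELE"],
            "WEIGHT": to_per_allele(effects, std_weights),
            "P": tab["P"].astype(float),
        }
    )
    return PrsModel(entries=entries, method_tag=f"ldpred@{fraction:g}", trait_label=trait_label)
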