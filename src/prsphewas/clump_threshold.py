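"""LD clumping and p-value thresholding of genome-wide summary statistics.

Greedy clumping keeps, per LD neighborhood, the variant with the smallest
p-value and discards correlated neighbors (r^2 > 0.1 within 1 Mb); the kept
set is then subset at six p-value thresholds to yield nested PRS models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prs_engine import PrsModel
from .synthetic_data import DosageMatrix

logger = logging.getLogger(__name__)

__all__ = ["LdPanel", "ClumpConfig", "compute_ld", "ld_clump", "threshold_subsets"]

DEFAULT_THRESHOLDS = (5e-9, 5e-8, 5e-7, 5e-6, 5e-5, 5e-4)


@dataclass
class LdPanel:
    """Windowed pairwise dosage correlations for a variant panel.

    ``r_matrix`` holds signed Pearson r with entries beyond the distance
    window (or across chromosomes) set to 0; the diagonal is 1.
    """

    variants: pd.DataFrame  # CHROM, POS, ID (coordinate-sorted)
    r_matrix: np.ndarray
    window_bp: int
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.variants["ID"])}

    def r2(self, id1: str, id2: str) -> float:
        i, j = self._index.get(id1), self._index.get(id2)
        if i is None or j is None:
            return 0.0
        return float(self.r_matrix[i, j] ** 2)

    def r2_row(self, variant_id: str) -> np.ndarray:
        return self.r_matrix[self._index[variant_id]] ** 2

    def ld_scores(self) -> np.ndarray:
        """Per-variant sum of windowed r^2 (including self)."""
        return (self.r_matrix ** 2).sum(axis=1)


@dataclass(frozen=True)
class ClumpConfig:
    p_entry: float = 5e-4
    r2_threshold: float = 0.1
    window_bp: int = 1_000_000
    maf_min: float = 0.005
    thresholds: tuple = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if any(t <= 0 or t > self.p_entry for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, p_entry]")


def compute_ld(dosages: DosageMatrix, window_bp: int = 1_000_000) -> LdPanel:
    """Pearson correlation of dosage vectors, zeroed beyond the bp window.

    Zero-variance (monomorphic) variants get r = 0 against everything, with a
    warning; their diagonal stays 1.
    """
    variants = dosages.variants.reset_index(drop=True)
    if not variants["POS"].is_monotonic_increasing:
        order = np.lexsort((variants["POS"].to_numpy(), variants["CHROM"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        mat = dosages.dosages[:, order]
    else:
        mat = dosages.dosages
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 subjects to estimate LD")
    sd = mat.std(axis=0)
    mono = sd == 0.0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variant(s); r set to 0", stacklevel=2)
    safe = mat.copy()
    safe[:, mono] = np.random.default_rng(0).standard_normal((mat.shape[0], int(mono.sum())))
    r = np.corrcoef(safe.T)
    r[mono, :] = 0.0
    r[:, mono] = 0.0
    pos = variants["POS"].to_numpy()
    chrom = variants["CHROM"].to_numpy()
    far = np.abs(pos[:, None] - pos[None, :]) > window_bp
    diff_chrom = chrom[:, None] != chrom[None, :]
    r[far | diff_chrom] = 0.0
    np.fill_diagonal(r, 1.0)
    return LdPanel(variants, r, window_bp)


def ld_clump(stats: pd.DataFrame, ld: LdPanel, cfg: ClumpConfig = ClumpConfig()) -> list:
    """Greedy LD clumping of summary statistics; returns index-variant IDs.

    Candidates: p < p_entry, MAF > maf_min (from the panel's variant table
    when available, else the stats' EAF), and present in the LD panel.
    Greedy by ascending p (ties by chrom, pos); each selected index variant
    removes neighbors with r^2 > threshold within the window.
    """
    df = stats.loc[stats["P"] < cfg.p_entry].copy()
    panel_ids = set(ld._index)
    df = df[df["ID"].isin(panel_ids)]
    if "MAF" in ld.variants.columns:
        maf = ld.variants.set_index("ID")["MAF"]
        df["_MAF"] = df["ID"].map(maf)
    elif "EAF" in df.columns:
        df["_MAF"] = np.minimum(df["EAF"], 1.0 - df["EAF"])
    else:
        df["_MAF"] = np.inf
    df = df[df["_MAF"] > cfg.maf_min]
    if df.empty:
        logger.warning("no variants pass the MAF/p-entry filters; empty clump result")
        return []
    df = df.sort_values(["P", "CHROM", "POS"], kind="mergesort")
    removed: set = set()
    kept: list = []
    ids = ld.variants["ID"].to_numpy()
    for row in df.itertuples(index=False):
        if row.ID in removed:
            continue
        kept.append(row.ID)
        r2 = ld.r2_row(row.ID)
        for j in np.flatnonzero(r2 > cfg.r2_threshold):
            if ids[j] != row.ID:
                removed.add(ids[j])
    return kept


def threshold_subsets(
    clumped: list,
    stats: pd.DataFrame,
    cfg: ClumpConfig = ClumpConfig(),
    trait_label: str = "",
) -> dict:
    """Nested PRS models: one per threshold, weights = summary-stat log-OR."""
    sub = stats.set_index("ID").loc[clumped]
    models = {}
    for t in sorted(cfg.thresholds):
        rows = sub[sub["P"] < t].reset_index()
        entries = pd.DataFrame(
            {
                "ID": rows["ID"],
                "CHROM": rows["CHROM"].astype(str),
                "POS": rows["POS"].astype(int),
                "EFFECT_ALLELE": rows["EFFECT_ALLELE"],
                "OTHER_ALLELE": rows.get("OTHER_ALLELE"),
                "WEIGHT": rows["BETA"].astype(float),
                "P": rows["P"].astype(float),
            }
        )
        models[t] = PrsModel(entries=entries, method_tag=f"clump_threshold@{t:g}", trait_label=trait_label)
    return models


def clump_report(kept: list, stats: pd.DataFrame, ld: LdPanel, cfg: ClumpConfig = ClumpConfig()) -> pd.DataFrame:
    """Per index variant: how many neighbors were removed and the strongest removed r^2."""
    ids = ld.variants["ID"].to_numpy()
    kept_set = set(kept)
    rows = []
    for vid in kept:
        r2 = ld.r2_row(vid)
        mask = (r2 > cfg.r2_threshold) & (ids != vid)
        removed = [i for i in np.flatnonzero(mask) if ids[i] not in kept_set]
        best = float(r2[removed].max()) if removed else 0.0
        rows.append((vid, len(removed), best))
    return pd.DataFrame(rows, columns=["ID", "N_REMOVED", "BEST_REMOVED_R2"])
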