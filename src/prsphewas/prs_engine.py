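"""Polygenic risk scoring, standardization, locus merging and the
shared/unique decomposition across disease subtypes.

A PRS is the weighted sum of effect-allele dosages, PRS_j = sum_i beta_i G_ij.
Scores are transformed to the standard normal scale per analytical set.
Risk SNPs within 1 Mb (single-linkage chaining on the same chromosome) are
merged into loci; loci present in all subtype models define the shared
(unweighted) PRS, loci private to one model define that subtype's unique PRS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import DosageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PrsModel",
    "Locus",
    "ScoreVector",
    "compute_prs",
    "ztransform",
    "merge_loci",
    "decompose_shared_unique",
]

_ENTRY_COLUMNS = ["ID", "CHROM", "POS", "EFFECT_ALLELE", "OTHER_ALLELE", "WEIGHT", "P"]


@dataclass
class PrsModel:
    """A list of (variant, effect allele, weight) with a construction tag.

    ``entries`` columns: ID, CHROM, POS, EFFECT_ALLELE, WEIGHT and optionally
    OTHER_ALLELE and P (used to pick shared-locus representatives).
    """

    entries: pd.DataFrame
    method_tag: str = "external"
    trait_label: str = ""

    def __post_init__(self) -> None:
        df = self.entries.copy()
        for col in _ENTRY_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("OTHER_ALLELE", "P") else None
        df = df[_ENTRY_COLUMNS]
        if df["ID"].duplicated().any():
            dup = df.loc[df["ID"].duplicated(), "ID"].iloc[0]
            raise ValueError(f"duplicate variant in PRS model: {dup}")
        if len(df) and not np.isfinite(df["WEIGHT"].astype(float)).all():
            raise ValueError("non-finite weight in PRS model")
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def variant_ids(self) -> list:
        return list(self.entries["ID"])


@dataclass
class Locus:
    """A merged genomic locus: member SNPs connected by <= window gaps."""

    chrom: str
    start: int
    end: int
    members: list
    name: str | None = None

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class ScoreVector:
    """Per-subject raw (and optionally standardized) PRS with model coverage."""

    raw: pd.Series  # index SUBJECT_ID
    coverage: float = 1.0
    z: pd.Series | None = None


def compute_prs(dosages: DosageMatrix, model: PrsModel, on_missing: str = "skip") -> ScoreVector:
    """Score subjects: PRS_j = sum_i beta_i * dosage of the model's effect allele.

    When the matrix counts the other allele the dosage is flipped (2 - d).
    Model variants absent from the matrix are skipped (``on_missing='skip'``,
    coverage reports the scored fraction of total |weight| mass) or raise
    (``on_missing='raise'``). An effect allele matching neither matrix allele
    is always a hard error naming the variant.
    """
    vtab = dosages.variants.set_index("ID")
    total_mass = float(np.abs(model.entries["WEIGHT"]).sum())
    scored_mass = 0.0
    score = np.zeros(dosages.n_subjects)
    for row in model.entries.itertuples(index=False):
        if row.ID not in vtab.index:
            if on_missing == "raise":
                raise KeyError(f"model variant {row.ID} missing from dosage matrix")
            logger.info("model variant %s missing from matrix; skipped", row.ID)
            continue
        a1, a2 = vtab.at[row.ID, "A1"], vtab.at[row.ID, "A2"]
        d = dosages.column(row.ID)
        if row.EFFECT_ALLELE == a1:
            g = d
        elif row.EFFECT_ALLELE == a2:
            g = 2.0 - d
        else:
            raise ValueError(
                f"variant {row.ID}: effect allele {row.EFFECT_ALLELE} matches neither "
                f"matrix allele ({a1}/{a2})"
            )
        score += float(row.WEIGHT) * g
        scored_mass += abs(float(row.WEIGHT))
    coverage = scored_mass / total_mass if total_mass > 0 else 1.0
    return ScoreVector(raw=pd.Series(score, index=dosages.subject_ids), coverage=coverage)


def ztransform(score, subject_ids=None):
    """Standardize to mean 0, SD 1 (sample SD, n-1) over the analytical set.

    ``score`` may be a ScoreVector or a raw pd.Series; with ``subject_ids``
    the transform is computed (and returned) on that subset only, matching
    the per-study standardization of the analysis.
    """
    raw = score.raw if isinstance(score, ScoreVector) else score
    if subject_ids is not None:
        raw = raw.loc[pd.Index(subject_ids)]
    if len(raw) < 2:
        raise ValueError("ztransform needs at least 2 subjects")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("ztransform: zero variance score")
    z = (raw - raw.mean()) / sd
    if isinstance(score, ScoreVector):
        return ScoreVector(raw=raw, coverage=score.coverage, z=z)
    return z


def merge_loci(models: list, window_bp: int = 1_000_000):
    """Single-linkage merge of all models' SNPs into loci (1 Mb chaining).

    Returns ``(loci, overlap)``: the loci over the union of model SNPs, and a
    boolean DataFrame (locus key x model position) flagging which models have
    a member SNP in each locus.
    """
    frames = []
    for mi, m in enumerate(models):
        f = m.entries[["ID", "CHROM", "POS"]].copy()
        f["MODEL"] = mi
        frames.append(f)
    union = pd.concat(frames, ignore_index=True)
    dedup = union.drop_duplicates("ID").sort_values(["CHROM", "POS"], kind="mergesort")
    loci: list[Locus] = []
    for chrom, grp in dedup.groupby("CHROM", sort=True):
        pos = grp["POS"].to_numpy()
        ids = grp["ID"].to_numpy()
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or pos[i] - pos[i - 1] > window_bp:
                loci.append(
                    Locus(chrom=str(chrom), start=int(pos[start]), end=int(pos[i - 1]),
                          members=list(ids[start:i]))
                )
                start = i
    member_locus = {vid: li for li, loc in enumerate(loci) for vid in loc.members}
    overlap = pd.DataFrame(
        False, index=pd.RangeIndex(len(loci), name="LOCUS"), columns=range(len(models))
    )
    for mi, m in enumerate(models):
        for vid in m.variant_ids:
            overlap.loc[member_locus[vid], mi] = True
    return loci, overlap


def decompose_shared_unique(models: list, window_bp: int = 1_000_000):
    """Split exactly three subtype models into one shared and three unique PRS.

    Shared: one representative SNP per locus present in all three models,
    all weights set to 1 (unweighted count of risk alleles); the
    representative is the member with the smallest p-value across the source
    models (ties by chrom, pos). Unique (per subtype): that subtype's SNPs in
    loci found in no other model, original weights retained.
    """
    if len(models) != 3:
        raise ValueError("decompose_shared_unique expects exactly 3 subtype models")
    loci, overlap = merge_loci(models, window_bp)
    entry_lookup = pd.concat([m.entries for m in models], ignore_index=True)
    entry_lookup["P"] = entry_lookup["P"].astype(float).fillna(np.inf)
    best = (
        entry_lookup.sort_values(["P", "CHROM", "POS"], kind="mergesort")
        .drop_duplicates("ID")
        .set_index("ID")
    )

    shared_rows = []
    for li, loc in enumerate(loci):
        if overlap.loc[li].all():
            members = best.loc[[m for m in loc.members if m in best.index]]
            rep = members.sort_values(["P", "CHROM", "POS"], kind="mergesort").iloc[0]
            effect, other = rep["EFFECT_ALLELE"], rep["OTHER_ALLELE"]
            # the unweighted score counts risk-increasing alleles
            if float(rep["WEIGHT"]) < 0 and isinstance(other, str):
                effect, other = other, effect
            elif float(rep["WEIGHT"]) < 0:
                logger.warning("cannot orient risk allele of %s (no other allele)", rep.name)
            shared_rows.append(
                (rep.name, rep["CHROM"], rep["POS"], effect, other, 1.0, rep["P"])
            )
    if not shared_rows:
        logger.warning("no loci shared by all three models; shared PRS is empty")
    shared = PrsModel(
        entries=pd.DataFrame(shared_rows, columns=_ENTRY_COLUMNS),
        method_tag="shared",
        trait_label="+".join(m.trait_label for m in models),
    )

    labels = [m.trait_label or str(i) for i, m in enumerate(models)]
    if len(set(labels)) < len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    unique: dict = {}
    for mi, m in enumerate(models):
        private_loci = {
            li for li in overlap.index
            if overlap.loc[li, mi] and not overlap.loc[li].drop(mi).any()
        }
        private_members = {
            vid for li in private_loci for vid in loci[li].members
        }
        keep = m.entries[m.entries["ID"].isin(private_members)]
        unique[labels[mi]] = PrsModel(
            entries=keep.reset_index(drop=True),
            method_tag="unique",
            trait_label=m.trait_label,
        )
    return shared, unique
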