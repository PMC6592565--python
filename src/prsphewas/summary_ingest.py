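"""Harmonization and QC of external GWAS association sources.

Catalog-style entries (risk allele, RAF, OR, p, publication date) and full
summary statistics are aligned to the forward-strand alleles of the target
genotype panel, cleaned by the standard QC rules, and reduced to
LD-independent risk-variant lists:

* entries with missing risk allele / RAF / OR are excluded;
* a risk allele matching neither forward-strand allele of a *non-ambiguous*
  panel variant is assumed to carry minus-strand designation and is corrected
  to its complementary base; at a strand-ambiguous variant (A/T or C/G) such
  an entry is unrecoverable and excluded;
* entries whose reported RAF deviates from the control-cohort frequency of
  the (harmonized) effect allele by more than 0.15 are excluded
  (for chromosome-X variants the control RAF is computed in females only);
* correlated entries (r^2 > 0.1) and duplicate IDs are deduplicated keeping
  the most recent publication date, ties broken by smaller p-value.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParseError
from .synthetic_data import COMPLEMENT, DosageMatrix, is_ambiguous

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogEntry",
    "HarmonizedVariant",
    "harmonize_alleles",
    "filter_raf",
    "dedup_ld",
    "select_latest_gwas",
    "read_catalog",
    "build_catalog_model",
]

_X_CHROMS = {"X", "23", "chrX"}
_BASES = set("ACGT")


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog-style reported association."""

    variant_id: str
    chrom: str
    pos: int
    risk_allele: str | None
    raf: float | None
    odds_ratio: float | None
    p_value: float
    pub_date: datetime.date
    ancestry_label: str = "European"
    trait: str = ""
    beta: float | None = None  # effect reported on the log scale instead of OR

    def weight(self) -> float | None:
        if self.beta is not None:
            return float(self.beta)
        if self.odds_ratio is None:
            return None
        return float(np.log(self.odds_ratio))


@dataclass(frozen=True)
class HarmonizedVariant:
    """Catalog entry aligned to the panel's forward-strand alleles."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str | None
    weight: float | None
    p_value: float
    pub_date: datetime.date
    raf: float | None = None
    exclusion_reason: str | None = None  # missing_fields | ambiguous_mismatch |
    # no_allele_match | raf_deviation | non_european | not_in_panel

    @property
    def kept(self) -> bool:
        return self.exclusion_reason is None


def _excluded(entry: CatalogEntry, reason: str) -> HarmonizedVariant:
    return HarmonizedVariant(
        variant_id=entry.variant_id,
        chrom=entry.chrom,
        pos=entry.pos,
        effect_allele=None,
        weight=entry.weight(),
        p_value=entry.p_value,
        pub_date=entry.pub_date,
        raf=entry.raf,
        exclusion_reason=reason,
    )


def harmonize_alleles(entry: CatalogEntry, variant) -> HarmonizedVariant:
    """Match an entry's risk allele to a panel variant's forward-strand alleles.

    ``variant`` is a row of the panel variant table (needs A1 and A2).
    Non-ambiguous variants with a complement match get the minus-strand
    correction; ambiguous variants without a direct match are excluded.
    """
    a1, a2 = str(variant["A1"]), str(variant["A2"])
    if a1 not in _BASES or a2 not in _BASES:
        raise ParseError(f"panel variant {entry.variant_id}: malformed alleles {a1}/{a2}")
    if "European" not in (entry.ancestry_label or ""):
        return _excluded(entry, "non_european")
    if entry.risk_allele is None or entry.raf is None or entry.weight() is None:
        return _excluded(entry, "missing_fields")
    risk = str(entry.risk_allele)
    if risk not in _BASES:
        raise ParseError(f"entry {entry.variant_id}: malformed risk allele {risk!r}")
    if risk in (a1, a2):
        effect = risk
    elif is_ambiguous(a1, a2):
        return _excluded(entry, "ambiguous_mismatch")
    elif COMPLEMENT[risk] in (a1, a2):
        effect = COMPLEMENT[risk]  # minus-strand designation assumed
    else:
        return _excluded(entry, "no_allele_match")
    return HarmonizedVariant(
        variant_id=entry.variant_id,
        chrom=entry.chrom,
        pos=entry.pos,
        effect_allele=effect,
        weight=entry.weight(),
        p_value=entry.p_value,
        pub_date=entry.pub_date,
        raf=entry.raf,
    )


def control_raf(
    dosages: DosageMatrix,
    variant_id: str,
    effect_allele: str,
    control_ids,
    female_ids=None,
) -> float:
    """Control-cohort frequency of the harmonized effect allele.

    For chromosome-X variants the frequency is computed on female controls
    only (pass ``female_ids``); autosomal calls ignore ``female_ids``.
    """
    row = dosages.variants.loc[dosages.variants["ID"] == variant_id]
    if row.empty:
        raise KeyError(f"variant {variant_id} not in panel")
    row = row.iloc[0]
    ids = control_ids
    if str(row["CHROM"]) in _X_CHROMS and female_ids is not None:
        ids = pd.Index(control_ids).intersection(pd.Index(female_ids))
    freq = dosages.allele_frequency(variant_id, ids)
    if effect_allele == row["A1"]:
        return freq
    if effect_allele == row["A2"]:
        return 1.0 - freq
    raise KeyError(f"effect allele {effect_allele} matches neither panel allele of {variant_id}")


def filter_raf(entry: HarmonizedVariant, ctrl_raf: float | None, threshold: float = 0.15):
    """Keep/drop by reported-vs-control risk allele frequency deviation.

    Returns ``(keep, reason)``; drop iff |reported - control| > threshold.
    """
    if ctrl_raf is None or not np.isfinite(ctrl_raf):
        logger.warning("control RAF unavailable for %s; dropping", entry.variant_id)
        return False, "raf_unavailable"
    if entry.raf is None:
        return False, "missing_fields"
    if abs(float(entry.raf) - float(ctrl_raf)) > threshold:
        return False, "raf_deviation"
    return True, None


def _priority(entry: HarmonizedVariant):
    # more recent pub_date first, then smaller p, then genomic coordinate
    return (-entry.pub_date.toordinal(), entry.p_value, str(entry.chrom), entry.pos)


def dedup_ld(entries: list, ld, r2_threshold: float = 0.1) -> list:
    """Deduplicate correlated entries (r^2 > threshold) and duplicate IDs.

    Among a correlated pair (or entries sharing a variant ID) the entry with
    the most recent publication date wins; ties go to the smaller p-value.
    ``ld`` is an :class:`~prsphewas.clump_threshold.LdPanel` (or None when no
    pairwise LD is available, in which case only duplicate IDs are removed).
    Output is sorted by genomic coordinate.
    """
    kept: list = []
    for e in sorted(entries, key=_priority):
        clash = False
        for k in kept:
            if e.variant_id == k.variant_id:
                clash = True
                break
            if ld is not None and ld.r2(e.variant_id, k.variant_id) > r2_threshold:
                clash = True
                break
        if not clash:
            kept.append(e)
    return sorted(kept, key=lambda e: (str(e.chrom), e.pos, e.variant_id))


def harmonize_stats_row(row, variant) -> tuple[str | None, float, str | None]:
    """Align one summary-statistic row to the panel; returns
    (effect_allele_on_panel, signed_beta, exclusion_reason)."""
    a1, a2 = str(variant["A1"]), str(variant["A2"])
    ea, oa = str(row["EFFECT_ALLELE"]), str(row["OTHER_ALLELE"])
    beta = float(row["BETA"])
    if {ea, oa} == {a1, a2}:
        return ea, beta, None
    if is_ambiguous(a1, a2):
        return None, beta, "ambiguous_mismatch"
    if {COMPLEMENT[ea], COMPLEMENT[oa]} == {a1, a2}:
        return COMPLEMENT[ea], beta, None  # strand flip repaired
    return None, beta, "no_allele_match"


def harmonize_stats_table(stats: pd.DataFrame, dosages: DosageMatrix) -> pd.DataFrame:
    """Align a full summary-statistic table to the panel's forward strand.

    Rows absent from the panel or with unresolvable alleles (ambiguous
    mismatch) are dropped; strand-flipped rows have both alleles complemented.
    Run this before clumping/scoring so downstream weights carry panel alleles.
    """
    vtab = dosages.variants.set_index("ID")
    keep, eas, oas = [], [], []
    for row in stats.itertuples(index=False):
        if row.ID not in vtab.index:
            keep.append(False); eas.append(row.EFFECT_ALLELE); oas.append(row.OTHER_ALLELE)
            continue
        effect, _, reason = harmonize_stats_row(row._asdict(), vtab.loc[row.ID])
        if reason is not None:
            keep.append(False); eas.append(row.EFFECT_ALLELE); oas.append(row.OTHER_ALLELE)
            continue
        other = vtab.at[row.ID, "A2"] if effect == vtab.at[row.ID, "A1"] else vtab.at[row.ID, "A1"]
        keep.append(True); eas.append(effect); oas.append(other)
    out = stats.assign(EFFECT_ALLELE=eas, OTHER_ALLELE=oas).loc[keep]
    n_dropped = len(stats) - len(out)
    if n_dropped:
        logger.info("harmonize_stats_table: dropped %d unresolvable row(s)", n_dropped)
    return out.reset_index(drop=True)


def select_latest_gwas(
    stats: pd.DataFrame,
    dosages: DosageMatrix,
    ld=None,
    p_cut: float = 5e-8,
    r2_threshold: float = 0.1,
) -> list:
    """Genome-wide significant rows (strict p < p_cut) harmonized against the
    panel and LD-deduplicated; returns kept :class:`HarmonizedVariant` list."""
    hits = stats.loc[stats["P"] < p_cut]
    if hits.empty:
        logger.warning("no rows pass p < %g; downstream model will be empty", p_cut)
        return []
    vtab = dosages.variants.set_index("ID")
    harmonized = []
    for row in hits.itertuples(index=False):
        rid = row.ID
        if rid not in vtab.index:
            continue
        variant = vtab.loc[rid]
        effect, beta, reason = harmonize_stats_row(row._asdict(), variant)
        if reason is not None:
            continue
        sign = 1.0 if effect == str(row.EFFECT_ALLELE) else 1.0  # sign unchanged by strand flip
        harmonized.append(
            HarmonizedVariant(
                variant_id=rid,
                chrom=str(row.CHROM),
                pos=int(row.POS),
                effect_allele=effect,
                weight=sign * beta,
                p_value=float(row.P),
                pub_date=datetime.date(1970, 1, 1),  # single source: dedup falls back to p
                raf=float(row.EAF) if "EAF" in hits.columns else None,
            )
        )
    return dedup_ld(harmonized, ld, r2_threshold)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def read_catalog(path) -> list:
    """Read a catalog-style TSV into CatalogEntry objects.

    Expected columns: ID, CHROM, POS, RISK_ALLELE, RAF, OR (or BETA), P,
    PUB_DATE (ISO), ANCESTRY, TRAIT. Missing RAF/OR/risk alleles are kept as
    None so the harmonizer can assign exclusion reasons.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    entries = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key):
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return v

        entries.append(
            CatalogEntry(
                variant_id=str(d["ID"]),
                chrom=str(d["CHROM"]),
                pos=int(d["POS"]),
                risk_allele=opt("RISK_ALLELE"),
                raf=opt("RAF"),
                odds_ratio=opt("OR"),
                p_value=float(d["P"]),
                pub_date=datetime.date.fromisoformat(str(d["PUB_DATE"])),
                ancestry_label=str(d.get("ANCESTRY", "European")),
                trait=str(d.get("TRAIT", "")),
                beta=opt("BETA"),
            )
        )
    return entries


def build_catalog_model(
    entries: list,
    dosages: DosageMatrix,
    control_ids,
    ld=None,
    raf_threshold: float = 0.15,
    r2_threshold: float = 0.1,
    female_ids=None,
):
    """Full catalog pipeline: harmonize -> RAF filter -> LD dedup.

    Returns ``(kept_variants, audit)`` where ``audit`` is one row per input
    entry with its fate (kept / exclusion reason).
    """
    vtab = dosages.variants.set_index("ID")
    processed: list[HarmonizedVariant] = []
    for entry in entries:
        if entry.variant_id not in vtab.index:
            processed.append(_excluded(entry, "not_in_panel"))
            continue
        h = harmonize_alleles(entry, vtab.loc[entry.variant_id])
        if h.kept:
            ctrl = control_raf(dosages, h.variant_id, h.effect_allele, control_ids, female_ids)
            keep, reason = filter_raf(h, ctrl, raf_threshold)
            if not keep:
                h = replace(h, exclusion_reason=reason)
        processed.append(h)

    survivors = [h for h in processed if h.kept]
    kept = dedup_ld(survivors, ld, r2_threshold)
    kept_ids = {id(k) for k in kept}
    audit_rows = []
    for h in processed:
        reason = h.exclusion_reason
        if reason is None and id(h) not in kept_ids:
            reason = "ld_duplicate"
        audit_rows.append(
            (h.variant_id, h.chrom, h.pos, h.effect_allele, h.weight, h.p_value,
             str(h.pub_date), reason is None, reason or "")
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=["ID", "CHROM", "POS", "EFFECT_ALLELE", "WEIGHT", "P", "PUB_DATE", "KEPT", "REASON"],
    )
    return kept, audit
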