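"""Harmonization and QC rules: strand correction, ambiguous exclusion,
RAF deviation filter, and recency-based LD deduplication."""

import datetime
import itertools

import numpy as np
import pandas as pd
import pytest

import prsphewas as pp
from prsphewas.errors import ParseError
from prsphewas.summary_ingest import (
    CatalogEntry,
    HarmonizedVariant,
    build_catalog_model,
    control_raf,
    dedup_ld,
    harmonize_alleles,
    filter_raf,
    select_latest_gwas,
)
from prsphewas.synthetic_data import COMPLEMENT


def entry(risk="A", raf=0.3, odds=1.2, p=1e-9, date="2018-01-01", anc="European", vid="rs1"):
    return CatalogEntry(
        variant_id=vid, chrom="1", pos=100, risk_allele=risk, raf=raf,
        odds_ratio=odds, p_value=p, pub_date=datetime.date.fromisoformat(date),
        ancestry_label=anc,
    )


def panel_row(a1, a2):
    return pd.Series({"A1": a1, "A2": a2})


class TestHarmonizeAlleles:
    @pytest.mark.parametrize(
        "risk,a1,a2,expect_effect,expect_reason",
        [
            ("A", "A", "G", "A", None),           # direct match
            ("A", "C", "T", "T", None),           # minus-strand correction
            ("C", "A", "T", None, "ambiguous_mismatch"),
            ("G", "A", "C", "C", None),           # complement of G matches C
            ("T", "A", "T", "T", None),           # ambiguous but direct match kept
        ],
    )
    def test_matching_rules(self, risk, a1, a2, expect_effect, expect_reason):
        h = harmonize_alleles(entry(risk=risk), panel_row(a1, a2))
        assert h.effect_allele == expect_effect
        assert h.exclusion_reason == expect_reason

    def test_missing_fields_excluded(self):
        for kwargs in ({"risk": None}, {"raf": None}, {"odds": None}):
            h = harmonize_alleles(entry(**kwargs), panel_row("A", "G"))
            assert h.exclusion_reason == "missing_fields"

    def test_beta_flag_substitutes_for_or(self):
        e = CatalogEntry(variant_id="rs1", chrom="1", pos=1, risk_allele="A",
                         raf=0.2, odds_ratio=None, p_value=1e-5,
                         pub_date=datetime.date(2018, 1, 1), beta=0.33)
        h = harmonize_alleles(e, panel_row("A", "G"))
        assert h.kept and h.weight == pytest.approx(0.33)

    def test_non_european_excluded(self):
        h = harmonize_alleles(entry(anc="East Asian"), panel_row("A", "G"))
        assert h.exclusion_reason == "non_european"

    def test_malformed_bases_raise(self):
        with pytest.raises(ParseError):
            harmonize_alleles(entry(risk="N"), panel_row("A", "G"))
        with pytest.raises(ParseError):
            harmonize_alleles(entry(), panel_row("A", "AT"))

    def test_strand_flip_round_trip_preserves_direction(self):
        # flipping the reported risk allele to the minus strand must recover
        # the same effect allele for every non-ambiguous panel pair
        pairs = [p for p in itertools.permutations("ACGT", 2)
                 if frozenset(p) not in ({"A", "T"}, {"C", "G"})]
        for a1, a2 in pairs:
            direct = harmonize_alleles(entry(risk=a1), panel_row(a1, a2))
            flipped = harmonize_alleles(entry(risk=COMPLEMENT[a1]), panel_row(a1, a2))
            assert direct.kept and flipped.kept
            assert direct.effect_allele == flipped.effect_allele


class TestRafFilter:
    @pytest.mark.parametrize(
        "reported,ctrl,keep",
        [(0.30, 0.50, False), (0.50, 0.50, True), (0.64, 0.50, True), (0.66, 0.50, False)],
    )
    def test_deviation_rule(self, reported, ctrl, keep):
        h = harmonize_alleles(entry(raf=reported), panel_row("A", "G"))
        got, reason = filter_raf(h, ctrl)
        assert got is keep
        if not keep:
            assert reason == "raf_deviation"

    def test_unavailable_control_raf_drops_with_reason(self):
        h = harmonize_alleles(entry(), panel_row("A", "G"))
        keep, reason = filter_raf(h, None)
        assert not keep and reason == "raf_unavailable"

    def test_control_raf_flips_for_other_allele(self, cohort):
        dm = cohort["dosages"]
        vid = dm.variants["ID"].iloc[0]
        a1, a2 = dm.variants.loc[0, "A1"], dm.variants.loc[0, "A2"]
        ids = dm.subject_ids
        f1 = control_raf(dm, vid, a1, ids)
        f2 = control_raf(dm, vid, a2, ids)
        assert f1 + f2 == pytest.approx(1.0)


class _FakeLd:
    """Minimal LD lookup for dedup tests."""

    def __init__(self, pairs):
        self.pairs = {frozenset(k): v for k, v in pairs.items()}

    def r2(self, a, b):
        return self.pairs.get(frozenset((a, b)), 0.0)


def hv(vid, pos, p=1e-8, date="2017-01-01"):
    return HarmonizedVariant(
        variant_id=vid, chrom="1", pos=pos, effect_allele="A", weight=0.1,
        p_value=p, pub_date=datetime.date.fromisoformat(date),
    )


class TestDedupLd:
    def test_most_recent_wins(self):
        ld = _FakeLd({("a", "b"): 0.2})
        kept = dedup_ld([hv("a", 1, date="2016-05-01"), hv("b", 2, date="2018-05-01")], ld)
        assert [k.variant_id for k in kept] == ["b"]

    def test_smaller_p_breaks_date_tie(self):
        ld = _FakeLd({("a", "b"): 0.2})
        kept = dedup_ld([hv("a", 1, p=1e-8), hv("b", 2, p=1e-9)], ld)
        assert [k.variant_id for k in kept] == ["b"]

    def test_uncorrelated_pair_both_kept_in_coordinate_order(self):
        ld = _FakeLd({("a", "b"): 0.05})
        kept = dedup_ld([hv("b", 500), hv("a", 10)], ld)
        assert [k.variant_id for k in kept] == ["a", "b"]

    def test_duplicate_ids_deduplicated(self):
        kept = dedup_ld([hv("a", 1, date="2016-01-01"), hv("a", 1, date="2019-01-01")], None)
        assert len(kept) == 1 and kept[0].pub_date.year == 2019

    def test_randomized_instances_satisfy_keep_rule(self):
        # property oracle: output independent, maximal, and every exclusion is
        # justified by a kept entry of higher (date, p) priority
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 20))
            entries = [
                hv(f"v{i}", pos=i * 10, p=float(rng.uniform(1e-12, 1e-4)),
                   date=f"{int(rng.integers(2010, 2020))}-01-01")
                for i in range(n)
            ]
            pairs = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        pairs[(f"v{i}", f"v{j}")] = float(rng.uniform(0.11, 1.0))
            ld = _FakeLd(pairs)
            kept = dedup_ld(entries, ld, 0.1)
            kept_ids = {k.variant_id for k in kept}
            for a in kept:
                for b in kept:
                    if a.variant_id < b.variant_id:
                        assert ld.r2(a.variant_id, b.variant_id) <= 0.1
            prio = lambda e: (-e.pub_date.toordinal(), e.p_value, e.pos)
            for e in entries:
                if e.variant_id in kept_ids:
                    continue
                blockers = [k for k in kept if ld.r2(e.variant_id, k.variant_id) > 0.1]
                assert blockers, "excluded entry with no kept conflict (not maximal)"
                assert any(prio(k) <= prio(e) for k in blockers)


class TestSelectLatestGwas:
    def test_strict_threshold_and_empty(self, cohort):
        dm = cohort["dosages"]
        stats = pd.DataFrame(
            {
                "ID": dm.variants["ID"].head(3),
                "CHROM": "1",
                "POS": dm.variants["POS"].head(3),
                "EFFECT_ALLELE": dm.variants["A1"].head(3),
                "OTHER_ALLELE": dm.variants["A2"].head(3),
                "BETA": 0.2,
                "SE": 0.02,
                "P": [5e-8, 0.5, 0.5],
                "EAF": 0.3,
                "N": 10000,
            }
        )
        assert select_latest_gwas(stats, dm) == []  # 5e-8 exactly is excluded
        stats.loc[0, "P"] = 4.9e-8
        kept = select_latest_gwas(stats, dm)
        assert [k.variant_id for k in kept] == [stats.loc[0, "ID"]]

    def test_synthetic_causal_variant_included(self, cohort):
        cfg, arch = cohort["cfg"], cohort["arch"]
        stats = pp.simulate_discovery_gwas(arch, cfg)
        kept = select_latest_gwas(stats, cohort["dosages"])
        top_causal = (
            stats[stats["ID"].isin(arch.effects.index)].sort_values("P").iloc[0]
        )
        if top_causal["P"] < 5e-8:
            assert top_causal["ID"] in {k.variant_id for k in kept}


class TestHarmonizeStatsTable:
    def test_flips_repaired_and_ambiguous_dropped(self, cohort):
        cfg, arch, dm = cohort["cfg"], cohort["arch"], cohort["dosages"]
        stats, inj = pp.simulate_discovery_gwas(arch, cfg, return_injections=True)
        out = pp.harmonize_stats_table(stats, dm)
        inj = inj.set_index("ID")["KIND"]
        vt = dm.variants.set_index("ID")
        out_idx = out.set_index("ID")
        flips = inj[inj == "strand_flip"].index
        assert (out_idx.loc[flips, "EFFECT_ALLELE"] == vt.loc[flips, "A1"]).all()
        ambig = inj[inj == "ambiguous"].index
        assert not set(ambig) & set(out["ID"])
        # every surviving row's alleles match the panel exactly
        assert all(
            {r.EFFECT_ALLELE, r.OTHER_ALLELE} == {vt.at[r.ID, "A1"], vt.at[r.ID, "A2"]}
            for r in out.itertuples(index=False)
        )


class TestCatalogPipelineAudit:
    def test_audit_reconciles_and_reasons_unique(self, cohort):
        cfg, arch, dm = cohort["cfg"], cohort["arch"], cohort["dosages"]
        stats, inj = pp.simulate_discovery_gwas(arch, cfg, return_injections=True)
        entries = [
            CatalogEntry(
                variant_id=r.ID, chrom=str(r.CHROM), pos=int(r.POS),
                risk_allele=r.EFFECT_ALLELE, raf=float(r.EAF),
                odds_ratio=float(np.exp(r.BETA)), p_value=float(r.P),
                pub_date=datetime.date(2018, 1, 1),
            )
            for r in stats.head(200).itertuples(index=False)
        ]
        kept, audit = build_catalog_model(entries, dm, dm.subject_ids)
        assert len(audit) == len(entries)
        assert (audit.loc[~audit["KEPT"], "REASON"] != "").all()
        assert (audit.loc[audit["KEPT"], "REASON"] == "").all()
        assert audit["KEPT"].sum() == len(kept)

    def test_qc_round_trip_on_injected_defects(self, cohort):
        cfg, arch, dm = cohort["cfg"], cohort["arch"], cohort["dosages"]
        stats, inj = pp.simulate_discovery_gwas(arch, cfg, return_injections=True)
        inj = inj.set_index("ID")["KIND"]
        vt = dm.variants.set_index("ID")
        entries = [
            CatalogEntry(
                variant_id=r.ID, chrom=str(r.CHROM), pos=int(r.POS),
                risk_allele=r.EFFECT_ALLELE, raf=float(r.EAF),
                odds_ratio=float(np.exp(r.BETA)), p_value=float(r.P),
                pub_date=datetime.date(2018, 1, 1),
            )
            for r in stats.itertuples(index=False)
        ]
        _, audit = build_catalog_model(entries, dm, dm.subject_ids)
        audit = audit.set_index("ID")
        flips = inj[inj == "strand_flip"].index
        # every strand flip repaired: harmonized effect allele is the panel allele
        assert (audit.loc[flips, "EFFECT_ALLELE"] == vt.loc[flips, "A1"]).all()
        assert (audit.loc[flips, "REASON"].isin(["", "ld_duplicate"])).all()
        ambig = inj[inj == "ambiguous"].index
        assert (audit.loc[ambig, "REASON"] == "ambiguous_mismatch").all()
        raf_err = inj[inj == "raf_error"].index
        assert (audit.loc[raf_err, "REASON"] == "raf_deviation").all()
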