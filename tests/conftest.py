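"""Shared fixtures: one mid-size synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import prsphewas as pp
from prsphewas.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def cohort():
    """A 2,000-subject cohort with block LD, three subtypes and a small phenome."""
    cfg = SimConfig(n_subjects=2000, n_variants=400, n_null_codes=20,
                    discovery_n=8000, seed=7)
    dosages, variants = pp.simulate_genotypes(cfg)
    arch = pp.simulate_architecture(cfg, variants)
    subjects, events, truth = pp.simulate_phenome(dosages, arch, cfg, return_truth=True)
    return {
        "cfg": cfg,
        "dosages": dosages,
        "variants": variants,
        "arch": arch,
        "subjects": subjects,
        "events": events,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def phenome_studies(cohort):
    defs = pp.read_phecode_map(pp.synthetic_phecode_map(cohort["cfg"]))
    incidence = pp.map_codes_to_phecodes(cohort["events"], defs)
    studies = pp.build_phenome_studies(incidence, cohort["subjects"], mode="unmatched")
    return {"definitions": defs, "incidence": incidence, "studies": studies}


def true_weight_model(cohort, subtype, variant_ids=None) -> pp.PrsModel:
    """PRS model from the true architecture effects for one subtype."""
    arch, variants = cohort["arch"], cohort["variants"]
    beta = arch.effects[subtype]
    beta = beta[beta != 0.0]
    if variant_ids is not None:
        beta = beta.loc[[v for v in beta.index if v in set(variant_ids)]]
    vt = variants.set_index("ID")
    entries = pd.DataFrame(
        {
            "ID": beta.index,
            "CHROM": vt.loc[beta.index, "CHROM"].astype(str).to_numpy(),
            "POS": vt.loc[beta.index, "POS"].to_numpy(),
            "EFFECT_ALLELE": vt.loc[beta.index, "A1"].to_numpy(),
            "OTHER_ALLELE": vt.loc[beta.index, "A2"].to_numpy(),
            "WEIGHT": beta.to_numpy(),
        }
    )
    return pp.PrsModel(entries=entries, method_tag="external", trait_label=subtype)
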