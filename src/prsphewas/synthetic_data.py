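"""Synthetic cohort generator: block-LD genotypes, subtype disease architectures,
discovery-cohort GWAS summary statistics, and a dated ICD-coded phenome.

The generator emulates the statistical structure a PRS-PheWAS analysis assumes:

* genotype dosages with block-wise linkage disequilibrium (LD), generated from a
  latent Gaussian copula thresholded to hard genotypes by Hardy-Weinberg
  frequencies; the latent equicorrelation of each block is numerically
  calibrated so the realized *dosage* correlation matches the requested value;
* three (or more) disease subtypes driven by shared and subtype-unique causal
  loci with normally distributed log-odds-ratio effects;
* secondary traits genetically correlated with the shared-locus score, plus
  independent null diagnosis codes;
* a discovery cohort GWAS (marginal per-variant logistic regression on an
  independent sample) with deliberately injected harmonization defects
  (strand flips, allele-frequency errors, ambiguous-allele mismatches) so that
  the QC pipeline can be exercised end to end.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigError, DegenerateSimulationError

__all__ = [
    "SimConfig",
    "DosageMatrix",
    "TrueArchitecture",
    "simulate_genotypes",
    "simulate_architecture",
    "simulate_phenome",
    "simulate_discovery_gwas",
    "synthetic_phecode_map",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

# independent substreams of the master seed
_S_PANEL, _S_GENO, _S_ARCH, _S_PHENOME, _S_GWAS_GENO, _S_GWAS_INJECT = range(6)

_DATE_WINDOW_START = pd.Timestamp("2008-01-01")
_DATE_WINDOW_DAYS = 3652  # 10 years


def is_ambiguous(a1: str, a2: str) -> bool:
    """Strand-ambiguous allele pair (A/T or C/G)?"""
    return frozenset((a1, a2)) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults define the reference study conditions: a mid-size biobank-style
    cohort with three skin-cancer-like subtypes sharing six risk loci
    (plus ten unique loci each), two genetically correlated secondary traits
    and one hundred null diagnosis codes.
    """

    n_subjects: int = 5000
    n_variants: int = 600
    block_size: int = 10
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_shared_causal: int = 6
    n_unique_causal_per_subtype: int = 10
    effect_sd: float = 0.3
    base_prevalence: dict = field(
        default_factory=lambda: {"melanoma": 0.05, "bcc": 0.08, "scc": 0.05}
    )
    n_secondary_traits: int = 2
    secondary_effect: float = 0.5  # log-OR per SD of the shared-locus score
    secondary_prevalence: float = 0.10
    n_null_codes: int = 100
    null_code_prev_range: tuple[float, float] = (0.03, 0.15)
    discovery_n: int = 20000
    qc_injection_rates: dict = field(
        default_factory=lambda: {"strand_flip": 0.05, "raf_error": 0.05, "ambiguous": 0.05}
    )
    pc_confounding: float = 0.0  # optional loading of PC1 on disease liability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_variants <= 0 or self.block_size <= 0:
            raise ConfigError("n_subjects, n_variants and block_size must be positive")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ConfigError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.effect_sd <= 0:
            raise ConfigError("effect_sd must be positive")
        for name, p in self.base_prevalence.items():
            if not (0.0 < p < 1.0):
                raise ConfigError(f"base prevalence for {name!r} must be in (0,1)")
        n_causal = self.n_shared_causal + len(self.base_prevalence) * self.n_unique_causal_per_subtype
        if n_causal > self.n_variants:
            raise ConfigError("more causal variants requested than variants available")
        if not (0.0 < self.secondary_prevalence < 1.0):
            raise ConfigError("secondary_prevalence must be in (0,1)")
        if self.n_null_codes > 400:
            raise ConfigError("at most 400 null codes supported (phecode namespace)")
        for key, rate in self.qc_injection_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"qc injection rate {key!r} must be in [0,1]")

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.base_prevalence)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class DosageMatrix:
    """Subjects x variants dosages of the counted (A1) allele, in [0, 2]."""

    dosages: np.ndarray
    subject_ids: pd.Index
    variants: pd.DataFrame  # columns: CHROM, POS, ID, A1, A2, MAF (+ generator extras)

    def __post_init__(self) -> None:
        self.subject_ids = pd.Index(self.subject_ids, name="SUBJECT_ID")
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ConfigError("dosage matrix shape does not match subject/variant tables")
        self._col = {v: i for i, v in enumerate(self.variants["ID"])}

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._col[variant_id]]

    def column_index(self, variant_id: str) -> int:
        return self._col[variant_id]

    def subset_subjects(self, subject_ids) -> "DosageMatrix":
        idx = self.subject_ids.get_indexer(pd.Index(subject_ids))
        if (idx < 0).any():
            raise KeyError("unknown subject ids in subset")
        return DosageMatrix(self.dosages[idx], pd.Index(subject_ids), self.variants)

    def allele_frequency(self, variant_id: str, subject_ids=None) -> float:
        """Frequency of the counted (A1) allele, optionally on a subject subset."""
        col = self.column(variant_id)
        if subject_ids is not None:
            idx = self.subject_ids.get_indexer(pd.Index(subject_ids))
            col = col[idx]
        return float(col.mean() / 2.0)

    # -- plain-text I/O ---------------------------------------------------
    def to_tsv(self, dosage_path, variant_path) -> None:
        df = pd.DataFrame(self.dosages, index=self.subject_ids, columns=self.variants["ID"])
        df.to_csv(dosage_path, sep="\t", float_format="%.6g")
        self.variants.to_csv(variant_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, variant_path) -> "DosageMatrix":
        df = pd.read_csv(dosage_path, sep="\t", index_col=0)
        variants = pd.read_csv(variant_path, sep="\t", dtype={"CHROM": str})
        return cls(df.to_numpy(dtype=float), df.index, variants)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF with a per-genotype DS (dosage) FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(map(str, self.subject_ids)) + "\n")
            for j, row in enumerate(self.variants.itertuples(index=False)):
                # ALT is the counted allele so DS equals the stored dosage
                vals = "\t".join(f"{d:.4g}" for d in self.dosages[:, j])
                fh.write(f"{row.CHROM}\t{row.POS}\t{row.ID}\t{row.A2}\t{row.A1}\t.\t.\t.\tDS\t{vals}\n")

    @classmethod
    def from_vcf(cls, path) -> "DosageMatrix":
        """Read dosages from a VCF carrying a DS FORMAT field (requires cyvcf2)."""
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        subjects = pd.Index(vcf.samples)
        rows, cols = [], []
        for var in vcf:
            ds = var.format("DS")
            cols.append(np.asarray(ds, dtype=float).ravel())
            rows.append((str(var.CHROM), var.POS, var.ID, var.ALT[0], var.REF))
        variants = pd.DataFrame(rows, columns=["CHROM", "POS", "ID", "A1", "A2"])
        dosages = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
        freq = dosages.mean(axis=0) / 2.0 if len(cols) else np.array([])
        variants["MAF"] = np.minimum(freq, 1 - freq)
        return cls(dosages, subjects, variants)


@dataclass
class TrueArchitecture:
    """True causal effects per subtype (log-OR scale), shared vs unique loci."""

    effects: pd.DataFrame  # index: variant ID (causal union), columns: subtypes
    shared_variant_ids: set
    unique_variant_ids: dict  # subtype -> set

    def __post_init__(self) -> None:
        nonzero = {s: set(self.effects.index[self.effects[s] != 0.0]) for s in self.effects}
        if len(nonzero) >= 2:  # "shared" is only meaningful across subtypes
            inter = set.intersection(*nonzero.values())
            if inter != self.shared_variant_ids:
                raise ConfigError("shared set must equal the intersection of nonzero-effect sets")
        all_unique = [self.unique_variant_ids[s] for s in sorted(self.unique_variant_ids)]
        seen: set = set()
        for u in all_unique:
            if u & seen or u & self.shared_variant_ids:
                raise ConfigError("unique sets must be pairwise disjoint and disjoint from shared")
            seen |= u

    def causal_ids(self, subtype: str) -> list:
        col = self.effects[subtype]
        return list(col.index[col != 0.0])


# ---------------------------------------------------------------------------
# bivariate normal helpers (latent-copula calibration)
# ---------------------------------------------------------------------------

def _bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(rho)
    if abs(rho) < 1e-12:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    denom = np.sqrt(1.0 - rho * rho)
    hs = np.where(h == 0.0, 1e-300, h)
    ks = np.where(k == 0.0, 1e-300, k)
    a_h = (k - rho * hs) / (hs * denom)
    a_k = (h - rho * ks) / (ks * denom)
    res = 0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
    res = res - special.owens_t(hs, a_h) - special.owens_t(ks, a_k)
    hk = h * k
    beta = np.where((hk < 0) | ((hk == 0) & (h + k < 0)), 0.5, 0.0)
    return np.clip(res - beta, 0.0, 1.0)


def _binary_corr(p: float, rho: float) -> float:
    """Correlation of two equal-frequency threshold indicators with latent corr rho."""
    t = stats.norm.ppf(p)
    p11 = float(_bvn_cdf(t, t, rho))
    return (p11 - p * p) / (p * (1.0 - p))


_RHO_CACHE: dict = {}


def _calibrate_latent_rho(target_r: float, maf: float) -> float:
    """Latent equicorrelation giving the requested dosage correlation at this MAF."""
    if target_r <= 0.0:
        return 0.0
    key = (round(target_r, 8), round(maf, 8))
    if key not in _RHO_CACHE:
        f = lambda rho: _binary_corr(maf, rho) - target_r
        hi = 1.0 - 1e-9
        if f(hi) < 0:  # numerically unattainable; saturate
            _RHO_CACHE[key] = hi
        else:
            _RHO_CACHE[key] = optimize.brentq(f, 0.0, hi, xtol=1e-10)
    return _RHO_CACHE[key]


# ---------------------------------------------------------------------------
# variant panel and genotypes
# ---------------------------------------------------------------------------

_NON_AMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_CHOICES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _variant_panel(config: SimConfig) -> pd.DataFrame:
    """Deterministic variant metadata shared by target and discovery cohorts.

    Blocks span < 1 Mb (5 kb spacing within a block) while distinct blocks are
    separated by > 1 Mb (2 Mb block origin spacing), so the 1 Mb clumping and
    locus-merging windows can distinguish within- from between-block pairs.
    """
    rng = config.rng(_S_PANEL)
    m = config.n_variants
    block = np.arange(m) // config.block_size
    within = np.arange(m) % config.block_size
    pos = block * 2_000_000 + within * 5_000 + 1
    n_blocks = int(block[-1]) + 1
    lo, hi = config.maf_range
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    maf = block_maf[block]
    amb_rate = config.qc_injection_rates.get("ambiguous", 0.0)
    is_amb = rng.random(m) < amb_rate
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    amb_idx = rng.integers(0, len(_AMBIGUOUS_CHOICES), size=m)
    non_idx = rng.integers(0, len(_NON_AMBIGUOUS_PAIRS), size=m)
    for i in range(m):
        a1[i], a2[i] = (
            _AMBIGUOUS_CHOICES[amb_idx[i]] if is_amb[i] else _NON_AMBIGUOUS_PAIRS[non_idx[i]]
        )
    return pd.DataFrame(
        {
            "CHROM": "1",
            "POS": pos.astype(np.int64),
            "ID": [f"rs{i + 1}" for i in range(m)],
            "A1": a1,
            "A2": a2,
            "MAF": maf,  # target MAF; replaced by realized MAF after simulation
            "BLOCK": block,
        }
    )


def _draw_dosages(config: SimConfig, panel: pd.DataFrame, n: int, rng) -> np.ndarray:
    """Hard-call dosages of A1 from the calibrated Gaussian-copula block model."""
    m = len(panel)
    dos = np.empty((n, m), dtype=float)
    blocks = panel["BLOCK"].to_numpy()
    target_maf = panel["MAF"].to_numpy()
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        maf = float(target_maf[cols[0]])
        t = stats.norm.ppf(maf)
        rho = _calibrate_latent_rho(config.within_block_r, maf)
        total = np.zeros((n, len(cols)))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, len(cols)))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            total += (z < t).astype(float)
        dos[:, cols] = total
    return dos


def simulate_genotypes(config: SimConfig) -> tuple[DosageMatrix, pd.DataFrame]:
    """Simulate the target cohort's dosage matrix and its variant table."""
    panel = _variant_panel(config)
    rng = config.rng(_S_GENO)
    dos = _draw_dosages(config, panel, config.n_subjects, rng)
    freq = dos.mean(axis=0) / 2.0
    variants = panel.copy()
    variants["A1_FREQ"] = freq
    variants["MAF"] = np.minimum(freq, 1.0 - freq)
    subjects = pd.Index([f"S{i:06d}" for i in range(config.n_subjects)], name="SUBJECT_ID")
    return DosageMatrix(dos, subjects, variants), variants


def simulate_architecture(config: SimConfig, variants: pd.DataFrame) -> TrueArchitecture:
    """Draw shared and subtype-unique causal loci, one per distinct LD block."""
    rng = config.rng(_S_ARCH)
    subtypes = config.subtypes
    blocks = variants["BLOCK"].to_numpy()
    uniq_blocks = np.unique(blocks)
    need = config.n_shared_causal + len(subtypes) * config.n_unique_causal_per_subtype
    if need > len(uniq_blocks):
        raise ConfigError(
            f"need {need} distinct LD blocks for causal loci, only {len(uniq_blocks)} available"
        )
    chosen_blocks = rng.choice(uniq_blocks, size=need, replace=False)
    chosen_ids = []
    ids = variants["ID"].to_numpy()
    for b in chosen_blocks:
        members = np.flatnonzero(blocks == b)
        chosen_ids.append(ids[rng.choice(members)])
    shared_ids = chosen_ids[: config.n_shared_causal]
    unique_ids = {}
    off = config.n_shared_causal
    for s in subtypes:
        unique_ids[s] = set(chosen_ids[off : off + config.n_unique_causal_per_subtype])
        off += config.n_unique_causal_per_subtype
    effects = pd.DataFrame(0.0, index=pd.Index(chosen_ids, name="ID"), columns=subtypes)
    shared_beta = rng.normal(0.0, config.effect_sd, size=len(shared_ids))
    for s in subtypes:
        effects.loc[shared_ids, s] = shared_beta  # identical across subtypes
        uids = sorted(unique_ids[s])
        effects.loc[uids, s] = rng.normal(0.0, config.effect_sd, size=len(uids))
    return TrueArchitecture(effects, set(shared_ids), unique_ids)


# ---------------------------------------------------------------------------
# phenome
# ---------------------------------------------------------------------------

def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    f = lambda a: special.expit(a + eta).mean() - prevalence
    return optimize.brentq(f, -40.0, 40.0)


def _trait_registry(config: SimConfig) -> pd.DataFrame:
    """Trait -> phecode and its ICD9/ICD10 aliases (deterministic, no RNG)."""
    rows = []

    def add(trait, phecode, desc):
        rows.append((trait, phecode, desc, f"D9-{phecode}", f"D10-{phecode}"))

    add("skin_cancer_any", "172", "skin cancer (any subtype)")
    for i, s in enumerate(config.subtypes):
        add(s, f"172.{i + 1}", f"skin cancer subtype: {s}")
    for k in range(config.n_secondary_traits):
        add(f"secondary_{k + 1}", f"702.{k + 1}", f"genetically correlated secondary trait {k + 1}")
    for k in range(config.n_null_codes):
        add(f"null_{k + 1}", f"{300 + k}", f"independent null trait {k + 1}")
    return pd.DataFrame(rows, columns=["TRAIT", "PHECODE", "DESCRIPTION", "ICD9", "ICD10"])


def synthetic_phecode_map(config: SimConfig) -> pd.DataFrame:
    """ICD->PheCode mapping table (PHECODE, DESCRIPTION, VOCAB, CODE) for the
    synthetic vocabulary; every trait has one ICD9 and one ICD10 alias."""
    reg = _trait_registry(config)
    out = []
    for row in reg.itertuples(index=False):
        out.append((row.PHECODE, row.DESCRIPTION, "ICD9", row.ICD9))
        out.append((row.PHECODE, row.DESCRIPTION, "ICD10", row.ICD10))
    return pd.DataFrame(out, columns=["PHECODE", "DESCRIPTION", "VOCAB", "CODE"])


def subtype_phecode(config: SimConfig, subtype: str) -> str:
    """PheCode assigned to a named subtype (or 'skin_cancer_any')."""
    reg = _trait_registry(config)
    trait = subtype if subtype != "overall" else "skin_cancer_any"
    hit = reg.loc[reg["TRAIT"] == trait, "PHECODE"]
    if hit.empty:
        raise KeyError(f"unknown trait {subtype!r}")
    return str(hit.iloc[0])


def _simulate_subtype_status(
    dosages: np.ndarray,
    variant_ids: pd.Index,
    architecture: TrueArchitecture,
    config: SimConfig,
    rng,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bernoulli subtype status from logit(P) = alpha + sum beta_i G_i."""
    col_of = {v: i for i, v in enumerate(variant_ids)}
    status = {}
    for s in config.subtypes:
        beta = architecture.effects[s]
        beta = beta[beta != 0.0]
        idx = [col_of[v] for v in beta.index]
        eta = dosages[:, idx] @ beta.to_numpy()
        if config.pc_confounding and pcs is not None:
            eta = eta + config.pc_confounding * pcs[:, 0]
        alpha = _solve_intercept(eta, config.base_prevalence[s])
        p = special.expit(alpha + eta)
        st = rng.random(len(p)) < p
        if st.all() or not st.any():
            raise DegenerateSimulationError(f"subtype {s!r} collapsed to prevalence 0 or 1")
        status[s] = st
    return pd.DataFrame(status)


def simulate_phenome(
    dosages: DosageMatrix,
    architecture: TrueArchitecture,
    config: SimConfig,
    return_truth: bool = False,
):
    """Generate the subject table and dated ICD9/ICD10 event table.

    Returns ``(subjects, events)``; with ``return_truth=True`` a third
    DataFrame of true per-subject binary trait status is appended.
    """
    rng = config.rng(_S_PHENOME)
    n = dosages.n_subjects
    ids = dosages.subject_ids
    pcs = rng.standard_normal((n, 4))
    subjects = pd.DataFrame(
        {
            "SUBJECT_ID": ids,
            "SEX": rng.choice(["M", "F"], size=n),
            "AGE": np.clip(np.round(rng.normal(55, 10, size=n)), 18, 90).astype(int),
            "ARRAY": rng.choice(["array_A", "array_B"], size=n),
            "PC1": pcs[:, 0],
            "PC2": pcs[:, 1],
            "PC3": pcs[:, 2],
            "PC4": pcs[:, 3],
        }
    )

    vids = pd.Index(dosages.variants["ID"])
    truth = _simulate_subtype_status(dosages.dosages, vids, architecture, config, rng, pcs)

    # shared-locus score drives the secondary traits (genetic correlation)
    shared = sorted(architecture.shared_variant_ids)
    if shared:
        col_of = {v: i for i, v in enumerate(vids)}
        idx = [col_of[v] for v in shared]
        w = architecture.effects.loc[shared, config.subtypes[0]].to_numpy()
        score = dosages.dosages[:, idx] @ w
        sd = score.std()
        z_shared = (score - score.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        z_shared = np.zeros(n)
    extra = {}
    for k in range(config.n_secondary_traits):
        eta = config.secondary_effect * z_shared
        alpha = _solve_intercept(eta, config.secondary_prevalence)
        extra[f"secondary_{k + 1}"] = rng.random(n) < special.expit(alpha + eta)

    lo, hi = config.null_code_prev_range
    null_prev = rng.uniform(lo, hi, size=config.n_null_codes)
    for k in range(config.n_null_codes):
        extra[f"null_{k + 1}"] = rng.random(n) < null_prev[k]

    truth = pd.concat([truth, pd.DataFrame(extra)], axis=1)
    truth.index = ids

    reg = _trait_registry(config).set_index("TRAIT")
    records = []
    for trait in truth.columns:
        carriers = np.flatnonzero(truth[trait].to_numpy())
        if carriers.size == 0:
            continue
        icd9, icd10 = reg.loc[trait, "ICD9"], reg.loc[trait, "ICD10"]
        days = rng.integers(0, _DATE_WINDOW_DAYS, size=carriers.size)
        vocab_is_9 = rng.random(carriers.size) < 0.5
        repeat = rng.random(carriers.size) < 0.3  # some subjects get a later repeat event
        extra_days = rng.integers(1, 400, size=carriers.size)
        for j, subj_idx in enumerate(carriers):
            sid = ids[subj_idx]
            vocab = "ICD9" if vocab_is_9[j] else "ICD10"
            code = icd9 if vocab_is_9[j] else icd10
            date = _DATE_WINDOW_START + pd.Timedelta(days=int(days[j]))
            records.append((sid, vocab, code, date))
            if repeat[j]:
                records.append((sid, vocab, code, date + pd.Timedelta(days=int(extra_days[j]))))
    events = pd.DataFrame(records, columns=["SUBJECT_ID", "VOCAB", "CODE", "DATE"])
    events = events.sort_values(["SUBJECT_ID", "DATE", "CODE"], kind="mergesort").reset_index(drop=True)

    if return_truth:
        return subjects, events, truth
    return subjects, events


# ---------------------------------------------------------------------------
# discovery GWAS
# ---------------------------------------------------------------------------

def _marginal_logistic(dosages: np.ndarray, y: np.ndarray, chunk: int = 256):
    """Vectorized per-variant logistic regression (intercept + dosage).

    Returns (beta, se, p) arrays; monomorphic variants get beta 0 / se inf.
    """
    n, m = dosages.shape
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    ybar = y.mean()
    for start in range(0, m, chunk):
        G = dosages[:, start : start + chunk]
        k = G.shape[1]
        poly = G.std(axis=0) > 0
        b0 = np.full(k, special.logit(ybar))
        b1 = np.zeros(k)
        for _ in range(12):
            eta = b0[None, :] + b1[None, :] * G
            p = special.expit(eta)
            w = p * (1.0 - p)
            sw = w.sum(axis=0)
            swg = (w * G).sum(axis=0)
            swgg = (w * G * G).sum(axis=0)
            r = y[:, None] - p
            u0 = r.sum(axis=0)
            u1 = (r * G).sum(axis=0)
            det = sw * swgg - swg * swg
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            d0 = (swgg * u0 - swg * u1) / det
            d1 = (sw * u1 - swg * u0) / det
            d0 = np.where(poly & np.isfinite(d0), d0, 0.0)
            d1 = np.where(poly & np.isfinite(d1), d1, 0.0)
            b0 += np.clip(d0, -4, 4)
            b1 += np.clip(d1, -4, 4)
            if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < 1e-10:
                break
        eta = b0[None, :] + b1[None, :] * G
        p = special.expit(eta)
        w = p * (1.0 - p)
        sw = w.sum(axis=0)
        swg = (w * G).sum(axis=0)
        swgg = (w * G * G).sum(axis=0)
        det = sw * swgg - swg * swg
        with np.errstate(divide="ignore", invalid="ignore"):
            se_chunk = np.sqrt(sw / det)
        beta[start : start + k] = np.where(poly, b1, 0.0)
        se[start : start + k] = np.where(poly & np.isfinite(se_chunk), se_chunk, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se), beta / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def simulate_discovery_gwas(
    architecture: TrueArchitecture,
    config: SimConfig,
    subtype: str = "overall",
    return_injections: bool = False,
):
    """Marginal summary statistics from an independent discovery cohort.

    ``subtype='overall'`` analyzes the any-subtype phenotype. With stated
    probabilities rows are corrupted for QC testing: non-ambiguous rows may be
    strand-flipped (both alleles complemented) or have their EAF replaced by a
    far-off value; rows at strand-ambiguous panel variants have their effect
    allele replaced by a base matching neither panel allele.
    """
    if config.discovery_n <= 0:
        raise ConfigError("discovery_n must be positive")
    panel = _variant_panel(config)
    rng = config.rng(_S_GWAS_GENO)
    dos = _draw_dosages(config, panel, config.discovery_n, rng)
    vids = pd.Index(panel["ID"])
    status = _simulate_subtype_status(dos, vids, architecture, config, rng)
    if subtype == "overall":
        y = status.any(axis=1).to_numpy().astype(float)
    elif subtype in status:
        y = status[subtype].to_numpy().astype(float)
    else:
        raise ConfigError(f"unknown subtype {subtype!r}")

    beta, se, pval = _marginal_logistic(dos, y)
    eaf = dos.mean(axis=0) / 2.0
    stats_df = pd.DataFrame(
        {
            "ID": panel["ID"],
            "CHROM": panel["CHROM"],
            "POS": panel["POS"],
            "EFFECT_ALLELE": panel["A1"].copy(),
            "OTHER_ALLELE": panel["A2"].copy(),
            "BETA": beta,
            "SE": se,
            "P": pval,
            "EAF": eaf,
            "N": config.discovery_n,
        }
    )

    inj_rng = config.rng(_S_GWAS_INJECT)
    m = len(stats_df)
    amb_mask = np.array(
        [is_ambiguous(a1, a2) for a1, a2 in zip(panel["A1"], panel["A2"])]
    )
    kinds = np.full(m, "", dtype=object)
    kinds[amb_mask] = "ambiguous"
    flip_rate = config.qc_injection_rates.get("strand_flip", 0.0)
    raf_rate = config.qc_injection_rates.get("raf_error", 0.0)
    u = inj_rng.random(m)
    flip_mask = (~amb_mask) & (u < flip_rate)
    kinds[flip_mask] = "strand_flip"
    raf_mask = (~amb_mask) & (~flip_mask) & (u >= flip_rate) & (u < flip_rate + raf_rate)
    kinds[raf_mask] = "raf_error"

    ea = stats_df["EFFECT_ALLELE"].to_numpy(dtype=object)
    oa = stats_df["OTHER_ALLELE"].to_numpy(dtype=object)
    for i in np.flatnonzero(amb_mask):
        # a base matching neither allele of an A/T or C/G pair
        ea[i] = "C" if frozenset((ea[i], oa[i])) == frozenset(("A", "T")) else "A"
    for i in np.flatnonzero(flip_mask):
        ea[i], oa[i] = COMPLEMENT[ea[i]], COMPLEMENT[oa[i]]
    stats_df["EFFECT_ALLELE"] = ea
    stats_df["OTHER_ALLELE"] = oa
    new_eaf = stats_df["EAF"].to_numpy().copy()
    new_eaf[raf_mask] = np.where(new_eaf[raf_mask] < 0.5, new_eaf[raf_mask] + 0.3, new_eaf[raf_mask] - 0.3)
    stats_df["EAF"] = new_eaf

    if return_injections:
        injections = pd.DataFrame({"ID": panel["ID"], "KIND": kinds})
        injections = injections[injections["KIND"] != ""].reset_index(drop=True)
        return stats_df, injections
    return stats_df


def write_truth(architecture: TrueArchitecture, path) -> None:
    """Write true per-subtype effects as TSV (ID + one column per subtype)."""
    architecture.effects.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_summary_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHROM": str})
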