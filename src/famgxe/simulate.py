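"""Synthetic family data with the structure of the GAW19 SBP simulation.

Emulates the study conditions behind the gene-medication interaction
comparison: ~20 extended pedigrees of ~1,060-1,080 individuals, additive
SNP dosages from gene dropping, cross-sectional antihypertensive-medication
status, and a quantitative SBP-like trait with a polygenic component
proportional to the pedigree relationship matrix.  Carriers of interaction
SNPs are non-responders: with ``beta_med = -6.2`` and ``beta_int = +6.2``
a medicated carrier's expected treatment benefit is exactly zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError, FamGxEError
from .pedigree import FamilyTemplate, Pedigree, build_pedigree
from .relatedness import (
    RelationshipMatrix,
    founder_pca,
    ld_prune,
    numerator_relationship_matrix,
    project_pcs,
)

# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypePanel:
    """Additive dosage matrix with per-SNP metadata.

    ``dosages`` is individuals x SNPs in [0, 2]; ``snp_meta`` is indexed by
    SNP id with columns chrom, pos, maf, mac (minor-allele frequency/count
    recomputed from the realized sample, dosages rounded to nearest before
    counting).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_meta)):
            raise FamGxEError("dosage matrix shape disagrees with ids/snp_meta")
        if np.any((self.dosages < 0) | (self.dosages > 2)):
            raise FamGxEError("dosages must lie in [0, 2]")
        if np.any(self.snp_meta["pos"] <= 0):
            raise FamGxEError("positions must be strictly positive")

    def column(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snp_meta.index.get_loc(snp)]

    @staticmethod
    def realized_meta(dosages: np.ndarray, chrom, pos, index) -> pd.DataFrame:
        counts = np.rint(dosages).sum(axis=0)
        n2 = 2 * dosages.shape[0]
        mac = np.minimum(counts, n2 - counts).astype(int)
        return pd.DataFrame(
            {"chrom": chrom, "pos": pos, "maf": mac / n2, "mac": mac}, index=index
        )


@dataclass(frozen=True)
class SnpSpec:
    """Placement and allele frequency of one simulated SNP."""

    snp: str
    chrom: str
    pos: int
    maf: float


@dataclass(frozen=True)
class CausalSnp(SnpSpec):
    """A SNP carrying a main effect (mm Hg per minor allele) and/or an
    interaction effect with medication (mm Hg)."""

    beta_snp: float = 0.0
    beta_int: float = 0.0


@dataclass(frozen=True)
class AgeDistribution:
    mean: float = 48.1
    sd: float = 14.0
    min: float = 18.0
    max: float = 101.0

    def __post_init__(self):
        if not self.min <= self.mean <= self.max:
            raise ConfigurationError("age distribution requires min <= mean <= max")
        if self.sd <= 0:
            raise ConfigurationError("age sd must be positive")


@dataclass
class SimConfig:
    """Generating parameters for one replicate family study.

    Defaults reproduce the emulated study conditions: 20 extended families
    (~1,080 individuals), medication prevalence 0.327 with a -6.2 mm Hg
    treatment effect, total phenotypic variance ~181 mm Hg^2 with
    heritability 0.30, and medication-specific residual variances in ratio
    1.2.
    """

    n_families: int = 20
    family_template: FamilyTemplate = field(default_factory=FamilyTemplate)
    null_snps: list[SnpSpec] = field(default_factory=list)
    causal_snps: list[CausalSnp] = field(default_factory=list)
    beta_med: float = -6.2
    med_prevalence: float = 0.327
    sigma2_additive: float = 54.3
    sigma2_resid_unmed: float = 119.0
    sigma2_resid_med: float = 142.8
    intercept: float = 135.0
    beta_age: float = 0.4
    beta_sex_female: float = -3.0
    age_distribution: AgeDistribution = field(default_factory=AgeDistribution)
    prop_female: float = 0.58
    n_replicates: int = 200
    seed: int = 2016
    medication_mode: str = "random"       # or "indication"
    indication_quantile: float = 0.673    # top (1-q) of latent SBP medicated
    attach_pcs: bool = True
    n_pcs: int = 5
    ld_r2: float = 0.2

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        for v in (self.sigma2_additive, self.sigma2_resid_unmed, self.sigma2_resid_med):
            if v < 0:
                raise ConfigurationError("variances must be >= 0")
        for p in (self.med_prevalence, self.prop_female):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must be in [0, 1]")
        if self.medication_mode not in ("random", "indication"):
            raise ConfigurationError("medication_mode must be 'random' or 'indication'")

    @property
    def all_snps(self) -> list[SnpSpec]:
        snps = list(self.null_snps) + list(self.causal_snps)
        return sorted(snps, key=lambda s: (_chrom_key(s.chrom), s.pos))


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


@dataclass
class ReplicateDataset:
    """One phenotype replicate over the shared pedigree and genotype panel."""

    pedigree: Pedigree
    genotypes: GenotypePanel
    phenotypes: pd.DataFrame
    replicate_index: int
    truth: dict
    relationship: RelationshipMatrix | None = None


# ---------------------------------------------------------------------------
# scenario constructors

CYP_POSITIONS = {0.001: ("7", 99457518), 0.008: ("7", 99454482), 0.054: ("7", 99457605)}
MAP4_CHROM, MAP4_POS = "3", 48040283


def uniform_null_snps(
    n: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    chroms: tuple[str, ...] = ("1", "5", "9", "13", "17", "21"),
    seed: int = 0,
    spacing_bp: int = 1_000_000,
) -> list[SnpSpec]:
    """Null SNPs with MAFs uniform over ``maf_range``, spread over odd
    chromosomes away from the simulated effect loci."""
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n)
    snps = []
    for j in range(n):
        chrom = chroms[j % len(chroms)]
        pos = 1_000_000 + (j // len(chroms)) * spacing_bp
        snps.append(SnpSpec(f"chr{chrom}:{pos}", chrom, pos, float(mafs[j])))
    return snps


def cyp3a43_scenario(
    mafs: tuple[float, ...] = (0.054,),
    n_background: int = 200,
    **overrides,
) -> SimConfig:
    """Carrier-nonresponse scenario: interaction +6.2 mm Hg, no main effect.

    ``mafs`` selects which of the three locus SNPs (MAF 0.1/0.8/5.4%) carry
    the interaction; background null SNPs support the PC adjustment.
    """
    causal = []
    for maf in mafs:
        chrom, pos = CYP_POSITIONS[maf]
        causal.append(CausalSnp(f"chr{chrom}:{pos}", chrom, pos, maf, 0.0, 6.2))
    return SimConfig(
        null_snps=uniform_null_snps(n_background, seed=11),
        causal_snps=causal,
        **overrides,
    )


def map4_scenario(n_background: int = 200, **overrides) -> SimConfig:
    """Strong main-effect scenario: -9.91 mm Hg per allele at MAF 2.7%."""
    causal = [CausalSnp(f"chr{MAP4_CHROM}:{MAP4_POS}", MAP4_CHROM, MAP4_POS, 0.027, -9.91, 0.0)]
    return SimConfig(
        null_snps=uniform_null_snps(n_background, seed=11),
        causal_snps=causal,
        **overrides,
    )


def null_scenario(
    n_snps: int = 400,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 11,
    **overrides,
) -> SimConfig:
    """No genetic effects; used for false-positive calibration."""
    return SimConfig(
        null_snps=uniform_null_snps(n_snps, maf_range=maf_range, seed=seed),
        causal_snps=[],
        **overrides,
    )


# ---------------------------------------------------------------------------
# operations


def generate_pedigree(config: SimConfig) -> Pedigree:
    """Disjoint extended families from the configured template."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    return build_pedigree(
        config.n_families, config.family_template, config.prop_female, rng
    )


def drop_genotypes(
    pedigree: Pedigree,
    snps: list[SnpSpec],
    seed: int | np.random.Generator = 0,
) -> GenotypePanel:
    """Gene dropping: founder genotypes Binomial(2, maf) under Hardy-Weinberg,
    one allele transmitted Mendelian-style from each parent; SNPs independent
    (no linkage)."""
    for s in snps:
        if not 0.0 < s.maf <= 0.5:
            raise ConfigurationError(f"{s.snp}: MAF must be in (0, 0.5], got {s.maf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = len(pedigree), len(snps)
    # alleles[i, j, :] are the two alleles of individual i at SNP j
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    mafs = np.array([s.maf for s in snps])
    order = pedigree.topological_order
    fidx, midx = pedigree.father_idx, pedigree.mother_idx
    for i in order:
        if fidx[i] < 0:
            alleles[i] = rng.random((m, 2)) < mafs[:, None]
        else:
            pick = rng.integers(0, 2, size=(2, m))
            alleles[i, :, 0] = alleles[fidx[i], np.arange(m), pick[0]]
            alleles[i, :, 1] = alleles[midx[i], np.arange(m), pick[1]]
    dosages = alleles.sum(axis=2).astype(float)
    meta = GenotypePanel.realized_meta(
        dosages,
        [s.chrom for s in snps],
        [s.pos for s in snps],
        pd.Index([s.snp for s in snps], name="snp"),
    )
    return GenotypePanel(dosages, meta, list(pedigree.ids))


def assign_medication(
    pedigree: Pedigree,
    prevalence: float,
    seed: int | np.random.Generator = 0,
    mode: str = "random",
    latent: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-sectional medication indicator.

    Default is independent Bernoulli(prevalence).  In ``indication`` mode the
    top ``prevalence`` fraction of a supplied latent pre-treatment SBP is
    medicated, introducing confounding by indication.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ConfigurationError("prevalence must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pedigree)
    if mode == "random":
        return (rng.random(n) < prevalence).astype(int)
    if mode == "indication":
        if latent is None:
            raise ConfigurationError("indication mode needs a latent SBP vector")
        k = int(round(prevalence * n))
        med = np.zeros(n, dtype=int)
        if k > 0:
            med[np.argsort(latent)[::-1][:k]] = 1
        return med
    raise ConfigurationError(f"unknown medication mode {mode!r}")


def simulate_phenotype(
    pedigree: Pedigree,
    genotypes: GenotypePanel,
    med: np.ndarray,
    R: RelationshipMatrix,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One SBP replicate.

    SBP = intercept + beta_age*age + beta_sex*I(female) + sum beta_snp*G
    + beta_med*Med + sum beta_int*G*Med + g + e, with
    g ~ N(0, sigma2_additive * R) and e heteroscedastic by medication status.
    """
    if R.n != len(pedigree):
        raise FamGxEError("relationship matrix not conformable with pedigree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pedigree)
    ad = config.age_distribution
    a = (ad.min - ad.mean) / ad.sd
    b = (ad.max - ad.mean) / ad.sd
    age = truncnorm.rvs(a, b, loc=ad.mean, scale=ad.sd, size=n, random_state=rng)
    female = pedigree.sex_mask_female().astype(float)
    y = (
        config.intercept
        + config.beta_age * age
        + config.beta_sex_female * female
        + config.beta_med * med
    )
    for c in config.causal_snps:
        g = genotypes.column(c.snp)
        y = y + c.beta_snp * g + c.beta_int * g * med
    if config.sigma2_additive > 0:
        try:
            chols = R.grouped_cholesky()
        except np.linalg.LinAlgError as exc:
            raise FamGxEError(f"relationship matrix not positive semidefinite: {exc}")
        g_poly = np.zeros(n)
        for idx, Ls in chols:
            z = rng.standard_normal(idx.shape)
            g_poly[idx.ravel()] = np.einsum("bst,bt->bs", Ls, z).ravel()
        y = y + np.sqrt(config.sigma2_additive) * g_poly
    resid_sd = np.where(
        med == 1,
        np.sqrt(config.sigma2_resid_med),
        np.sqrt(config.sigma2_resid_unmed),
    )
    y = y + resid_sd * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "id": pedigree.ids,
            "sbp_t3": y,
            "age": age,
            "sex": [ind.sex for ind in pedigree.individuals],
            "med": med.astype(int),
        }
    ).set_index("id", drop=False)


def generate_replicates(config: SimConfig) -> Iterator[ReplicateDataset]:
    """Stream of phenotype replicates over one shared genotype panel.

    The pedigree, genotypes, relationship matrix and PC scores are generated
    once; each replicate re-draws medication, ages and the phenotype with an
    independent stream that is a deterministic function of (seed, replicate).
    """
    if config.n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    pedigree = generate_pedigree(config)
    geno_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    panel = drop_genotypes(pedigree, config.all_snps, geno_rng)
    R = numerator_relationship_matrix(pedigree)
    pcs = None
    if config.attach_pcs:
        pruned = ld_prune(panel, config.ld_r2, subset=pedigree.founder_ids)
        pruned = [
            s for s in pruned if panel.column(s)[pedigree.founder_mask].std() > 0
        ]
        if len(pruned) > config.n_pcs:
            model = founder_pca(panel, pedigree.founder_ids, pruned, k=config.n_pcs)
            pcs = project_pcs(model, panel)
    base_truth = {
        "beta_med": config.beta_med,
        "causal_snps": {
            c.snp: {"maf": c.maf, "beta_snp": c.beta_snp, "beta_int": c.beta_int}
            for c in config.causal_snps
        },
    }
    for r in range(config.n_replicates):
        rep_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, r]))
        if config.medication_mode == "indication":
            latent = simulate_phenotype(
                pedigree, panel, np.zeros(len(pedigree), dtype=int), R, config,
                np.random.default_rng(np.random.SeedSequence([config.seed, 3, r])),
            )["sbp_t3"].to_numpy()
            med = assign_medication(
                pedigree, config.med_prevalence, rep_rng, "indication", latent
            )
        else:
            med = assign_medication(pedigree, config.med_prevalence, rep_rng)
        phen = simulate_phenotype(pedigree, panel, med, R, config, rep_rng)
        if pcs is not None:
            phen = phen.join(pcs)
        truth = dict(
            base_truth,
            replicate=r,
            realized_prevalence=float(med.mean()),
        )
        yield ReplicateDataset(pedigree, panel, phen, r, truth, R)
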