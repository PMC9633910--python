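"""Synthetic mutagenized-population generator.

Emulates the statistical structure the pooled-screening analysis assumes: a
population of diploid M2 plants carrying induced variants at a low per-base
rate inside two target gene intervals, 8-plex equal-mass pooling with one
wild-type (WT) reference sample, binomially sampled read pileups with
sequencing error, Sanger-style per-individual genotyping with an optional
discordance rate, and grain length/width phenotypes built from WT means plus
per-(consequence, domain) effect rules and replicate seed noise.

All randomness flows through one :class:`numpy.random.Generator`, so a fixed
seed reproduces every table bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .annotate import VariantConsequence, classify_variant, domain_overlap
from .errors import ConfigError, DataError
from .genemodels import GeneModel, reference_base
from .screen import BASES, PileupSite

logger = logging.getLogger(__name__)


class SimulationConfig(BaseModel):
    """Study-design parameters of the simulated screen.

    Defaults reproduce the screening design: 3872 M2 plants pooled 8:1 into
    484 mixed samples plus one WT sample, grain length/width WT means of
    9.31/2.03 mm with 30 replicate seeds per plant, and induced mutations
    that are homozygous in the M2 material.
    """

    population_size: int = Field(default=3872, ge=1)
    pool_size: int = Field(default=8, ge=2)
    per_base_mutation_rate: float = Field(default=5e-6, ge=0.0, le=1.0)
    homozygous_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    indel_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    depth_mean: float = Field(default=2000.0, gt=0.0)
    sequencing_error_rate: float = Field(default=1e-3, ge=0.0, le=1.0)
    sanger_discordance_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    wt_length_mean: float = Field(default=9.31, gt=0.0)
    wt_width_mean: float = Field(default=2.03, gt=0.0)
    noise_sd_length: float = Field(default=0.18, ge=0.0)
    noise_sd_width: float = Field(default=0.0113, ge=0.0)
    n_replicates: int = Field(default=30, ge=2)
    seed: int = 0

    @model_validator(mode="after")
    def _check_pooling(self) -> "SimulationConfig":
        if self.population_size < self.pool_size:
            raise ValueError(
                f"population_size {self.population_size} smaller than "
                f"pool_size {self.pool_size}"
            )
        return self


@dataclass
class InducedVariant:
    """One induced mutation carried by one plant (dash-convention alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "hom" | "het"
    gene: str | None = None
    consequence: VariantConsequence | None = None
    domain: str | None = None

    @property
    def genotype(self) -> tuple[str, str]:
        return (self.alt, self.alt) if self.zygosity == "hom" else (self.ref, self.alt)


@dataclass
class SimulatedIndividual:
    individual_id: str
    variants: list[InducedVariant] = field(default_factory=list)
    true_length: float | None = None
    true_width: float | None = None
    length_replicates: np.ndarray | None = None
    width_replicates: np.ndarray | None = None

    def genotype_at(self, chrom: str, pos: int, ref: str) -> tuple[str, str]:
        for v in self.variants:
            if v.chrom == chrom and v.pos == pos:
                return v.genotype
        return (ref, ref)


@dataclass
class Pool:
    """An equal-mass mixture of member plants sequenced as one library."""

    pool_id: str
    members: list[SimulatedIndividual]

    @property
    def member_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    @property
    def n_haplotypes(self) -> int:
        # the WT reference sample is a single diploid plant, not a mixture
        return 2 * len(self.members) if self.members else 2

    def allele_frequencies(self, chrom: str, pos: int, ref: str) -> dict[str, float]:
        if not self.members:
            return {ref: 1.0}
        counts: dict[str, int] = {}
        for m in self.members:
            for allele in m.genotype_at(chrom, pos, ref):
                counts[allele] = counts.get(allele, 0) + 1
        n = self.n_haplotypes
        return {a: c / n for a, c in counts.items()}


@dataclass
class PoolSet:
    pools: list[Pool]
    wt: Pool

    @property
    def n_pools(self) -> int:
        return len(self.pools)


@dataclass
class EffectTable:
    """Additive phenotype effects keyed by (consequence class, domain or None).

    Lookup is total: an exact (class, domain) rule wins, then a
    (class, None) wildcard-domain rule, else (0, 0).  Effects are added to
    the WT trait means in millimetres.
    """

    rules: dict[tuple[str, str | None], tuple[float, float]] = field(default_factory=dict)

    def effect_for(self, klass: str | None, domain: str | None) -> tuple[float, float]:
        if klass is None:
            return (0.0, 0.0)
        if (klass, domain) in self.rules:
            return self.rules[(klass, domain)]
        return self.rules.get((klass, None), (0.0, 0.0))

    @classmethod
    def default_grain_effects(cls) -> "EffectTable":
        """Effect rules matching the observed significant grain-shape shifts:
        OSR truncation lengthens the grain by ~0.91 mm, TNFR/NGFR and VWFC
        missense shorten it, calmodulin-binding missense widens it."""
        return cls({
            ("stopgain", "OSR"): (0.91, 0.0),
            ("frameshift_insertion", "OSR"): (0.91, 0.0),
            ("frameshift_deletion", "OSR"): (0.91, 0.0),
            ("nonsynonymous", "TNFR/NGFR"): (-1.25, 0.0),
            ("nonsynonymous", "VWFC"): (-0.80, 0.0),
            ("nonsynonymous", "calmodulin-binding"): (0.0, 0.26),
        })


# -- population -------------------------------------------------------------


def _target_positions(models: list[GeneModel], reference: dict[str, str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for m in models:
        lo, hi = m.span
        if m.chrom not in reference or hi > len(reference[m.chrom]):
            raise ConfigError(f"{m.gene_id}: interval not covered by the reference")
        out.extend((m.chrom, p) for p in range(lo, hi + 1))
    return out


def simulate_population(
    config: SimulationConfig,
    models: list[GeneModel],
    reference: dict[str, str],
    rng: np.random.Generator | None = None,
) -> list[SimulatedIndividual]:
    """Draw induced variants for every plant in the population.

    Per plant, the variant count is Binomial(total target bases,
    per_base_mutation_rate); positions are uniform without replacement over
    the target intervals, substitutions go to a uniformly random other base,
    and each variant is homozygous with probability ``homozygous_fraction``.
    """
    if not models:
        raise ConfigError("simulate_population requires at least one gene model")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    targets = _target_positions(models, reference)
    n_targets = len(targets)
    width = len(str(config.population_size))
    individuals = []
    counts = rng.binomial(n_targets, config.per_base_mutation_rate,
                          size=config.population_size)
    for i, n_var in enumerate(counts, start=1):
        ind = SimulatedIndividual(f"M2-{i:0{width}d}")
        if n_var:
            idx = rng.choice(n_targets, size=n_var, replace=False)
            for j in sorted(idx):
                chrom, pos = targets[j]
                ref = reference_base(reference, chrom, pos)
                ref_a, alt_a = _draw_alleles(rng, ref, config.indel_fraction)
                zyg = "hom" if rng.random() < config.homozygous_fraction else "het"
                ind.variants.append(InducedVariant(chrom, pos, ref_a, alt_a, zyg))
        individuals.append(ind)
    total = sum(len(ind.variants) for ind in individuals)
    logger.info("simulated %d plants with %d induced variants over %d target bases",
                len(individuals), total, n_targets)
    return individuals


def _draw_alleles(rng: np.random.Generator, ref: str, indel_fraction: float) -> tuple[str, str]:
    if indel_fraction and rng.random() < indel_fraction:
        ins_base = BASES[rng.integers(4)]
        return ("-", ins_base) if rng.random() < 0.5 else (ref, "-")
    others = [b for b in BASES if b != ref]
    return ref, others[rng.integers(3)]


def annotate_individuals(
    individuals: list[SimulatedIndividual],
    models: list[GeneModel],
    reference: dict[str, str],
) -> None:
    """Attach gene, consequence and domain labels to every induced variant."""
    by_chrom = [(m, m.span) for m in models]
    cache: dict[tuple, tuple] = {}
    for ind in individuals:
        for v in ind.variants:
            key = (v.chrom, v.pos, v.ref, v.alt)
            if key not in cache:
                model = next((m for m, (lo, hi) in by_chrom
                              if m.chrom == v.chrom and lo <= v.pos <= hi), None)
                if model is None:
                    cache[key] = (None, VariantConsequence("intergenic"), None)
                else:
                    cons = classify_variant(model, reference, v.pos, v.ref, v.alt)
                    domain = None
                    if cons.is_coding and cons.residue is not None:
                        hit = domain_overlap(cons, model)
                        domain = hit.domain or (hit.lost[0] if hit.lost else None)
                    cache[key] = (model.gene_id, cons, domain)
            v.gene, v.consequence, v.domain = cache[key]


def assign_phenotypes(
    individuals: list[SimulatedIndividual],
    effect_table: EffectTable,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimulatedIndividual]:
    """Give every plant replicate grain measurements around its true means.

    True trait means are the WT means plus the summed effects of the plant's
    annotated variants; each of the ``n_replicates`` seed measurements adds
    independent Normal(0, noise_sd) noise.
    """
    for sd in (config.noise_sd_length, config.noise_sd_width):
        if sd < 0:
            raise ConfigError(f"negative noise SD {sd}")
    for ind in individuals:
        if any(v.consequence is None for v in ind.variants):
            raise DataError(
                f"{ind.individual_id}: variants must be annotated before effect lookup"
            )
        dl = sum(effect_table.effect_for(v.consequence.klass, v.domain)[0]
                 for v in ind.variants)
        dw = sum(effect_table.effect_for(v.consequence.klass, v.domain)[1]
                 for v in ind.variants)
        ind.true_length = config.wt_length_mean + dl
        ind.true_width = config.wt_width_mean + dw
        ind.length_replicates = ind.true_length + rng.normal(
            0.0, config.noise_sd_length, config.n_replicates)
        ind.width_replicates = ind.true_width + rng.normal(
            0.0, config.noise_sd_width, config.n_replicates)
    return individuals


# -- pooling & sequencing ---------------------------------------------------


def make_pools(individuals: list[SimulatedIndividual], pool_size: int) -> PoolSet:
    """Partition the population in input order into pools of ``pool_size``.

    A remainder forms a final short pool (warned).  A WT reference sample
    (an empty pool standing for the unirradiated parent plant) is always
    emitted alongside.
    """
    if pool_size < 2:
        raise ConfigError(f"pool_size must be >= 2, got {pool_size}")
    if len(individuals) < pool_size:
        raise ConfigError(
            f"population of {len(individuals)} is smaller than pool_size {pool_size}"
        )
    pools = []
    n_pools = (len(individuals) + pool_size - 1) // pool_size
    width = len(str(n_pools))
    for k in range(n_pools):
        chunk = individuals[k * pool_size : (k + 1) * pool_size]
        pools.append(Pool(f"P{k + 1:0{width}d}", chunk))
    if len(individuals) % pool_size:
        logger.warning("final pool %s is short: %d members instead of %d",
                       pools[-1].pool_id, len(pools[-1].members), pool_size)
    return PoolSet(pools, Pool("WT", []))


def simulate_pileup(
    pool: Pool,
    chrom: str,
    pos: int,
    ref: str,
    depth_mean: float,
    error_rate: float,
    rng: np.random.Generator,
    fixed_depth: bool = False,
) -> PileupSite:
    """Multinomially sample a read pileup for one pool at one site.

    Reads draw their true allele from the pool's haplotype frequencies; a
    substitution error (probability ``error_rate``) moves a base call to a
    uniformly random other base.  Indel alleles are read correctly with
    probability 1 − error, otherwise as the reference base.  Depth is
    Poisson(depth_mean) unless ``fixed_depth``.
    """
    if depth_mean <= 0:
        raise ConfigError(f"depth_mean must be positive, got {depth_mean}")
    freqs = pool.allele_frequencies(chrom, pos, ref)
    cats: list[str] = list(BASES) + sorted(a for a in freqs if a not in BASES)
    probs = np.zeros(len(cats))
    cat_index = {c: i for i, c in enumerate(cats)}
    e = error_rate
    for allele, f in freqs.items():
        if allele in BASES:
            for b in BASES:
                probs[cat_index[b]] += f * ((1 - e) if b == allele else e / 3)
        else:  # indel allele: misread as the reference base
            probs[cat_index[allele]] += f * (1 - e)
            probs[cat_index[ref]] += f * e
    depth = int(round(depth_mean)) if fixed_depth else int(rng.poisson(depth_mean))
    counts = rng.multinomial(depth, probs / probs.sum()) if depth > 0 else np.zeros(len(cats), int)
    return PileupSite(pool.pool_id, chrom, pos, ref,
                      {c: int(n) for c, n in zip(cats, counts)})


def simulate_sanger(
    individual: SimulatedIndividual,
    positions: list[tuple[str, int]],
    reference: dict[str, str],
    discordance_rate: float,
    rng: np.random.Generator,
    forced_discordant: frozenset[tuple[str, int]] = frozenset(),
) -> dict[tuple[str, int], tuple[str, str]]:
    """Per-individual genotype calls at the given positions.

    A call equals the true genotype with probability 1 − discordance_rate and
    otherwise reverts to the homozygous WT (reference) call — the failure
    mode seen when pooled-sequencing candidates are not confirmed in any
    member plant.  ``forced_discordant`` positions always revert.
    """
    if not 0.0 <= discordance_rate <= 1.0:
        raise ConfigError(f"discordance_rate {discordance_rate} outside [0, 1]")
    calls = {}
    for chrom, pos in positions:
        ref = reference_base(reference, chrom, pos)
        truth = individual.genotype_at(chrom, pos, ref)
        discordant = ((chrom, pos) in forced_discordant
                      or rng.random() < discordance_rate)
        calls[(chrom, pos)] = (ref, ref) if discordant else truth
    return calls


# -- whole-genome trio ------------------------------------------------------


def simulate_wgs_trio(
    models: list[GeneModel],
    reference: dict[str, str],
    grain_genes: list[str],
    rng: np.random.Generator,
    n_background: int = 500,
    n_planted: int = 3,
    n_wt_sites: int = 150,
    n_shared: int = 150,
    depth_mean: float = 30.0,
    low_depth_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Variant tables for two bulked mutant samples and WT, plus the truth.

    Background variants sit on a synthetic off-target contig and split into
    WT-shared sites (subtracted), sites shared by both bulks (removed by
    differencing), and per-bulk private sites with a het/hom VAF mixture and
    occasional sub-threshold depth.  ``n_planted`` homozygous
    function-changing, domain-altering variants are planted in the first
    bulk's grain genes; the returned truth table lists exactly those.
    """
    grain_models = [m for m in models if m.gene_id in grain_genes]
    if len(grain_models) < 1:
        raise ConfigError("no gene model matches the grain gene list")

    bg_chrom = "chrBG"
    bg_positions = rng.choice(10_000_000, size=n_wt_sites + n_shared + n_background,
                              replace=False) + 1
    bg_positions = np.sort(bg_positions)
    cursor = 0

    def bg_rows(n: int, sample: str, vaf_draw, depth_draw) -> list[dict]:
        nonlocal cursor
        rows = []
        for pos in bg_positions[cursor : cursor + n]:
            ref, alt = _draw_alleles(rng, BASES[rng.integers(4)], 0.0)
            rows.append({"sample_id": sample, "chrom": bg_chrom, "pos": int(pos),
                         "ref": ref, "alt": alt, "vaf": vaf_draw(), "depth": depth_draw()})
        cursor += n
        return rows

    def hom_vaf() -> float:
        return float(rng.uniform(0.9, 1.0))

    def mixed_vaf() -> float:
        return float(rng.uniform(0.85, 1.0)) if rng.random() < 0.5 else float(rng.uniform(0.3, 0.7))

    def depth_draw() -> int:
        if rng.random() < low_depth_fraction:
            return int(rng.integers(0, 5))
        return int(rng.poisson(depth_mean)) + 5

    wt_shared = bg_rows(n_wt_sites, "WT", hom_vaf, depth_draw)
    both_shared = bg_rows(n_shared, "shared", mixed_vaf, depth_draw)
    n_m1 = n_background // 2
    m1_private = bg_rows(n_m1, "M1", mixed_vaf, depth_draw)
    m2_private = bg_rows(n_background - n_m1, "M2", mixed_vaf, depth_draw)

    def with_sample(rows: list[dict], sample: str) -> list[dict]:
        return [{**r, "sample_id": sample,
                 "vaf": r["vaf"], "depth": r["depth"]} for r in rows]

    planted = _plant_functional_variants(grain_models, reference, rng, n_planted)
    planted_rows = [{"sample_id": "M1", "chrom": c, "pos": p, "ref": r, "alt": a,
                     "vaf": hom_vaf(), "depth": int(rng.poisson(depth_mean)) + 10}
                    for c, p, r, a in planted]

    m1 = pd.DataFrame(with_sample(wt_shared, "M1") + with_sample(both_shared, "M1")
                      + m1_private + planted_rows)
    m2 = pd.DataFrame(with_sample(wt_shared, "M2") + with_sample(both_shared, "M2")
                      + m2_private)
    wt = pd.DataFrame(wt_shared)
    truth = pd.DataFrame(planted, columns=["chrom", "pos", "ref", "alt"])
    return (m1.sort_values(["chrom", "pos"]).reset_index(drop=True),
            m2.sort_values(["chrom", "pos"]).reset_index(drop=True),
            wt.sort_values(["chrom", "pos"]).reset_index(drop=True),
            truth)


def _plant_functional_variants(
    models: list[GeneModel],
    reference: dict[str, str],
    rng: np.random.Generator,
    n_planted: int,
) -> list[tuple[str, int, str, str]]:
    """Choose variants that are functional and domain-affecting by construction.

    Cycles through missense / stopgain / frameshift-insertion targets inside
    domain-covered codons, verifying each pick with the annotator before
    accepting it.
    """
    wanted = ["nonsynonymous", "stopgain", "frameshift_insertion"]
    picks: list[tuple[str, int, str, str]] = []
    attempts = 0
    while len(picks) < n_planted and attempts < 10_000:
        attempts += 1
        model = models[rng.integers(len(models))]
        if not model.domains:
            continue
        want = wanted[len(picks) % len(wanted)]
        dom = model.domains[rng.integers(len(model.domains))]
        residue = int(rng.integers(dom.residue_start, dom.residue_end + 1))
        cds_pos = model.cds_positions()
        codon_offsets = range((residue - 1) * 3, (residue - 1) * 3 + 3)
        if codon_offsets[-1] >= len(cds_pos):
            continue
        genomic = [cds_pos[o] for o in codon_offsets]
        if want == "frameshift_insertion":
            pos = int(min(genomic))
            ref, alt = "-", BASES[rng.integers(4)]
            cons = classify_variant(model, reference, pos, ref, alt)
        else:
            pos = int(genomic[rng.integers(3)])
            ref = reference_base(reference, model.chrom, pos)
            alt = [b for b in BASES if b != ref][rng.integers(3)]
            cons = classify_variant(model, reference, pos, ref, alt)
        if cons.klass != want or cons.residue is None:
            continue
        if not domain_overlap(cons, model).affects_domain:
            continue
        key = (model.chrom, pos, ref, alt)
        if key not in picks:
            picks.append(key)
    if len(picks) < n_planted:
        raise DataError("could not plant the requested functional variants")
    return picks
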