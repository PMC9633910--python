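"""End-to-end orchestration: simulate → screen → validate → phenotype → WGS cascade.

``run_all`` executes the full workflow against either user-supplied gene
models/reference or the built-in synthetic demo loci, writes every stage's
table before the next stage starts, and finishes with a reproducibility
manifest (config snapshot, versions, seed, per-stage record counts, SHA-256
checksums of every output).  Re-running with the same config and seed
reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as mio
from .datasets import demo_gene_models, demo_wgs_gene_models
from .errors import ConfigError
from .genemodels import GeneModel, read_gene_models
from .phenotypes import PhenotypeRecord, classify_mutants, compare_to_wt, percent_change
from .screen import ScreenParams, compute_vaf, filter_functional, mutation_frequency, screen_site
from .simulate import (EffectTable, SimulationConfig, annotate_individuals,
                       assign_phenotypes, make_pools, simulate_pileup,
                       simulate_population, simulate_sanger, simulate_wgs_trio)
from .validate import CandidateSNP, concordance_rate, deconvolve_pool
from .wgs import CascadeParams, run_cascade

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """One declarative configuration for the whole run."""

    sim: SimulationConfig = Field(default_factory=SimulationConfig)
    delta_threshold: float = 1.0 / 16.0
    het_band: tuple[float, float] = (0.2, 0.8)
    min_depth: int = 5
    min_reads_candidate: int = 50
    alphas: tuple[float, float] = (0.05, 0.01)
    n_control_sites: int = 200
    wgs_n_background: int = 500
    wgs_n_planted: int = 3
    gene_models_path: str | None = None
    reference_path: str | None = None
    seed: int = 0

    def screen_params(self) -> ScreenParams:
        return ScreenParams(self.delta_threshold, self.het_band,
                            self.min_depth, self.min_reads_candidate)


@dataclass
class PipelineResult:
    """In-memory artifacts of one run, mirrored on disk under ``outdir``."""

    manifest: dict
    candidates: pd.DataFrame
    confirmed: pd.DataFrame
    labels: dict[str, tuple[str, ...]]
    cascade_stages: pd.DataFrame
    cascade_candidates: pd.DataFrame
    screen_metrics: dict = dc_field(default_factory=dict)


def _load_targets(config: PipelineConfig) -> tuple[list[GeneModel], dict[str, str]]:
    if (config.gene_models_path is None) != (config.reference_path is None):
        raise ConfigError("gene_models_path and reference_path must be given together")
    if config.gene_models_path:
        return (read_gene_models(config.gene_models_path),
                mio.read_reference(config.reference_path))
    return demo_gene_models()


def run_all(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    params = config.screen_params()
    logger.info(
        "thresholds: delta=%g het_band=%s min_depth=%d min_reads=%d hom_bounds=(0.2,0.8)",
        params.delta_threshold, params.het_band, params.min_depth,
        params.min_reads_candidate,
    )
    counts: dict[str, int] = {}
    models, reference = _load_targets(config)

    # -- stage 1: simulate the mutagenized population and pools -------------
    individuals = simulate_population(config.sim, models, reference, rng)
    annotate_individuals(individuals, models, reference)
    assign_phenotypes(individuals, EffectTable.default_grain_effects(), config.sim, rng)
    pool_set = make_pools(individuals, config.sim.pool_size)
    pool_of = {m: p.pool_id for p in pool_set.pools for m in p.member_ids}
    pools_by_id = {p.pool_id: p for p in pool_set.pools}

    mio.write_reference(reference, out / "reference.fa")
    from .genemodels import write_gene_models
    write_gene_models(models, out / "gene_models.tsv")
    population = mio.population_frame(individuals)
    mio.write_tsv(population, out / "population.tsv")
    mio.write_tsv(mio.pools_frame(pool_set), out / "pools.tsv")
    mio.write_tsv(mio.phenotype_frame(individuals), out / "phenotypes.tsv")
    counts["individuals"] = len(individuals)
    counts["induced_variants"] = int(len(population))
    counts["pools"] = pool_set.n_pools

    # -- stage 2: pooled screen against WT ----------------------------------
    seg_sites = sorted({(v.chrom, v.pos, v.ref)
                        for ind in individuals for v in ind.variants
                        if v.ref != "-"})
    control = _control_sites(models, reference, rng, config.n_control_sites,
                             exclude={(c, p) for c, p, _ in seg_sites})
    sites = seg_sites + control
    truth = {(pool_of[ind.individual_id], v.chrom, v.pos)
             for ind in individuals for v in ind.variants if v.ref != "-"}

    pileups, retained = [], []
    for chrom, pos, ref in sites:
        wt_site = simulate_pileup(pool_set.wt, chrom, pos, ref, config.sim.depth_mean,
                                  config.sim.sequencing_error_rate, rng)
        wt_vaf = compute_vaf(wt_site)
        pileups.append(wt_site)
        for pool in pool_set.pools:
            site = simulate_pileup(pool, chrom, pos, ref, config.sim.depth_mean,
                                   config.sim.sequencing_error_rate, rng)
            pileups.append(site)
            rec = compute_vaf(site)
            result = screen_site(wt_vaf, rec, params)
            if result.retained:
                retained.append((pool.pool_id, rec))
    mio.write_tsv(mio.pileups_frame(pileups), out / "pileups.tsv")
    counts["pileup_sites"] = len(pileups)
    counts["retained_pool_sites"] = len(retained)

    retained_keys = {(pid, r.chrom, r.pos) for pid, r in retained}
    screen_metrics = {
        "n_truth_pool_sites": len(truth),
        "n_retained": len(retained_keys),
        "false_negatives": len(truth - retained_keys),
        "false_positives": len(retained_keys - truth),
    }
    for m in models:
        lo, hi = m.span
        mutated = {p for c, p, _ in seg_sites if c == m.chrom and lo <= p <= hi}
        screen_metrics[f"mutation_frequency_{m.gene_id}"] = mutation_frequency(
            len(mutated), hi - lo + 1)

    candidates = _candidate_table(retained, models, reference, params)
    mio.write_tsv(candidates, out / "candidates.tsv")
    counts["candidate_snps"] = len(candidates)

    # -- stage 3: Sanger deconvolution of candidate pools -------------------
    confirmed_rows = []
    n_confirmed = 0
    for row in candidates.itertuples(index=False):
        pool = pools_by_id[row.pool_id]
        cand = CandidateSNP(row.snp_id, row.pool_id, row.gene, row.chrom,
                            int(row.pos), row.ref, row.alt, row.function_type)
        calls = {}
        for member in pool.members:
            member_calls = simulate_sanger(
                member, [(cand.chrom, cand.pos)], reference,
                config.sim.sanger_discordance_rate, rng)
            calls[(member.individual_id, cand.pos)] = member_calls[(cand.chrom, cand.pos)]
        result = deconvolve_pool(pool.member_ids, cand, calls)
        n_confirmed += result.confirmed
        for carrier in result.carriers:
            confirmed_rows.append({
                "snp_id": cand.snp_id, "pool_id": cand.pool_id,
                "individual_id": carrier.individual_id,
                "genotype": "/".join(carrier.genotype), "gene": cand.gene,
                "chrom": cand.chrom, "pos": cand.pos,
            })
        if not result.confirmed:
            confirmed_rows.append({
                "snp_id": cand.snp_id, "pool_id": cand.pool_id,
                "individual_id": ".", "genotype": ".", "gene": cand.gene,
                "chrom": cand.chrom, "pos": cand.pos,
            })
    confirmed = pd.DataFrame(
        confirmed_rows, columns=["snp_id", "pool_id", "individual_id",
                                 "genotype", "gene", "chrom", "pos"])
    mio.write_tsv(confirmed, out / "confirmed_mutants.tsv")
    counts["confirmed_candidates"] = n_confirmed
    concordance = concordance_rate(n_confirmed, len(candidates)) if len(candidates) else None

    # -- stage 4: phenotype comparison of confirmed mutants -----------------
    by_id = {ind.individual_id: ind for ind in individuals}
    wt_length = config.sim.wt_length_mean + rng.normal(
        0, config.sim.noise_sd_length, config.sim.n_replicates)
    wt_width = config.sim.wt_width_mean + rng.normal(
        0, config.sim.noise_sd_width, config.sim.n_replicates)
    pheno_rows = []
    mutant_ids = sorted({r["individual_id"] for r in confirmed_rows
                         if r["individual_id"] != "."})
    for mid in mutant_ids:
        ind = by_id[mid]
        for trait, reps, wt_reps, wt_mean in (
            ("length", ind.length_replicates, wt_length, config.sim.wt_length_mean),
            ("width", ind.width_replicates, wt_width, config.sim.wt_width_mean),
        ):
            cmp = compare_to_wt(PhenotypeRecord(mid, trait, reps),
                                PhenotypeRecord("WT", trait, wt_reps),
                                alphas=config.alphas)
            pheno_rows.append({
                "line_id": mid, "trait": trait,
                "mutant_mean": float(np.mean(reps)),
                "wt_mean": float(np.mean(wt_reps)),
                "percent_change": percent_change(float(np.mean(reps)), wt_mean),
                "p_value": cmp.p_value, "significance": cmp.significance,
            })
    pheno = pd.DataFrame(pheno_rows, columns=["line_id", "trait", "mutant_mean",
                                              "wt_mean", "percent_change",
                                              "p_value", "significance"])
    labels = classify_mutants(pheno) if len(pheno) else {}
    pheno["labels"] = pheno["line_id"].map(
        lambda l: "+".join(labels.get(l, ("no-change",))))
    mio.write_tsv(pheno, out / "phenotype_comparisons.tsv")
    counts["phenotyped_mutants"] = len(mutant_ids)
    counts["labeled_mutants"] = sum(1 for ls in labels.values() if ls != ("no-change",))

    # -- stage 5: whole-genome differential cascade -------------------------
    wgs_models, wgs_ref = demo_wgs_gene_models()
    grain_genes = [m.gene_id for m in wgs_models]
    m1, m2, wt, wgs_truth = simulate_wgs_trio(
        wgs_models, wgs_ref, grain_genes, rng,
        n_background=config.wgs_n_background, n_planted=config.wgs_n_planted)
    report = run_cascade(m1, m2, wt, wgs_models, grain_genes,
                         reference=wgs_ref, params=CascadeParams(config.min_depth))
    stages = report.to_frame()
    mio.write_tsv(stages, out / "cascade_report.tsv")
    mio.write_tsv(report.candidates, out / "wgs_candidates.tsv")
    counts["wgs_final_candidates"] = len(report.candidates)
    truth_keys = set(map(tuple, wgs_truth[["chrom", "pos", "ref", "alt"]].to_numpy()))
    final_keys = (set(map(tuple, report.candidates[["chrom", "pos", "ref", "alt"]].to_numpy()))
                  if len(report.candidates) else set())
    screen_metrics["wgs_planted_recovered"] = len(truth_keys & final_keys)
    screen_metrics["wgs_planted_total"] = len(truth_keys)

    # -- manifest -----------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "versions": _versions(),
        "counts": counts,
        "concordance_percent": concordance,
        "screen_metrics": screen_metrics,
        "checksums": {name: mio.sha256_of(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(manifest, candidates, confirmed, labels, stages,
                          report.candidates, screen_metrics)


def _control_sites(models, reference, rng, n_control, exclude):
    """Monomorphic positions inside the target intervals, to probe false positives."""
    all_pos = []
    for m in models:
        lo, hi = m.span
        all_pos.extend((m.chrom, p) for p in range(lo, hi + 1)
                       if (m.chrom, p) not in exclude)
    if not all_pos or n_control <= 0:
        return []
    idx = rng.choice(len(all_pos), size=min(n_control, len(all_pos)), replace=False)
    out = []
    for i in sorted(idx):
        chrom, pos = all_pos[i]
        out.append((chrom, pos, reference[chrom][pos - 1].upper()))
    return out


def _candidate_table(retained, models, reference, params) -> pd.DataFrame:
    """Annotate retained pool sites and keep exonic function-changing ones."""
    from .annotate import classify_variant

    rows = []
    model_for = {m.chrom: m for m in models}
    for pool_id, rec in retained:
        model = model_for.get(rec.chrom)
        cons = (classify_variant(model, reference, rec.pos, rec.ref, rec.alt)
                if model is not None and rec.alt is not None else None)
        rows.append({
            "pool_id": pool_id, "gene": model.gene_id if model else "",
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alt if rec.alt else ".",
            "function_type": cons.klass if cons else "intergenic",
            "protein_change": cons.protein_change if cons else "",
            "vaf": rec.vaf, "depth": rec.depth,
        })
    table = pd.DataFrame(rows, columns=["pool_id", "gene", "chrom", "pos", "ref", "alt",
                                        "function_type", "protein_change", "vaf", "depth"])
    if not len(table):
        table["snp_id"] = pd.Series(dtype=str)
        return table
    result = filter_functional(table, params)
    kept = result.table.copy()
    kept.insert(0, "snp_id", [f"SNP-{i + 1}" for i in range(len(kept))])
    return kept


def _versions() -> dict[str, str]:
    import Bio
    import scipy

    from . import __version__

    return {"mtwa": __version__, "numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "biopython": Bio.__version__}
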