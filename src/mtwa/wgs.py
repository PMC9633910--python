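"""Whole-genome differential filtering of two bulked mutant samples against WT.

The cascade takes per-sample variant tables (chrom, pos, ref, alt, VAF,
depth), genotype-calls every site (depth < 5 is treated as missing; VAF ≥ 0.8
or ≤ 0.2 is homozygous, in between heterozygous, boundaries inclusive for
homozygous), removes WT sites, takes the symmetric difference between the two
mutant bulks, and then keeps only homozygous, function-changing,
domain-altering sites in a supplied list of grain genes.  Every stage's
input/output counts are recorded so the monotone shrinkage of the candidate
set is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import (FUNCTIONAL_CLASSES, VariantConsequence, classify_variant,
                       domain_overlap)
from .errors import ConfigError, DataError
from .genemodels import GeneModel

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
WGS_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth"]


@dataclass
class CascadeParams:
    min_depth: int = 5
    hom_low: float = 0.2
    hom_high: float = 0.8
    keep_hom_ref: bool = False  # VAF <= hom_low sites: effectively absent by default

    def __post_init__(self) -> None:
        if not 0.0 <= self.hom_low < self.hom_high <= 1.0:
            raise ConfigError(f"invalid homozygosity bounds ({self.hom_low}, {self.hom_high})")


def call_genotype(vaf: float, depth: int, min_depth: int = 5,
                  hom_low: float = 0.2, hom_high: float = 0.8) -> str:
    """Genotype class of one site: missing / homozygous / heterozygous."""
    if not 0.0 <= vaf <= 1.0:
        raise DataError(f"VAF {vaf} outside [0, 1]")
    if depth < 0:
        raise DataError(f"negative depth {depth}")
    if depth < min_depth:
        return "missing"
    if vaf >= hom_high or vaf <= hom_low:
        return "homozygous"
    return "heterozygous"


def call_genotypes(variants: pd.DataFrame, params: CascadeParams | None = None) -> pd.DataFrame:
    """Vectorised genotype calling; adds/overwrites a ``genotype_class`` column."""
    p = params or CascadeParams()
    vaf = variants["vaf"].to_numpy(dtype=float)
    depth = variants["depth"].to_numpy(dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise DataError("VAF outside [0, 1] in variant table")
    out = variants.copy()
    klass = np.where((vaf >= p.hom_high) | (vaf <= p.hom_low), "homozygous", "heterozygous")
    klass = np.where(depth < p.min_depth, "missing", klass)
    out["genotype_class"] = klass
    return out


def _keys(variants: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(variants[VARIANT_KEY])


def subtract_wt(sample_variants: pd.DataFrame, wt_variants: pd.DataFrame) -> pd.DataFrame:
    """Remove sites present in WT, keyed by (chrom, pos, ref, alt).

    WT sites whose genotype is missing (insufficient depth) do not cause
    subtraction, because the WT state there cannot be asserted.
    """
    if "genotype_class" not in wt_variants.columns:
        raise DataError("WT variants must be genotype-called before subtraction")
    wt_known = wt_variants.loc[wt_variants["genotype_class"] != "missing"]
    n_masked = len(wt_variants) - len(wt_known)
    if n_masked:
        logger.info("subtract_wt: %d WT sites are missing (depth-masked) and "
                    "do not subtract", n_masked)
    keep = ~_keys(sample_variants).isin(_keys(wt_known))
    return sample_variants.loc[keep].reset_index(drop=True)


def differential_sites(m1_variants: pd.DataFrame, m2_variants: pd.DataFrame) -> pd.DataFrame:
    """Symmetric difference of the two bulks' variant keys, tagged by source sample."""
    k1, k2 = _keys(m1_variants), _keys(m2_variants)
    only1 = m1_variants.loc[~k1.isin(k2)]
    only2 = m2_variants.loc[~k2.isin(k1)]
    nonempty = [df for df in (only1, only2) if len(df)]
    out = (pd.concat(nonempty, ignore_index=True) if nonempty
           else m1_variants.iloc[0:0].copy())
    out["source_sample"] = out["sample_id"] if len(out) else pd.Series(dtype=object)
    return out


def annotate_variants(variants: pd.DataFrame, models: list[GeneModel],
                      reference: dict[str, str]) -> pd.DataFrame:
    """Attach gene / function_type / residue / protein_change columns.

    Each site is classified against the gene model whose span contains it;
    sites in no modelled interval are intergenic with an empty gene.
    """
    out = variants.copy()
    genes, klasses, residues, changes = [], [], [], []
    cache: dict[tuple, tuple] = {}
    for row in out.itertuples(index=False):
        key = (row.chrom, row.pos, row.ref, row.alt)
        if key not in cache:
            model = _containing_model(models, row.chrom, int(row.pos))
            if model is None:
                cache[key] = ("", "intergenic", None, "")
            else:
                cons = classify_variant(model, reference, int(row.pos),
                                        str(row.ref), str(row.alt))
                cache[key] = (model.gene_id, cons.klass, cons.residue, cons.protein_change)
        g, k, r, c = cache[key]
        genes.append(g); klasses.append(k); residues.append(r); changes.append(c)
    out["gene"] = genes
    out["function_type"] = klasses
    out["residue"] = residues
    out["protein_change"] = changes
    return out


def _containing_model(models: list[GeneModel], chrom: str, pos: int) -> GeneModel | None:
    for m in models:
        lo, hi = m.span
        if m.chrom == chrom and lo <= pos <= hi:
            return m
    return None


@dataclass
class CascadeReport:
    """Per-stage input/output counts plus the final candidate table."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise DataError(f"cascade stage {name} grew the site set ({n_in} -> {n_out})")
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def run_cascade(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    wt: pd.DataFrame,
    gene_models: list[GeneModel],
    grain_gene_list: list[str],
    reference: dict[str, str] | None = None,
    params: CascadeParams | None = None,
) -> CascadeReport:
    """Run the full differential filtering cascade and report per-stage counts.

    Inputs are raw per-sample variant tables (``WGS_COLUMNS``); annotation
    columns are computed from ``gene_models`` + ``reference`` when absent.
    Stages: genotype calling / missing-site removal, WT subtraction, bulk
    symmetric difference, heterozygous removal, functional-consequence
    filter, grain-gene restriction, protein-domain overlap filter.
    """
    p = params or CascadeParams()
    if not grain_gene_list:
        raise ConfigError("grain_gene_list must not be empty")
    report = CascadeReport()

    m1c, m2c, wtc = (call_genotypes(df, p) for df in (m1, m2, wt))
    n_in = len(m1c) + len(m2c)
    m1c = m1c.loc[m1c["genotype_class"] != "missing"].reset_index(drop=True)
    m2c = m2c.loc[m2c["genotype_class"] != "missing"].reset_index(drop=True)
    report.record("genotype_call_drop_missing", n_in, len(m1c) + len(m2c))

    m1s = subtract_wt(m1c, wtc)
    m2s = subtract_wt(m2c, wtc)
    report.record("subtract_wt", len(m1c) + len(m2c), len(m1s) + len(m2s))

    diff = differential_sites(m1s, m2s)
    report.record("differential_sites", len(m1s) + len(m2s), len(diff))

    hom = diff.loc[diff["genotype_class"] == "homozygous"]
    if not p.keep_hom_ref:
        # VAF <= hom_low means the alternate allele is essentially absent
        hom = hom.loc[hom["vaf"] >= p.hom_high]
    hom = hom.reset_index(drop=True)
    report.record("drop_heterozygous", len(diff), len(hom))

    if "function_type" not in hom.columns:
        if reference is None:
            raise DataError("variants are unannotated and no reference was supplied")
        hom = annotate_variants(hom, gene_models, reference)
    if hom["function_type"].isna().any():
        raise DataError("unannotated sites reached the functional filter")
    func = hom.loc[hom["function_type"].isin(FUNCTIONAL_CLASSES)].reset_index(drop=True)
    report.record("functional_consequence", len(hom), len(func))

    in_genes = func.loc[func["gene"].isin(grain_gene_list)].reset_index(drop=True)
    report.record("grain_gene_restrict", len(func), len(in_genes))

    models_by_gene = {m.gene_id: m for m in gene_models}
    keep_rows = []
    for row in in_genes.itertuples(index=False):
        cons = VariantConsequence(row.function_type, row.protein_change,
                                  int(row.residue))
        hit = domain_overlap(cons, models_by_gene[row.gene])
        keep_rows.append(hit.affects_domain)
    final = in_genes.loc[keep_rows].reset_index(drop=True) if len(in_genes) else in_genes
    report.record("domain_overlap", len(in_genes), len(final))

    report.candidates = final
    logger.info("cascade: %s", " -> ".join(f"{s}:{o}" for s, _, o in report.stages))
    return report
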