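"""Pooled-sample variant screening against a wild-type reference sample.

One heterozygous carrier in an 8-plex equal-mass diploid pool contributes one
of 16 haplotypes, so the expected shift in variant allele frequency (VAF) is
1/16 — the default retention threshold.  A site is retained when the absolute
VAF difference between a pool and the wild-type (WT) sample reaches that
threshold, whether the WT genotype at the site is pure or heterozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
#: candidate classes kept by the functional filter (targeted screen)
SCREEN_KEEP_CLASSES = frozenset({"nonsynonymous", "stopgain"})


@dataclass
class PileupSite:
    """Per-allele read counts for one sample at one genomic position."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise DataError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class VafRecord:
    """Variant allele frequency at one site: the best-supported non-reference allele."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str | None
    vaf: float
    depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise DataError(f"VAF {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.vaf > 0 and self.alt == self.ref:
            raise DataError(f"alt equals ref with positive VAF at {self.chrom}:{self.pos}")


@dataclass
class ScreenParams:
    """Thresholds of the pooled screen.

    delta_threshold : minimum |pool VAF − WT VAF| to retain a site (default 1/16).
    het_band        : WT VAF interval regarded as a heterozygous parent genotype.
    min_depth       : sites below this depth in either sample are reported missing.
    min_reads_candidate : minimum depth for a candidate to count as reliably read.
    """

    delta_threshold: float = 1.0 / 16.0
    het_band: tuple[float, float] = (0.2, 0.8)
    min_depth: int = 5
    min_reads_candidate: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_threshold < 1.0:
            raise ConfigError(f"delta_threshold {self.delta_threshold} outside (0, 1)")
        lo, hi = self.het_band
        if not lo < hi:
            raise ConfigError(f"het_band {self.het_band} must satisfy low < high")


@dataclass(frozen=True)
class ScreenResult:
    retained: bool
    reason: str


def compute_vaf(site: PileupSite) -> VafRecord | None:
    """VAF of the best-supported non-reference allele.

    Returns None ("missing") for a zero-depth site.  Ties between non-ref
    alleles are broken by fixed allele order (A<C<G<T, then indel alleles
    lexicographically) with a logged warning.
    """
    depth = site.depth
    if depth == 0:
        return None
    nonref = {a: c for a, c in site.counts.items() if a != site.ref and c > 0}
    if not nonref:
        return VafRecord(site.sample_id, site.chrom, site.pos, site.ref, None, 0.0, depth)
    best_count = max(nonref.values())
    tied = sorted(a for a, c in nonref.items() if c == best_count)
    if len(tied) > 1:
        # ties at sequencing-noise level (<1% VAF) are routine; real candidate
        # alleles tying is worth a warning
        level = logging.WARNING if best_count / depth >= 0.01 else logging.DEBUG
        logger.log(level, "VAF tie at %s:%d between %s; keeping %s (fixed allele order)",
                   site.chrom, site.pos, tied, tied[0])
    alt = tied[0]
    return VafRecord(site.sample_id, site.chrom, site.pos, site.ref,
                     alt, nonref[alt] / depth, depth)


def screen_site(parent: VafRecord | None, pool: VafRecord | None,
                params: ScreenParams) -> ScreenResult:
    """Retain a pool site when its VAF differs from the parent's by ≥ the threshold.

    The parent (WT) genotype is labelled pure when its VAF falls outside
    ``het_band`` and heterozygous inside it; the same |Δ| ≥ threshold rule
    applies in both cases and the reason string names which rule fired.
    Sub-threshold depth in either sample yields ``missing``, never retention.
    """
    if parent is None or pool is None:
        return ScreenResult(False, "missing: zero-depth site")
    if (parent.chrom, parent.pos) != (pool.chrom, pool.pos):
        raise DataError(
            f"position mismatch: parent {parent.chrom}:{parent.pos} "
            f"vs pool {pool.chrom}:{pool.pos}"
        )
    if parent.depth < params.min_depth or pool.depth < params.min_depth:
        return ScreenResult(False, f"missing: depth below {params.min_depth}")
    lo, hi = params.het_band
    parent_het = lo < parent.vaf < hi
    rule = "het-parent" if parent_het else "pure-parent"
    delta = abs(pool.vaf - parent.vaf)
    if delta >= params.delta_threshold:
        return ScreenResult(True, f"{rule}: |dVAF| = {delta:.4f} >= {params.delta_threshold:.4f}")
    return ScreenResult(False, f"{rule}: |dVAF| = {delta:.4f} < {params.delta_threshold:.4f}")


def mutation_frequency(n_mutated_bases: int, fragment_length: int) -> float:
    """Total mutation frequency of an interval: mutated bases / fragment length."""
    if fragment_length <= 0:
        raise DataError(f"fragment_length must be positive, got {fragment_length}")
    if n_mutated_bases < 0:
        raise DataError("n_mutated_bases cannot be negative")
    return n_mutated_bases / fragment_length


@dataclass
class FunctionalFilterResult:
    """Candidate SNP table restricted to exonic function-changing sites."""

    table: pd.DataFrame
    pools: pd.DataFrame = field(repr=False)

    @property
    def n_pools(self) -> int:
        return len(self.pools)


CANDIDATE_COLUMNS = ["snp_id", "pool_id", "gene", "chrom", "pos", "ref", "alt",
                     "function_type", "depth"]


def filter_functional(candidates: pd.DataFrame, params: ScreenParams) -> FunctionalFilterResult:
    """Keep nonsynonymous/stopgain candidates with reliable read support.

    ``candidates`` needs columns ``pool_id, chrom, pos, ref, alt,
    function_type`` (plus optional ``snp_id, gene, depth``).  Every row must
    be annotated; rows whose depth is unknown (NaN / absent column) are taken
    to be pre-filtered for read support upstream and pass the depth check.
    Output is sorted by (pool, chrom, pos) and accompanied by the per-pool
    grouping of kept SNPs.
    """
    required = {"pool_id", "chrom", "pos", "ref", "alt", "function_type"}
    missing = required - set(candidates.columns)
    if missing:
        raise DataError(f"candidate table lacks columns: {sorted(missing)}")
    if candidates["function_type"].isna().any():
        bad = candidates.loc[candidates["function_type"].isna(), ["chrom", "pos"]]
        raise DataError(f"unannotated candidates at: {bad.to_dict('records')}")
    df = candidates.copy()
    keep = df["function_type"].isin(SCREEN_KEEP_CLASSES)
    if "depth" in df.columns:
        depth_ok = df["depth"].isna() | (df["depth"] >= params.min_reads_candidate)
        keep &= depth_ok
    kept = df.loc[keep].sort_values(["pool_id", "chrom", "pos"]).reset_index(drop=True)
    aggregations = {"n_snps": ("pos", "size")}
    if "gene" in kept.columns:
        aggregations["genes"] = ("gene", lambda g: ",".join(sorted(set(g))))
    pools = kept.groupby("pool_id", sort=True).agg(**aggregations).reset_index()
    logger.info("functional filter: %d of %d candidates kept across %d pools "
                "(min_reads_candidate=%d)", len(kept), len(df), len(pools),
                params.min_reads_candidate)
    return FunctionalFilterResult(kept, pools)
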