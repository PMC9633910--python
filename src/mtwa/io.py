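"""Plain-text readers and writers for every pipeline table.

All tabular interchange is TSV with a header row; sequences are FASTA; the
run manifest is JSON.  VCF input (AD/DP or AF/DP FORMAT fields) is accepted
for whole-genome variant tables alongside the native TSV schema.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .screen import BASES, PileupSite
from .simulate import PoolSet, SimulatedIndividual


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# -- FASTA ------------------------------------------------------------------


def write_reference(reference: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reference(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- simulation tables ------------------------------------------------------


def population_frame(individuals: list[SimulatedIndividual]) -> pd.DataFrame:
    rows = [
        {"individual_id": ind.individual_id, "chrom": v.chrom, "pos": v.pos,
         "ref": v.ref, "alt": v.alt, "zygosity": v.zygosity,
         "genotype": "/".join(v.genotype)}
        for ind in individuals for v in ind.variants
    ]
    return pd.DataFrame(rows, columns=["individual_id", "chrom", "pos", "ref",
                                       "alt", "zygosity", "genotype"])


def pools_frame(pool_set: PoolSet) -> pd.DataFrame:
    rows = [
        {"pool_id": pool.pool_id, "member_index": i + 1, "individual_id": m}
        for pool in pool_set.pools for i, m in enumerate(pool.member_ids)
    ]
    return pd.DataFrame(rows, columns=["pool_id", "member_index", "individual_id"])


def phenotype_frame(individuals: list[SimulatedIndividual]) -> pd.DataFrame:
    rows = []
    for ind in individuals:
        if ind.length_replicates is None:
            raise DataError(f"{ind.individual_id} has no phenotypes assigned")
        for r, (ln, wd) in enumerate(zip(ind.length_replicates, ind.width_replicates), 1):
            rows.append({"line_id": ind.individual_id, "replicate": r,
                         "length_mm": round(float(ln), 4), "width_mm": round(float(wd), 4)})
    return pd.DataFrame(rows, columns=["line_id", "replicate", "length_mm", "width_mm"])


PILEUP_COLUMNS = ["sample_id", "chrom", "pos", "ref", "A", "C", "G", "T",
                  "indel", "indel_allele", "depth"]


def pileups_frame(sites: list[PileupSite]) -> pd.DataFrame:
    """One row per sample/site; the best-supported indel allele is kept by name."""
    rows = []
    for s in sites:
        indels = {a: c for a, c in s.counts.items() if a not in BASES and c > 0}
        indel_allele = max(sorted(indels), key=indels.get) if indels else "."
        rows.append({
            "sample_id": s.sample_id, "chrom": s.chrom, "pos": s.pos, "ref": s.ref,
            **{b: s.counts.get(b, 0) for b in BASES},
            "indel": sum(indels.values()), "indel_allele": indel_allele,
            "depth": s.depth,
        })
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def read_pileups(path: str | Path) -> list[PileupSite]:
    df = pd.read_csv(path, sep="\t", dtype={"indel_allele": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"pileup table lacks columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        counts = {b: int(getattr(row, b)) for b in BASES}
        if row.indel and row.indel_allele != ".":
            counts[str(row.indel_allele)] = int(row.indel)
        sites.append(PileupSite(row.sample_id, row.chrom, int(row.pos), row.ref, counts))
    return sites


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- whole-genome variant tables -------------------------------------------


def read_wgs_variants(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a per-sample variant table from native TSV or VCF.

    TSV needs columns ``sample_id, chrom, pos, ref, alt, vaf, depth``.  For
    VCF, VAF comes from the AF FORMAT field or is computed as alt AD / DP;
    indels are normalised to the dash convention used throughout.
    """
    p = Path(path)
    if p.suffix.lower() == ".vcf" or p.name.endswith(".vcf.gz"):
        return _read_vcf(p, sample_id)
    df = pd.read_csv(p, sep="\t")
    required = {"sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"variant table {p} lacks columns: {sorted(missing)}")
    return df


def _normalise_vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """VCF anchored indels -> dash convention (1-based, insertion after pos)."""
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    if len(ref) < len(alt) and alt.startswith(ref):
        return pos + len(ref) - 1, "-", alt[len(ref):]
    if len(ref) > len(alt) and ref.startswith(alt):
        return pos + len(alt), ref[len(alt):], "-"
    raise DataError(f"cannot normalise VCF alleles {ref}>{alt} at position {pos}")


def _read_vcf(path: Path, sample_id: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.samples:
        raise DataError(f"{path}: VCF has no sample columns")
    if sample_id is None:
        sample_id = vcf.samples[0]
    try:
        si = vcf.samples.index(sample_id)
    except ValueError:
        raise DataError(f"{path}: sample {sample_id!r} not in VCF ({vcf.samples})")
    def fmt(rec, tag):
        try:
            return rec.format(tag)
        except KeyError:  # tag absent from the header
            return None

    rows = []
    for rec in vcf:
        if not rec.ALT:
            continue
        depths = fmt(rec, "DP")
        depth = int(depths[si][0]) if depths is not None else 0
        afs = fmt(rec, "AF")
        if afs is not None:
            vaf = float(afs[si][0])
        else:
            ad = fmt(rec, "AD")
            if ad is None:
                raise DataError(f"{path}: neither AF nor AD FORMAT present")
            alt_reads = int(ad[si][1])
            vaf = alt_reads / depth if depth else 0.0
        pos, ref, alt = _normalise_vcf_alleles(rec.POS, rec.REF, rec.ALT[0])
        rows.append({"sample_id": sample_id, "chrom": rec.CHROM, "pos": pos,
                     "ref": ref, "alt": alt, "vaf": min(max(vaf, 0.0), 1.0),
                     "depth": depth})
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                       "alt", "vaf", "depth"])
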