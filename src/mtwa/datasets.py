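"""Built-in example data: published screening tables and synthetic demo loci.

Two kinds of objects live here.  First, the worked-example tables from the
rice GS3/GW5 grain-shape screen (the 15-SNP targeted-sequencing candidate
table, the per-mutant grain phenotypes with significance flags, and the
whole-genome candidate variants), typed exactly as the pipeline's own
outputs, so every downstream operation can be demonstrated on real numbers.
Second, deterministic *synthetic* gene models and reference sequences for
demonstration and simulation: their exon/intron layout, domain residue
ranges and sequences are constructed stand-ins (seeded, reproducible), not
the real rice loci — the real reference genome is not bundled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genemodels import GeneModel, Interval, ProteinDomain

WT_GRAIN_LENGTH_MM = 9.31
WT_GRAIN_WIDTH_MM = 2.03

#: grain genes named by the whole-genome candidate table
GRAIN_GENES = ["Os02g0614100", "Os06g0154500", "Os08g0485500"]

#: candidates not confirmed by per-individual Sanger genotyping
EXCLUDED_SNP_IDS = ("SNP-5", "SNP-6")

_CANDIDATE_ROWS = [
    ("SNP-1", "4-101", "GS3", "chr3", 16732992, "G", "C", "nonsynonymous"),
    ("SNP-2", "4-101", "GS3", "chr3", 16734441, "G", "T", "stopgain"),
    ("SNP-3", "5-6", "GS3", "chr3", 16734009, "G", "C", "nonsynonymous"),
    ("SNP-4", "6-23", "GS3", "chr3", 16731920, "C", "A", "nonsynonymous"),
    ("SNP-5", "6-44", "GS3", "chr3", 16729753, "A", "T", "nonsynonymous"),
    ("SNP-6", "6-44", "GS3", "chr3", 16729861, "G", "T", "nonsynonymous"),
    ("SNP-7", "7-112", "GS3", "chr3", 16735064, "G", "C", "nonsynonymous"),
    ("SNP-8", "7-41", "GS3", "chr3", 16729815, "C", "T", "nonsynonymous"),
    ("SNP-9", "7-78", "GS3", "chr3", 16729903, "G", "A", "nonsynonymous"),
    ("SNP-10", "7-78", "GS3", "chr3", 16729863, "C", "A", "nonsynonymous"),
    ("SNP-11", "9-5", "GS3", "chr3", 16729886, "C", "A", "nonsynonymous"),
    ("SNP-12", "5-35", "GW5", "chr5", 5365411, "A", "G", "nonsynonymous"),
    ("SNP-13", "7-82", "GW5", "chr5", 5366479, "C", "G", "nonsynonymous"),
    ("SNP-14", "10-14", "GW5", "chr5", 5366520, "T", "G", "nonsynonymous"),
    ("SNP-15", "10-51", "GW5", "chr5", 5366501, "A", "G", "nonsynonymous"),
]


def candidate_snps() -> pd.DataFrame:
    """The 15 exonic function-changing candidates from the targeted screen.

    Columns match the pipeline's candidate-table schema; read depth is not
    part of the published table (candidates were read-filtered upstream), so
    the ``depth`` column is NaN.
    """
    df = pd.DataFrame(
        _CANDIDATE_ROWS,
        columns=["snp_id", "pool_id", "gene", "chrom", "pos", "ref", "alt", "function_type"],
    )
    df["depth"] = np.nan
    return df


_PHENOTYPE_ROWS = [
    # line, plant, protein change, length mm, width mm, length sig, width sig
    ("GS3-1", "7-112-2-4", "A5G", 9.21, 2.12, "ns", "ns"),
    ("GS3-2", "4-101-1-3", "C55X", 10.22, 2.03, "**", "ns"),
    ("GS3-3", "5-6-1-4", "C135W", 8.06, 2.04, "**", "ns"),
    ("GS3-4", "4-101-2-2", "S141C", 9.41, 2.17, "ns", "ns"),
    ("GS3-5", "6-23-1-4", "C173F", 8.51, 1.90, "**", "ns"),
    ("GS3-6", "7-78-1-3", "G167C", 9.33, 1.94, "ns", "ns"),
    ("GS3-7", "9-5-1-1", "C190F", 9.97, 1.86, "**", "ns"),
    ("GS3-8", "7-78-2-3", "S184F", 9.33, 2.09, "ns", "ns"),
    ("GS3-9", "7-41-1-4", "R200H", 9.30, 1.90, "ns", "ns"),
    ("GW5-1", "5-35-1-2", "V411G", 9.53, 2.29, "ns", "**"),
    ("GW5-2", "7-82-1-4", "A405G", 9.42, 2.02, "ns", "ns"),
    ("GW5-3", "10-14-2-1", "K397E", 9.46, 2.03, "ns", "ns"),
    ("GW5-4", "10-51-2-3", "D97G", 9.40, 1.84, "ns", "**"),
]


def mutant_phenotypes() -> pd.DataFrame:
    """Grain length/width means and significance flags of the 13 confirmed mutants."""
    return pd.DataFrame(
        _PHENOTYPE_ROWS,
        columns=["line_id", "plant_id", "protein_change",
                 "length_mm", "width_mm", "length_sig", "width_sig"],
    )


def wgs_new_variants() -> pd.DataFrame:
    """New allelic variants recovered by the whole-genome differential cascade."""
    rows = [
        ("GS3-G1", "chr2", 24236917, "C", "T", "Os02g0614100", "nonsynonymous"),
        ("GS3-G2", "chr6", 2812755, "T", "C", "Os06g0154500", "nonsynonymous"),
        ("GS3-G3", "chr8", 23999540, "-", "C", "Os08g0485500", "frameshift_insertion"),
    ]
    return pd.DataFrame(
        rows, columns=["number", "chrom", "pos", "ref", "alt", "gene", "function_type"]
    )


def trait_survey() -> pd.DataFrame:
    """Population-wide grain-shape survey (3872 M2 plants)."""
    rows = [
        ("length", 8.00, 10.22, 9.28, 0.18, 1.89),
        ("width", 1.54, 2.87, 2.02, 0.01, 0.56),
    ]
    return pd.DataFrame(rows, columns=["trait", "min", "max", "mean", "sd", "cv_percent"])


# -- synthetic demo loci ----------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_COMPL = str.maketrans("ACGT", "TGCA")


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    codons = ["ATG"]
    bases = np.array(list("ACGT"))
    while len(codons) < n_aa:
        codon = "".join(bases[rng.integers(0, 4, size=3)])
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    n_aa: int,
    domains: list[ProteinDomain],
    cds_split: list[int],
    intron_lengths: list[int],
    utr5: int = 60,
    utr3: int = 60,
    gene_start: int = 1001,
) -> tuple[GeneModel, str]:
    """Construct one synthetic locus and its chromosome sequence.

    ``cds_split`` gives per-exon coding lengths (must sum to 3*(n_aa+1));
    the 5' UTR sits in the first transcribed exon and the 3' UTR in the last.
    Works for both strands: coding bases are written into the genome so that
    reading the CDS intervals in transcription order yields the CDS.
    """
    cds_len = 3 * (n_aa + 1)
    if sum(cds_split) != cds_len or len(intron_lengths) != len(cds_split) - 1:
        raise ValueError("inconsistent exon/intron layout")
    cds = _random_cds(rng, n_aa)

    # lay out exons left-to-right in transcription order, then mirror for '-'
    tx_exons: list[Interval] = []
    tx_cds: list[Interval] = []
    cursor = gene_start
    for i, clen in enumerate(cds_split):
        lead = utr5 if i == 0 else 0
        tail = utr3 if i == len(cds_split) - 1 else 0
        exon = (cursor, cursor + lead + clen + tail - 1)
        tx_exons.append(exon)
        tx_cds.append((cursor + lead, cursor + lead + clen - 1))
        cursor = exon[1] + 1
        if i < len(intron_lengths):
            cursor += intron_lengths[i]
    gene_end = tx_exons[-1][1]

    if strand == "-":
        # mirror coordinates so exon 1 (transcription order) is rightmost
        def mirror(iv: Interval) -> Interval:
            a, b = iv
            return gene_start + gene_end - b, gene_start + gene_end - a

        tx_exons = [mirror(iv) for iv in reversed(tx_exons)]
        tx_cds = [mirror(iv) for iv in reversed(tx_cds)]

    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                      exons=tx_exons, cds=tx_cds, domains=domains)

    chrom_len = gene_end + 500
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=chrom_len)]))
    tpos = model.cds_positions()
    assert len(tpos) == cds_len
    for i, p in enumerate(tpos):
        seq[p - 1] = cds[i] if strand == "+" else cds[i].translate(_COMPL)
    return model, "".join(seq)


def demo_gene_models(seed: int = 0) -> tuple[list[GeneModel], dict[str, str]]:
    """Synthetic stand-ins for the two targeted grain-shape loci.

    A 232-residue, 5-exon plus-strand gene with OSR, TNFR/NGFR and VWFC
    domains (so a stop at residue 55 truncates away every domain, residue 5
    precedes them all, and residues 135/141 and 167–200 fall in the second
    and third domains), and a 420-residue, 2-exon minus-strand gene with a
    C-terminal calmodulin-binding domain.  Domain residue ranges and all
    sequence are synthetic; only the residue-placement logic mirrors the
    published loci.
    """
    rng = np.random.default_rng(seed)
    gs3, chr3 = _build_gene(
        rng, "GS3", "chr3", "+", n_aa=232,
        domains=[ProteinDomain("OSR", 10, 90),
                 ProteinDomain("TNFR/NGFR", 110, 145),
                 ProteinDomain("VWFC", 160, 220)],
        cds_split=[100, 110, 160, 180, 149],
        intron_lengths=[1200, 1800, 900, 600],
    )
    gw5, chr5 = _build_gene(
        rng, "GW5", "chr5", "-", n_aa=420,
        domains=[ProteinDomain("calmodulin-binding", 380, 420)],
        cds_split=[700, 563],
        intron_lengths=[2000],
    )
    return [gs3, gw5], {"chr3": chr3, "chr5": chr5}


def demo_wgs_gene_models(seed: int = 1) -> tuple[list[GeneModel], dict[str, str]]:
    """Synthetic stand-ins for the three grain genes of the WGS candidate list."""
    rng = np.random.default_rng(seed)
    models, reference = [], {}
    layouts = [
        ("Os02g0614100", "chr2", "+", 300, [ProteinDomain("glycosyltransferase", 40, 260)],
         [400, 503], [900]),
        ("Os06g0154500", "chr6", "-", 250, [ProteinDomain("kinase", 30, 220)],
         [353, 400], [700]),
        ("Os08g0485500", "chr8", "+", 120, [ProteinDomain("cysteine-rich", 60, 115)],
         [163, 200], [500]),
    ]
    for gene_id, chrom, strand, n_aa, domains, split, introns in layouts:
        model, seq = _build_gene(rng, gene_id, chrom, strand, n_aa, domains, split, introns)
        models.append(model)
        reference[chrom] = seq
    return models, reference
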