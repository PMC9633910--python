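"""Shared fixtures: toy loci and an independent brute-force consequence oracle.

The oracle translates with its own codon dictionary and classifies by direct
protein comparison, so it shares no code path with the package's annotator.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mtwa.datasets import _build_gene
from mtwa.genemodels import GeneModel, ProteinDomain

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# standard genetic code, written out so the oracle is independent of Biopython
_B = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AA[16 * i + 4 * j + k]
               for i, a in enumerate(_B)
               for j, b in enumerate(_B)
               for k, c in enumerate(_B)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def oracle_classify_snv(model: GeneModel, reference: dict[str, str],
                        pos: int, alt: str) -> tuple[str, int | None]:
    """Brute-force SNV classification: direct interval scans + full translation."""
    lo, hi = model.span
    if not lo <= pos <= hi:
        return "intergenic", None
    in_exon = any(a <= pos <= b for a, b in model.exons)
    in_cds = any(a <= pos <= b for a, b in model.cds)
    if not in_exon:
        return "intronic", None
    if not in_cds:
        return "utr", None
    # rebuild the spliced CDS directly from the (mutated) chromosome
    chrom = list(reference[model.chrom].upper())
    ref_cds = _splice(model, chrom)
    chrom[pos - 1] = alt
    mut_cds = _splice(model, chrom)
    ref_prot, mut_prot = oracle_translate(ref_cds), oracle_translate(mut_cds)
    diffs = [i for i, (r, m) in enumerate(zip(ref_prot, mut_prot)) if r != m]
    # codon index of the edited base, independent of whether the aa changed
    order = [p for a, b in model.cds for p in range(a, b + 1)]
    if model.strand == "-":
        order = order[::-1]
    k = order.index(pos) // 3 + 1
    if not diffs:
        return "synonymous", k
    i = diffs[0]
    if mut_prot[i] == "*":
        return "stopgain", k
    if ref_prot[i] == "*":
        return "stoploss", k
    return "nonsynonymous", k


def _splice(model: GeneModel, chrom: list[str]) -> str:
    seq = "".join("".join(chrom[a - 1 : b]) for a, b in model.cds)
    if model.strand == "-":
        seq = "".join(COMPLEMENT[c] for c in reversed(seq))
    return seq


@pytest.fixture(scope="session")
def toy_plus():
    """Small plus-strand gene (60 aa, 183-bp CDS, two exons, three domains)."""
    rng = np.random.default_rng(11)
    model, seq = _build_gene(
        rng, "TOY", "chrT", "+", n_aa=60,
        domains=[ProteinDomain("D1", 10, 20),
                 ProteinDomain("D2", 25, 40),
                 ProteinDomain("D3", 45, 58)],
        cds_split=[90, 93], intron_lengths=[70],
        utr5=40, utr3=40,
    )
    return model, {"chrT": seq}


@pytest.fixture(scope="session")
def toy_minus():
    """Same layout on the minus strand."""
    rng = np.random.default_rng(13)
    model, seq = _build_gene(
        rng, "YOT", "chrY", "-", n_aa=60,
        domains=[ProteinDomain("D1", 10, 20),
                 ProteinDomain("D2", 25, 40),
                 ProteinDomain("D3", 45, 58)],
        cds_split=[90, 93], intron_lengths=[70],
        utr5=40, utr3=40,
    )
    return model, {"chrY": seq}


@pytest.fixture(scope="session")
def demo_targets():
    from mtwa.datasets import demo_gene_models

    return demo_gene_models()
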