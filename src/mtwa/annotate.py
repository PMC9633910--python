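"""Variant consequence annotation: transcript location, coding effect, domains.

Variant alleles follow the dash convention used in published rice mutation
tables: an SNV has single-base ``ref`` and ``alt``; an insertion has
``ref == '-'`` and the inserted bases as ``alt``, placed immediately *after*
``pos``; a deletion has the deleted bases as ``ref`` starting at ``pos`` and
``alt == '-'``.

Coding consequences are derived by rebuilding and translating the full mutant
coding sequence against the reference one, so premature stops introduced
anywhere downstream of the edited codon are detected, not just in-codon
changes.  Protein changes use single-letter refPosAlt notation with ``X`` for
a stop codon (e.g. ``C55X``), and ``fs``/``ins``/``del`` suffixes for indels
(e.g. ``S99fs``).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import DataError
from .genemodels import GeneModel, revcomp

logger = logging.getLogger(__name__)

CODING_CLASSES = frozenset({
    "synonymous", "nonsynonymous", "stopgain", "stoploss",
    "frameshift_insertion", "frameshift_deletion",
    "nonframeshift_insertion", "nonframeshift_deletion",
})
#: consequence classes that truncate or shift everything downstream
TRUNCATING_CLASSES = frozenset({"stopgain", "frameshift_insertion", "frameshift_deletion"})
#: classes retained as potentially function-changing in downstream filters
FUNCTIONAL_CLASSES = frozenset({
    "nonsynonymous", "stopgain", "frameshift_insertion", "frameshift_deletion",
    "nonframeshift_insertion", "nonframeshift_deletion",
})


@dataclass(frozen=True)
class VariantConsequence:
    """Predicted effect of one variant on one gene model."""

    klass: str
    protein_change: str = ""
    residue: int | None = None

    def __post_init__(self) -> None:
        coding = self.klass in CODING_CLASSES
        if coding and not self.protein_change:
            raise DataError(f"coding consequence {self.klass} requires a protein change")
        if not coding and self.protein_change:
            raise DataError(f"non-coding consequence {self.klass} cannot carry a protein change")

    @property
    def is_coding(self) -> bool:
        return self.klass in CODING_CLASSES

    @property
    def is_functional(self) -> bool:
        return self.klass in FUNCTIONAL_CLASSES


@dataclass(frozen=True)
class DomainHit:
    """Outcome of mapping an affected residue onto the protein's domains.

    ``domain`` is the domain containing the residue (or None); ``lost`` lists
    every domain at or downstream of the residue when the consequence
    truncates the protein (stopgain / frameshift), since those domains are
    removed or scrambled in the product.
    """

    domain: str | None
    lost: tuple[str, ...] = ()

    @property
    def affects_domain(self) -> bool:
        return self.domain is not None or bool(self.lost)


def locate_variant(model: GeneModel, position: int) -> str:
    """Label a position as ``exon k`` / ``intron k`` (transcription order) or ``outside``."""
    if position < 1:
        raise DataError(f"position must be a positive 1-based coordinate, got {position}")
    k = model.exon_index(position)
    if k is not None:
        return f"exon {k}"
    k = model.intron_index(position)
    if k is not None:
        return f"intron {k}"
    return "outside"


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def classify_variant(
    model: GeneModel,
    reference: dict[str, str],
    position: int,
    ref_allele: str,
    alt_allele: str,
) -> VariantConsequence:
    """Classify one variant against one gene model.

    A position outside the model span is ``intergenic`` (not an error); a
    reference-allele mismatch is a :class:`DataError` naming the position.
    """
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    chrom_seq = reference.get(model.chrom)
    if chrom_seq is None:
        raise DataError(f"chromosome {model.chrom!r} not in reference")
    is_insertion = ref_allele == "-"
    is_deletion = alt_allele == "-"

    if not is_insertion:
        have = chrom_seq[position - 1 : position - 1 + len(ref_allele)].upper()
        if have != ref_allele:
            raise DataError(
                f"reference mismatch at {model.chrom}:{position}: "
                f"expected {ref_allele!r}, reference has {have!r}"
            )

    lo, hi = model.span
    if position < lo or position > hi:
        return VariantConsequence("intergenic")

    cds_pos = model.cds_positions()  # transcription order
    offset_of = {p: i for i, p in enumerate(cds_pos)}

    if is_insertion:
        return _classify_insertion(model, chrom_seq, position, alt_allele, offset_of)
    if is_deletion:
        return _classify_deletion(model, chrom_seq, position, ref_allele, offset_of)
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise DataError(
            f"multi-base substitution at {model.chrom}:{position} is not supported; "
            "use dash-convention indels"
        )
    return _classify_snv(model, reference, position, alt_allele, offset_of)


def _noncoding_label(model: GeneModel, position: int) -> VariantConsequence:
    if model.exon_index(position) is not None:
        return VariantConsequence("utr")
    if model.intron_index(position) is not None:
        return VariantConsequence("intronic")
    return VariantConsequence("intergenic")


def _classify_snv(model, reference, position, alt, offset_of) -> VariantConsequence:
    if position not in offset_of:
        return _noncoding_label(model, position)
    offset = offset_of[position]
    ref_cds = model.cds_sequence(reference)
    alt_base = revcomp(alt) if model.strand == "-" else alt
    mut_cds = ref_cds[:offset] + alt_base + ref_cds[offset + 1 :]
    k = offset // 3 + 1  # codon number of the edited base
    ref_aa = _translate(ref_cds)[k - 1]
    mut_aa = _translate(mut_cds)[k - 1]
    if mut_aa == ref_aa:
        return VariantConsequence("synonymous", f"{ref_aa}{k}{ref_aa}", k)
    if mut_aa == "*":
        return VariantConsequence("stopgain", f"{ref_aa}{k}X", k)
    if ref_aa == "*":
        return VariantConsequence("stoploss", f"X{k}{mut_aa}", k)
    return VariantConsequence("nonsynonymous", f"{ref_aa}{k}{mut_aa}", k)


def _classify_insertion(model, chrom_seq, position, alt, offset_of) -> VariantConsequence:
    # inserted between `position` and `position + 1`; coding only if both flanks are
    if position not in offset_of or position + 1 not in offset_of:
        return _noncoding_label(model, position)
    offset = min(offset_of[position], offset_of[position + 1])
    residue = offset // 3 + 1
    ref_aa = _aa_at(model, chrom_seq, residue)
    if len(alt) % 3:
        return VariantConsequence("frameshift_insertion", f"{ref_aa}{residue}fs", residue)
    return VariantConsequence("nonframeshift_insertion", f"{ref_aa}{residue}ins", residue)


def _classify_deletion(model, chrom_seq, position, ref, offset_of) -> VariantConsequence:
    deleted = [offset_of[p] for p in range(position, position + len(ref)) if p in offset_of]
    if not deleted:
        return _noncoding_label(model, position)
    offset = min(deleted)
    residue = offset // 3 + 1
    ref_aa = _aa_at(model, chrom_seq, residue)
    if len(deleted) % 3:
        return VariantConsequence("frameshift_deletion", f"{ref_aa}{residue}fs", residue)
    return VariantConsequence("nonframeshift_deletion", f"{ref_aa}{residue}del", residue)


def _aa_at(model: GeneModel, chrom_seq: str, residue: int) -> str:
    prot = model.translate({model.chrom: chrom_seq})
    return prot[residue - 1] if residue <= len(prot) else "X"


def domain_overlap(consequence: VariantConsequence, model: GeneModel) -> DomainHit:
    """Map a coding consequence onto the model's protein domains.

    Missense and in-frame changes affect only the domain containing the
    residue; truncating changes additionally lose every domain at or
    downstream of the residue.
    """
    if not consequence.is_coding or consequence.residue is None:
        raise DataError("domain_overlap requires a coding consequence with a residue")
    residue = consequence.residue
    containing = next((d.name for d in model.domains if d.contains(residue)), None)
    lost: tuple[str, ...] = ()
    if consequence.klass in TRUNCATING_CLASSES:
        lost = tuple(d.name for d in model.domains if d.residue_end >= residue)
    return DomainHit(containing, lost)


def summarize_locations(locations: list[str]) -> pd.DataFrame:
    """Count and percentage per region class from ``locate_variant`` labels.

    ``exon k`` / ``intron k`` labels collapse to ``exon`` / ``intron``.
    Percentages are rounded to 2 decimals at reporting only.
    """
    if not locations:
        raise DataError("summarize_locations: empty location list")
    collapsed = [lab.split(" ")[0] for lab in locations]
    counts = Counter(collapsed)
    total = len(collapsed)
    rows = [
        {"region": region, "count": n, "percent": round(100.0 * n / total, 2)}
        for region, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["region", "count", "percent"])
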