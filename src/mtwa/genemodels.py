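"""Gene models: strand-aware exon/CDS structures with protein-domain annotations.

Coordinates are 1-based inclusive genomic intervals throughout, matching the
convention of published rice variant tables.  Exon and intron indices are
counted in transcription order, so on a minus-strand gene exon 1 is the exon
with the highest genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .errors import ConfigError, DataError

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProteinDomain:
    """A named conserved region of the protein, in 1-based residue coordinates."""

    name: str
    residue_start: int
    residue_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.residue_start <= self.residue_end:
            raise ConfigError(
                f"domain {self.name}: invalid residue interval "
                f"[{self.residue_start}, {self.residue_end}]"
            )

    def contains(self, residue: int) -> bool:
        return self.residue_start <= residue <= self.residue_end


@dataclass
class GeneModel:
    """Exon/CDS structure of one locus plus protein-domain residue ranges.

    ``exons`` and ``cds`` are sorted, non-overlapping, 1-based inclusive
    genomic intervals; every CDS interval must lie within an exon.  ``strand``
    is ``'+'`` or ``'-'``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    domains: list[ProteinDomain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ConfigError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ConfigError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        prev_end = 0
        for a, b in self.exons:
            if a <= prev_end:
                raise ConfigError(f"{self.gene_id}: exons overlap or are unsorted")
            if a > b:
                raise ConfigError(f"{self.gene_id}: exon interval ({a}, {b}) reversed")
            prev_end = b
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ConfigError(
                    f"{self.gene_id}: CDS interval ({a}, {b}) not contained in an exon"
                )

    # -- coordinate helpers -------------------------------------------------

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_index(self, position: int) -> int | None:
        """1-based exon number in transcription order, or None if intronic/outside."""
        for i, (a, b) in enumerate(self.exons):
            if a <= position <= b:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def intron_index(self, position: int) -> int | None:
        """1-based intron number in transcription order, or None."""
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] < position < self.exons[i + 1][0]:
                return i + 1 if self.strand == "+" else len(self.exons) - 1 - i
        return None

    def in_cds(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.cds)

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases in transcription order."""
        pos = [p for a, b in self.cds for p in range(a, b + 1)]
        return pos if self.strand == "+" else pos[::-1]

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def protein_length(self) -> int:
        """Residue count excluding the stop codon."""
        return self.cds_length // 3 - 1

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced coding sequence (5'→3' of the transcript)."""
        chrom_seq = self._chrom_seq(reference)
        parts = [chrom_seq[a - 1 : b] for a, b in self.cds]
        seq = "".join(parts).upper()
        return revcomp(seq) if self.strand == "-" else seq

    def _chrom_seq(self, reference: dict[str, str]) -> str:
        try:
            chrom_seq = reference[self.chrom]
        except KeyError:
            raise ConfigError(f"{self.gene_id}: chromosome {self.chrom!r} not in reference")
        if self.span[1] > len(chrom_seq):
            raise ConfigError(
                f"{self.gene_id}: interval {self.span} extends past the end of "
                f"{self.chrom} (length {len(chrom_seq)})"
            )
        return chrom_seq

    def translate(self, reference: dict[str, str]) -> str:
        cds = self.cds_sequence(reference)
        return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def reference_base(reference: dict[str, str], chrom: str, position: int) -> str:
    try:
        seq = reference[chrom]
    except KeyError:
        raise DataError(f"chromosome {chrom!r} not in reference")
    if not 1 <= position <= len(seq):
        raise DataError(f"position {chrom}:{position} outside reference")
    return seq[position - 1].upper()


# -- tabular round trip -----------------------------------------------------

_HEADER = "gene_id\tchrom\tstrand\tfeature\tstart\tend\tname"


def write_gene_models(models: list[GeneModel], path: str | Path) -> None:
    """Write models as a BED-like 1-based inclusive TSV (one feature per row)."""
    lines = [_HEADER]
    for m in models:
        for a, b in m.exons:
            lines.append(f"{m.gene_id}\t{m.chrom}\t{m.strand}\texon\t{a}\t{b}\t.")
        for a, b in m.cds:
            lines.append(f"{m.gene_id}\t{m.chrom}\t{m.strand}\tcds\t{a}\t{b}\t.")
        for d in m.domains:
            lines.append(
                f"{m.gene_id}\t{m.chrom}\t{m.strand}\tdomain\t"
                f"{d.residue_start}\t{d.residue_end}\t{d.name}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    raw: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise DataError(f"unexpected gene-model header in {path}: {header!r}")
        for line in fh:
            gene_id, chrom, strand, feature, start, end, name = line.rstrip("\n").split("\t")
            rec = raw.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "exons": [], "cds": [], "domains": []},
            )
            if feature == "exon":
                rec["exons"].append((int(start), int(end)))
            elif feature == "cds":
                rec["cds"].append((int(start), int(end)))
            elif feature == "domain":
                rec["domains"].append(ProteinDomain(name, int(start), int(end)))
            else:
                raise DataError(f"unknown gene-model feature {feature!r}")
    return [
        GeneModel(gene_id=g, chrom=r["chrom"], strand=r["strand"],
                  exons=r["exons"], cds=r["cds"], domains=r["domains"])
        for g, r in raw.items()
    ]
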