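"""Pool deconvolution by per-individual Sanger-style genotyping.

A candidate site found in a pooled library only localises the mutation to the
8 member plants; genotyping each member individually identifies the carrier.
A candidate with no carrier among the members is a non-confirmation (a
targeted-sequencing artifact), and the fraction of candidates confirmed is
the targeted-vs-Sanger concordance rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import DataError

logger = logging.getLogger(__name__)

GenotypeCall = tuple[str, str]


@dataclass(frozen=True)
class CandidateSNP:
    snp_id: str
    pool_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    function_type: str


@dataclass(frozen=True)
class ConfirmedMutant:
    snp_id: str
    individual_id: str
    genotype: GenotypeCall
    confirmed: bool


@dataclass
class DeconvolutionResult:
    candidate: CandidateSNP
    carriers: list[ConfirmedMutant]

    @property
    def confirmed(self) -> bool:
        return bool(self.carriers)


def deconvolve_pool(
    members: list[str],
    candidate: CandidateSNP,
    sanger_calls: dict[tuple[str, int], GenotypeCall],
) -> DeconvolutionResult:
    """Identify which pool member(s) carry the candidate's alternate allele.

    ``sanger_calls`` maps (individual_id, position) to a diploid call.  Every
    member must be called at the candidate position; zero carriers is a valid
    non-confirmation, more than one carrier is reported in full with a
    warning.
    """
    uncalled = [m for m in members if (m, candidate.pos) not in sanger_calls]
    if uncalled:
        raise DataError(
            f"{candidate.snp_id}: missing Sanger calls at {candidate.chrom}:"
            f"{candidate.pos} for members {uncalled}"
        )
    carriers = [
        ConfirmedMutant(candidate.snp_id, m, sanger_calls[(m, candidate.pos)], True)
        for m in members
        if candidate.alt in sanger_calls[(m, candidate.pos)]
    ]
    if len(carriers) > 1:
        logger.warning(
            "%s: %d carriers in pool %s (%s); the induced mutation may have recurred",
            candidate.snp_id, len(carriers), candidate.pool_id,
            [c.individual_id for c in carriers],
        )
    if not carriers:
        logger.info("%s: all %d member calls equal WT; candidate not confirmed",
                    candidate.snp_id, len(members))
    return DeconvolutionResult(candidate, carriers)


def concordance_rate(n_confirmed: int, n_candidates: int) -> float:
    """Percent of candidates confirmed by individual genotyping, to 2 decimals."""
    if n_candidates <= 0:
        raise DataError("concordance_rate requires at least one candidate")
    if not 0 <= n_confirmed <= n_candidates:
        raise DataError(
            f"n_confirmed {n_confirmed} outside [0, {n_candidates}]"
        )
    return round(100.0 * n_confirmed / n_candidates, 2)
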