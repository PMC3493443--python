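"""Forkhead-domain excision by local alignment against a reference domain.

A candidate full-length protein is scanned with an affine-gap local
alignment against a reference domain (~100 residues for the forkhead/FKH
winged-helix domain); the candidate subsequence covered by the optimal
local alignment is excised, with its coordinates recorded on the returned
record.  This is the alignment-based equivalent of looking a protein up in
a domain-annotation service and cutting out the reported domain region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .pairwise import DEFAULT_SCHEME, ScoringScheme, smith_waterman
from .seq_io import SequenceRecord

logger = logging.getLogger(__name__)

#: Minimum reference-domain length accepted for scanning.
MIN_REFERENCE_LENGTH = 20

#: Default minimum fraction of the reference domain that must be aligned.
DEFAULT_MIN_COVERAGE = 0.70


class DomainNotFoundError(ValueError):
    """No positive-scoring local alignment to the reference domain."""


@dataclass(frozen=True)
class DomainHit:
    """An excised domain plus its scan diagnostics."""

    record: SequenceRecord
    coverage: float
    score: float
    partial: bool


def extract_domain(
    candidate: SequenceRecord,
    reference_domain: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> DomainHit:
    """Excise the domain-like region of ``candidate``.

    Returns the candidate subsequence covered by the optimal local
    alignment to ``reference_domain``, with 1-based ``region`` coordinates
    set on the record.  ``coverage`` is the aligned fraction of the
    reference domain; hits below ``min_coverage`` are returned flagged
    ``partial`` rather than rejected (truncated gene models are common, and
    the longest available sequence is still informative).

    Raises
    ------
    DomainNotFoundError
        If no local alignment with positive score exists.
    """
    if len(reference_domain) < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference domain shorter than {MIN_REFERENCE_LENGTH} residues"
        )
    aln = smith_waterman(candidate, reference_domain, scheme)
    if aln.is_empty:
        raise DomainNotFoundError(
            f"no domain-like region found in {candidate.id!r}"
        )
    start, end = aln.a_span
    ref_start, ref_end = aln.b_span
    coverage = (ref_end - ref_start + 1) / len(reference_domain)
    partial = coverage < min_coverage
    if partial:
        logger.warning(
            "partial domain in %r: coverage %.2f < %.2f",
            candidate.id,
            coverage,
            min_coverage,
        )
    record = SequenceRecord(
        id=candidate.id,
        residues=candidate.residues[start - 1 : end],
        description=f"{candidate.description} [domain {start}-{end}]".strip(),
        region=(start, end),
        parent_id=candidate.id,
    )
    return DomainHit(record=record, coverage=coverage, score=aln.raw_score, partial=partial)
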