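"""Pairwise protein alignment, scoring and search statistics.

Affine-gap local (Smith–Waterman) and global (Needleman–Wunsch) alignment
under a substitution matrix, percent identity, and Karlin–Altschul
bit-score/E-value conversion.  Together these provide an in-package
similarity search with an E-value inclusion filter: the desk-scale
equivalent of a BLASTP screen of a proteome with a query domain.

The dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module fixes the scoring conventions (gap model, statistics, identity
denominator) and the result/record types used by the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import SequenceRecord

# Selenocysteine is absent from the published BLOSUM matrices; score it as
# cysteine (its closest chemical analog), the usual search-tool convention.
_RESIDUE_REMAP = str.maketrans({"U": "C"})


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and search statistics.

    A gap of length ``k`` costs ``gap_open + k * gap_extend`` (the opening
    charge and the first residue's extension are both applied).  ``lam`` and
    ``K`` are the Karlin–Altschul parameters used to convert raw scores to
    bit scores; the defaults are the published values for gapped BLOSUM62
    with gap penalties 11/1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    matrix: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.matrix is None:
            object.__setattr__(
                self, "matrix", substitution_matrices.load(self.matrix_name)
            )

    @classmethod
    def from_matrix_file(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        """Build a scheme from an NCBI-format substitution-matrix text file."""
        with Path(path).open() as fh:
            matrix = substitution_matrices.read(fh)
        return cls(matrix_name=Path(path).name, matrix=matrix, **kwargs)

    def pair_score(self, a: str, b: str) -> float:
        a = a.translate(_RESIDUE_REMAP)
        b = b.translate(_RESIDUE_REMAP)
        return float(self.matrix[a, b])

    def bit_score(self, raw_score: float) -> float:
        """Karlin–Altschul normalized score: (λ·S − ln K) / ln 2."""
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


#: Default scheme used across the pipeline (gapped BLOSUM62, 11/1).
DEFAULT_SCHEME = ScoringScheme()

#: Global-alignment scheme for domain-vs-domain identity reports.
GLOBAL_SCHEME = ScoringScheme(gap_open=10, gap_extend=1)


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment with score and identity bookkeeping.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; spans are
    1-based inclusive coordinates of the aligned region in each input (for
    global alignments, the whole sequences).
    """

    mode: str  # "local" | "global"
    aligned_a: str
    aligned_b: str
    raw_score: float
    bit_score: float
    n_identical: int
    n_columns: int
    a_span: tuple[int, int] | None
    b_span: tuple[int, int] | None

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@dataclass(frozen=True)
class SearchHit:
    """One subject passing the E-value filter of a similarity search."""

    query_id: str
    subject_id: str
    alignment: AlignmentResult
    evalue: float


def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    aligner.mode = mode
    return aligner


def _empty_result(mode: str, scheme: ScoringScheme) -> AlignmentResult:
    return AlignmentResult(
        mode=mode,
        aligned_a="",
        aligned_b="",
        raw_score=0.0,
        bit_score=scheme.bit_score(0.0),
        n_identical=0,
        n_columns=0,
        a_span=None,
        b_span=None,
    )


def _from_biopython(
    aln, mode: str, scheme: ScoringScheme, a_res: str, b_res: str
) -> AlignmentResult:
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    n_columns = len(aligned_a)
    n_identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return _empty_result(mode, scheme)
    a_span = (int(blocks_a[0][0]) + 1, int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]) + 1, int(blocks_b[-1][1]))
    return AlignmentResult(
        mode=mode,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        raw_score=float(aln.score),
        bit_score=scheme.bit_score(float(aln.score)),
        n_identical=n_identical,
        n_columns=n_columns,
        a_span=a_span,
        b_span=b_span,
    )


def smith_waterman(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Optimal affine-gap local alignment; empty alignment (score 0) when no
    positive-scoring alignment exists or either sequence is empty."""
    if len(a) == 0 or len(b) == 0:
        return _empty_result("local", scheme)
    aligner = _make_aligner(scheme, "local")
    sa = a.residues.translate(_RESIDUE_REMAP)
    sb = b.residues.translate(_RESIDUE_REMAP)
    alns = aligner.align(sa, sb)
    if alns.score <= 0:
        return _empty_result("local", scheme)
    return _from_biopython(alns[0], "local", scheme, a.residues, b.residues)


def needleman_wunsch(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme = GLOBAL_SCHEME
) -> AlignmentResult:
    """Optimal affine-gap global alignment with end gaps penalized."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("global alignment of two empty sequences")
    aligner = _make_aligner(scheme, "global")
    sa = a.residues.translate(_RESIDUE_REMAP)
    sb = b.residues.translate(_RESIDUE_REMAP)
    aln = aligner.align(sa, sb)[0]
    result = _from_biopython(aln, "global", scheme, a.residues, b.residues)
    # global spans always cover the full sequences
    return AlignmentResult(
        mode="global",
        aligned_a=result.aligned_a,
        aligned_b=result.aligned_b,
        raw_score=result.raw_score,
        bit_score=result.bit_score,
        n_identical=result.n_identical,
        n_columns=result.n_columns,
        a_span=(1, len(a)) if len(a) else None,
        b_span=(1, len(b)) if len(b) else None,
    )


def percent_identity(aln: AlignmentResult, denominator: str = "all") -> float:
    """Percent identity of an alignment.

    denominator
        ``"all"`` — every alignment column, gaps included (default
        reporting convention); ``"ungapped"`` — columns where both rows
        have residues; ``"shorter"`` — length of the shorter ungapped
        sequence.
    """
    if aln.n_columns == 0:
        raise ValueError("percent identity of an empty alignment")
    if denominator == "all":
        denom = aln.n_columns
    elif denominator == "ungapped":
        denom = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != "-" and y != "-"
        )
    elif denominator == "shorter":
        denom = min(
            len(aln.aligned_a.replace("-", "")),
            len(aln.aligned_b.replace("-", "")),
        )
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ValueError("identity denominator is zero")
    return 100.0 * aln.n_identical / denom


def evalue(bit_score: float, m: int, n: int) -> float:
    """Expected chance hits at this bit score: ``E = m · n · 2^(−bit)``.

    ``m`` is the query length and ``n`` the total database length.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    return float(m) * float(n) * math.pow(2.0, -bit_score)


def search(
    query: SequenceRecord,
    database: list[SequenceRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = 1e-2,
) -> list[SearchHit]:
    """Local-alignment search of ``query`` against ``database``.

    Returns hits with ``E < threshold`` sorted by ascending E-value, then
    descending bit score, then subject id.  The search space ``n`` is the
    summed residue count of the database.
    """
    if not database:
        raise ValueError("empty search database")
    n_db = sum(len(s) for s in database)
    hits: list[SearchHit] = []
    for subject in database:
        aln = smith_waterman(query, subject, scheme)
        if aln.is_empty:
            continue
        e = evalue(aln.bit_score, len(query), n_db)
        if e < threshold:
            hits.append(
                SearchHit(
                    query_id=query.id,
                    subject_id=subject.id,
                    alignment=aln,
                    evalue=e,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.alignment.bit_score, h.subject_id))
    return hits


def write_hits_tsv(hits: list[SearchHit], path: str | Path) -> None:
    """Write hits as BLAST-like tabular TSV."""
    with Path(path).open("w") as fh:
        fh.write("qid\tsid\tpident\tlength\tbitscore\tevalue\n")
        for h in hits:
            pid = percent_identity(h.alignment)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{pid:.1f}\t"
                f"{h.alignment.n_columns}\t{h.alignment.bit_score:.1f}\t"
                f"{h.evalue:.3g}\n"
            )
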