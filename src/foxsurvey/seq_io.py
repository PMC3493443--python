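"""Protein FASTA input/output and labeled reference panels.

Sequences are plain amino-acid strings over the 20 canonical residues plus
the ambiguity/rare codes X, B, Z and U (selenocysteine).  Reference panels
pair a forkhead-domain sequence (and optionally the full-length protein)
with a Fox subfamily label, e.g. FoxJ1 or FoxN3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: Accepted residue alphabet: 20 canonical amino acids plus X/B/Z/U.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")

#: Line width used when writing FASTA.
FASTA_WRAP = 60


class FastaError(ValueError):
    """Malformed FASTA input or invalid sequence content."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein (or excised domain) sequence.

    Parameters
    ----------
    id : str
        Unique identifier token (first word of the FASTA header).
    residues : str
        Upper-case amino-acid string; validated against
        :data:`PROTEIN_ALPHABET`.
    description : str
        Free text following the id on the header line.
    region : tuple of (int, int), optional
        1-based inclusive coordinates of this sequence within a parent
        sequence (used for excised domains).
    parent_id : str, optional
        Identifier of the parent sequence ``region`` refers to.
    """

    id: str
    residues: str
    description: str = ""
    region: tuple[int, int] | None = None
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record requires a non-empty id")
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in PROTEIN_ALPHABET:
                raise FastaError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        if self.region is not None:
            start, end = self.region
            if not (1 <= start <= end):
                raise FastaError(
                    f"record {self.id!r}: invalid region {self.region}"
                )
            if end - start + 1 != len(self.residues):
                raise FastaError(
                    f"record {self.id!r}: region {self.region} does not match "
                    f"sequence length {len(self.residues)}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def _clean_residues(raw: str, rec_id: str) -> str:
    seq = "".join(raw.split()).upper()
    if "*" in seq:
        logger.warning("record %r: stripping %d stop character(s)", rec_id, seq.count("*"))
        seq = seq.replace("*", "")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased, whitespace and ``'*'`` stop characters are
    stripped, and insertion order is preserved.  Duplicate ids and residues
    outside the accepted alphabet raise :class:`FastaError`.
    """
    path = Path(path)
    with path.open() as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if first and not first.startswith(">"):
            raise FastaError(f"{path}: not FASTA — first non-blank line lacks '>'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    # the pearson dialect tolerates blank lines between and within records
    for bio in SeqIO.parse(str(path), "fasta-pearson"):
        if bio.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {bio.id!r}")
        seen.add(bio.id)
        residues = _clean_residues(str(bio.seq), bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description.startswith(bio.id) else bio.description
        records.append(SequenceRecord(id=bio.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at :data:`FASTA_WRAP` columns."""
    bio_records = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(bio_records)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id to subfamily label.

    Lines starting with ``'#'`` and blank lines are ignored.
    """
    labels: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FastaError(f"{path}:{lineno}: expected 'id<TAB>subfamily'")
            if parts[0] in labels:
                raise FastaError(f"{path}:{lineno}: duplicate id {parts[0]!r}")
            labels[parts[0]] = parts[1]
    return labels


@dataclass
class PanelEntry:
    """A labeled reference-panel member."""

    record: SequenceRecord
    subfamily: str
    full_length: SequenceRecord | None = None


@dataclass
class ReferencePanel:
    """Labeled reference set of subfamily domain (and full-length) sequences.

    The panel plays two roles: its domain sequences anchor the phylogenetic
    placement of candidates, and the labeled set as a whole is the database
    for reverse-best-hit subfamily assignment.
    """

    entries: list[PanelEntry]
    target_subfamily: str = "FoxJ1"
    foxj1_like_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference panel is empty")
        for e in self.entries:
            if not e.subfamily:
                raise ValueError(f"panel entry {e.record.id!r}: empty subfamily label")
        if not self.foxj1_like_ids:
            self.foxj1_like_ids = [
                e.record.id for e in self.entries if e.subfamily == self.target_subfamily
            ]
        if not self.foxj1_like_ids:
            raise ValueError(
                f"target subfamily {self.target_subfamily!r} absent from panel"
            )

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def subfamilies(self) -> list[str]:
        return [e.subfamily for e in self.entries]

    def entry(self, rec_id: str) -> PanelEntry:
        for e in self.entries:
            if e.record.id == rec_id:
                return e
        raise KeyError(rec_id)

    def domain_records(self) -> list[SequenceRecord]:
        return [e.record for e in self.entries]

    def subfamily_of(self, rec_id: str) -> str:
        return self.entry(rec_id).subfamily


def load_panel(
    domain_path: str | Path,
    labels_path: str | Path,
    fulllength_path: str | Path | None = None,
    target_subfamily: str = "FoxJ1",
) -> ReferencePanel:
    """Load a labeled reference panel from FASTA + label-table files.

    Every domain record must appear in the label table; unused label-table
    ids are accepted with a warning.  Full-length records (optional FASTA)
    are joined to domain records by id.
    """
    domains = read_fasta(domain_path)
    labels = read_labels(labels_path)
    full_by_id: dict[str, SequenceRecord] = {}
    if fulllength_path is not None:
        full_by_id = {r.id: r for r in read_fasta(fulllength_path)}

    entries: list[PanelEntry] = []
    for rec in domains:
        if rec.id not in labels:
            raise ValueError(f"domain id {rec.id!r} missing from label table")
        entries.append(
            PanelEntry(record=rec, subfamily=labels[rec.id], full_length=full_by_id.get(rec.id))
        )
    unused = set(labels) - {r.id for r in domains}
    if unused:
        logger.warning("label table has %d unused id(s): %s", len(unused), sorted(unused))
    return ReferencePanel(entries=entries, target_subfamily=target_subfamily)
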