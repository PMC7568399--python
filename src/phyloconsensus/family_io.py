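"""Reading, validating and pre-filtering protein family alignments.

The central container is :class:`AlignedFamily`: a multiple sequence
alignment of protein homologs with one designated *query* row (the sequence
being engineered).  Everything downstream — distances, the tree, sequence
weights, the consensus profile — derives from this object.

Alignments are consumed as produced by an external aligner (Clustal, MAFFT,
...); this module never re-aligns.  Pre-filtering mirrors the conventional
curation applied to BLAST harvests before consensus analysis: drop duplicate
sequences, drop sequences whose ungapped length is far from the query's, and
drop remote homologs below an identity floor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, InsufficientFamilyError, ValidationError

#: The twenty canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Characters allowed in an aligned row: residues, unknown 'X', and the gap.
ALLOWED_CHARS = frozenset(AMINO_ACIDS + "X-")

GAP = "-"

_FORMAT_ALIASES = {
    "fasta": "fasta",
    "fa": "fasta",
    "clustal": "clustal",
    "aln": "clustal",
}


@dataclass(frozen=True)
class AlignedFamily:
    """An immutable protein MSA with a designated query row.

    Parameters
    ----------
    records:
        Ordered ``(sequence_id, aligned_sequence)`` pairs.  Aligned sequences
        are upper-case strings over the amino-acid alphabet plus ``'X'`` and
        the gap character ``'-'``; all rows share the same length.
    query_id:
        The id of the query row; must name exactly one record.
    """

    records: tuple[tuple[str, str], ...]
    query_id: str
    alignment_length: int = field(init=False)

    def __post_init__(self):
        records = tuple((str(i), str(s).upper()) for i, s in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValidationError("alignment contains no records")
        length = len(records[0][1])
        for sid, seq in records:
            if len(seq) != length:
                raise AlignmentError(
                    f"record '{sid}' has length {len(seq)}, expected {length}"
                )
            for col, ch in enumerate(seq):
                if ch not in ALLOWED_CHARS:
                    raise ValidationError(
                        f"record '{sid}' column {col + 1}: illegal character {ch!r}"
                    )
        ids = [sid for sid, _ in records]
        seen = set()
        for sid in ids:
            if sid in seen:
                raise ValidationError(f"duplicate sequence id '{sid}'")
            seen.add(sid)
        if self.query_id not in seen:
            raise ValidationError(f"query id '{self.query_id}' not in alignment")
        object.__setattr__(self, "alignment_length", length)

    # -- basic accessors ---------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, sequence_id: str) -> str:
        for sid, seq in self.records:
            if sid == sequence_id:
                return seq
        raise KeyError(sequence_id)

    @property
    def query_sequence(self) -> str:
        return self.sequence(self.query_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def drop(self, ids: Iterable[str]) -> "AlignedFamily":
        """Return a copy without the given ids (query cannot be dropped)."""
        dropped = set(ids)
        if self.query_id in dropped:
            raise ValidationError("cannot drop the query sequence")
        kept = tuple(r for r in self.records if r[0] not in dropped)
        return AlignedFamily(kept, self.query_id)


def ungapped(seq: str) -> str:
    """Return the sequence with gap characters removed."""
    return seq.replace(GAP, "")


def _resolve_format(fmt: str) -> str:
    try:
        return _FORMAT_ALIASES[fmt.lower()]
    except KeyError:
        raise ValidationError(f"unsupported alignment format '{fmt}'") from None


def read_alignment(path, format: str = "fasta", query_id: str | None = None) -> AlignedFamily:
    """Read a protein alignment from FASTA or Clustal into an AlignedFamily.

    Record order is preserved from the file.  ``query_id`` defaults to the
    first record, which is the usual convention when the engineered sequence
    seeds the alignment.
    """
    fmt = _resolve_format(format)
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython raises ValueError both for parse failures and ragged rows.
        raise AlignmentError(f"could not parse '{path}' as {fmt}: {exc}") from exc
    records = tuple((rec.id, str(rec.seq).upper()) for rec in msa)
    if query_id is None:
        query_id = records[0][0]
    return AlignedFamily(records, query_id)


def write_alignment(family: AlignedFamily, path, format: str = "fasta") -> None:
    """Write the family back out in FASTA or Clustal format."""
    fmt = _resolve_format(format)
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in family
    )
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, fmt)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over mutually non-gap columns.

    'X' never counts as a match.  Returns 0.0 when the two sequences share
    no non-gap column.
    """
    if len(a) != len(b):
        raise AlignmentError("sequences have different aligned lengths")
    matches = 0
    shared = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x == y and x != "X":
            matches += 1
    return matches / shared if shared else 0.0


def filter_homologs(
    family: AlignedFamily,
    min_identity: float = 0.5,
    length_tolerance: float = 0.2,
) -> AlignedFamily:
    """Apply the standard pre-consensus curation to a homolog family.

    Removes, in order of precedence recorded in the report:

    1. *duplicates* — records whose ungapped sequence is byte-identical to an
       earlier record's;
    2. *length outliers* — records whose ungapped length falls outside
       ``[(1 - tol), (1 + tol)] ×`` the query's ungapped length;
    3. *remote homologs* — records with identity to the query (matches over
       mutually non-gap columns) below ``min_identity``.

    The query is never removed.  Raises
    :class:`~phyloconsensus.errors.InsufficientFamilyError` if fewer than
    three records survive.  Use :func:`filter_report` for the per-record audit.
    """
    removed = filter_report(family, min_identity, length_tolerance)
    result = family.drop(removed)
    if len(result) < 3:
        raise InsufficientFamilyError(
            f"only {len(result)} sequences survive filtering; "
            "a consensus needs at least 3"
        )
    return result


def filter_report(
    family: AlignedFamily,
    min_identity: float = 0.5,
    length_tolerance: float = 0.2,
) -> dict[str, str]:
    """Return ``{sequence_id: reason_removed}`` for records filter_homologs drops."""
    if not (0.0 < min_identity <= 1.0):
        raise ValidationError("min_identity must lie in (0, 1]")
    if length_tolerance < 0:
        raise ValidationError("length_tolerance must be non-negative")
    query_seq = family.query_sequence
    qlen = len(ungapped(query_seq))
    lo = (1.0 - length_tolerance) * qlen
    hi = (1.0 + length_tolerance) * qlen
    removed: dict[str, str] = {}
    seen_ungapped: set[str] = set()
    for sid, seq in family:
        bare = ungapped(seq)
        if sid == family.query_id:
            seen_ungapped.add(bare)
            continue
        if bare in seen_ungapped:
            removed[sid] = "duplicate"
            continue
        if not (lo <= len(bare) <= hi):
            removed[sid] = "length"
            seen_ungapped.add(bare)
            continue
        if pairwise_identity(seq, query_seq) < min_identity:
            removed[sid] = "identity"
            seen_ungapped.add(bare)
            continue
        seen_ungapped.add(bare)
    return removed


def write_filter_report(report: dict[str, str], path) -> None:
    """Write the removal audit as a two-column TSV (id, reason_removed)."""
    with open(path, "w") as handle:
        handle.write("sequence_id\treason_removed\n")
        for sid, reason in report.items():
            handle.write(f"{sid}\t{reason}\n")
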