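"""Alignment input/output and pre-split filtering.

Reads multi-record Stockholm files (the Pfam-A.seed / Pfam-A.full dialect:
records concatenated, each terminated by ``//``, possibly interleaved) and
aligned FASTA.  Writes training sets as Stockholm and test sets as ungapped
FASTA.  Also implements the fragment filter that removes alignment rows much
shorter than the family average before splitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

__all__ = [
    "GAP_CHARS",
    "Alignment",
    "MalformedRecordError",
    "ungapped_length",
    "degap",
    "read_stockholm_multi",
    "read_fasta_alignment",
    "read_alignments",
    "write_stockholm",
    "write_fasta",
    "write_train_test",
    "fragment_filter",
]

#: Characters treated as alignment gaps (Pfam uses both '-' and '.').
GAP_CHARS = frozenset("-.")

_GAP_RE = re.compile(r"[-.]")


class MalformedRecordError(ValueError):
    """A Stockholm/FASTA record could not be assembled into an alignment.

    Carries the name of the offending record so that batch processing can
    report and skip it.
    """

    def __init__(self, record_name: str, reason: str):
        self.record_name = record_name
        self.reason = reason
        super().__init__(f"record {record_name!r}: {reason}")


def ungapped_length(seq: str) -> int:
    """Number of residue (non-gap) characters in a gapped row."""
    return sum(1 for c in seq if c not in GAP_CHARS)


def degap(seq: str) -> str:
    """Remove gap characters from a gapped row."""
    return _GAP_RE.sub("", seq)


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: ordered, identically-long gapped rows.

    Parameters
    ----------
    name:
        Family identifier (``#=GF ID`` for Pfam records, or synthesized).
    ids:
        Row identifiers, unique within the alignment.
    seqs:
        Gapped sequences, all of the same length (the column count).
    """

    name: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have the same length")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise MalformedRecordError(self.name, f"duplicate sequence ids: {sorted(dupes)}")
        if self.seqs:
            n_cols = len(self.seqs[0])
            if any(len(s) != n_cols for s in self.seqs):
                raise MalformedRecordError(self.name, "rows have unequal lengths")
            if n_cols == 0:
                raise MalformedRecordError(self.name, "alignment has zero columns")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.seqs))

    def subset(self, indices: Iterable[int]) -> "Alignment":
        """New alignment keeping the given row indices, in the given order."""
        idx = list(indices)
        return Alignment(
            self.name,
            tuple(self.ids[i] for i in idx),
            tuple(self.seqs[i] for i in idx),
        )


def _check_block_duplicates(lines: list[str], name: str) -> None:
    # Within one interleaved block a sequence id may appear only once;
    # a repeat inside a block is a genuine duplicate, not interleaving.
    seen: set[str] = set()
    for line in lines:
        stripped = line.strip()
        if not stripped:
            seen = set()
            continue
        if stripped.startswith("#") or stripped == "//":
            continue
        seq_id = stripped.split(None, 1)[0]
        if seq_id in seen:
            raise MalformedRecordError(name, f"duplicate sequence id in one block: {seq_id!r}")
        seen.add(seq_id)


def _parse_stockholm_record(lines: list[str], fallback_name: str) -> Alignment:
    # Rows are assembled by hand (not via Bio.AlignIO) so that '.' and '-'
    # gap characters survive a write/read round-trip verbatim.
    name = fallback_name
    for line in lines:
        if line.startswith("#=GF ID"):
            parts = line.split(None, 2)
            if len(parts) == 3:
                name = parts[2].strip()
            break
    _check_block_duplicates(lines, name)
    order: list[str] = []
    parts_by_id: dict[str, list[str]] = {}
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or stripped == "//":
            continue
        fields = stripped.split()
        if len(fields) != 2:
            raise MalformedRecordError(name, f"cannot parse sequence line: {stripped!r}")
        seq_id, chunk = fields
        if seq_id not in parts_by_id:
            order.append(seq_id)
            parts_by_id[seq_id] = []
        parts_by_id[seq_id].append(chunk)
    if not order:
        raise MalformedRecordError(name, "record contains no sequence rows")
    return Alignment(
        name,
        tuple(order),
        tuple("".join(parts_by_id[i]) for i in order),
    )


def read_stockholm_multi(stream: TextIO) -> list[Alignment]:
    """Parse a (possibly multi-record) Stockholm 1.0 stream.

    Each ``//``-terminated record becomes one :class:`Alignment`; row order
    is preserved and interleaved/wrapped sequence lines are assembled.  The
    ``#=GF ID`` annotation supplies the family name when present; otherwise
    a name is synthesized from the record's position in the file.

    Raises
    ------
    MalformedRecordError
        If a record's rows assemble to unequal lengths or contain duplicate
        identifiers.
    """
    alignments: list[Alignment] = []
    current: list[str] = []
    has_content = False
    for line in stream:
        current.append(line)
        if line.strip().startswith("#") or not line.strip():
            continue
        if line.strip() == "//":
            alignments.append(_parse_stockholm_record(current, f"record{len(alignments) + 1}"))
            current = []
            has_content = False
        else:
            has_content = True
    if has_content:
        # Trailing sequence data without the closing "//" terminator.
        alignments.append(_parse_stockholm_record(current, f"record{len(alignments) + 1}"))
    return alignments


def read_fasta_alignment(stream: TextIO, name: str = "alignment") -> Alignment:
    """Read an aligned FASTA stream into an :class:`Alignment`."""
    records = list(SeqIO.parse(stream, "fasta"))
    return Alignment(name, tuple(r.id for r in records), tuple(str(r.seq) for r in records))


def read_alignments(path: str) -> list[Alignment]:
    """Read Stockholm (multi-record) or aligned FASTA by sniffing the header."""
    with open(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            return [read_fasta_alignment(fh)]
        return read_stockholm_multi(fh)


def write_stockholm(aln: Alignment, stream: TextIO) -> None:
    """Write one non-interleaved Stockholm record (one line per sequence)."""
    stream.write("# STOCKHOLM 1.0\n")
    if aln.name:
        stream.write(f"#=GF ID {aln.name}\n")
    width = max((len(i) for i in aln.ids), default=0)
    for seq_id, seq in aln.rows:
        stream.write(f"{seq_id:<{width}} {seq}\n")
    stream.write("//\n")


def write_fasta(records: Sequence[tuple[str, str]], stream: TextIO, line_width: int = 60) -> None:
    for seq_id, seq in records:
        stream.write(f">{seq_id}\n")
        for i in range(0, len(seq), line_width):
            stream.write(seq[i : i + line_width] + "\n")
        if not seq:
            stream.write("\n")


def write_train_test(
    train: Alignment,
    test: Sequence[tuple[str, str]],
    train_stream: TextIO,
    test_stream: TextIO,
    rng,
) -> None:
    """Write a split: training set as Stockholm, test set as ungapped FASTA.

    The training rows keep their original columns but their order is randomly
    permuted (drawn from ``rng``), so that downstream profile builders cannot
    exploit input ordering.  Test sequences are emitted individually with gap
    characters removed.
    """
    perm = rng.permutation(train.n_rows)
    write_stockholm(train.subset(int(i) for i in perm), train_stream)
    write_fasta([(seq_id, degap(seq)) for seq_id, seq in test], test_stream)


def fragment_filter(aln: Alignment, min_frac: float = 0.7) -> Alignment:
    """Remove fragment rows shorter than ``min_frac`` of the mean length.

    The mean ungapped length is computed once, over all input rows, and every
    row whose ungapped length is at least ``min_frac`` times that mean is
    kept (row order preserved, columns untouched).  Applied exactly once
    before splitting; re-application after removal could remove more rows
    because the mean shifts.
    """
    if aln.n_rows == 0:
        raise ValueError("cannot fragment-filter an empty alignment")
    lengths = [ungapped_length(s) for s in aln.seqs]
    cutoff = min_frac * (sum(lengths) / len(lengths))
    kept = [i for i, length in enumerate(lengths) if length >= cutoff]
    return aln.subset(kept)
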