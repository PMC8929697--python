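"""Homology-search benchmark construction from a train/test split.

Test domains are turned into *positive* full-length sequences by embedding
each domain once inside nonhomologous flanking sequence: the total length is
drawn from the empirical length distribution of a background protein
database (conditioned to fit the domain), the domain is placed at a uniform
position, and each flank is a shuffled window cut from the background
database.  *Negative* decoys copy the three segment lengths of a randomly
chosen positive and fill all three segments with shuffled windows, so the
negative set matches the positives' length and composition statistics while
carrying no homologous signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from Bio import SeqIO

__all__ = [
    "BackgroundDB",
    "PositiveRecord",
    "NegativeRecord",
    "BenchmarkSet",
    "downsample_test",
    "shuffle_subsequence",
    "make_positive",
    "make_negatives",
]


@dataclass(frozen=True)
class BackgroundDB:
    """A background sequence database (UniProt-like) used as raw material
    for decoy segments and as the empirical length distribution."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if not self.seqs:
            raise ValueError("background database must be nonempty")
        if any(len(s) < 1 for s in self.seqs):
            raise ValueError("background sequences must have length >= 1")

    @classmethod
    def from_fasta(cls, stream: TextIO) -> "BackgroundDB":
        records = list(SeqIO.parse(stream, "fasta"))
        return cls(tuple(r.id for r in records), tuple(str(r.seq) for r in records))

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "BackgroundDB":
        return cls(tuple(f"bg{i}" for i in range(len(seqs))), tuple(seqs))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs])


@dataclass(frozen=True)
class PositiveRecord:
    """A test domain embedded once in a synthetic nonhomologous sequence.

    ``full_seq[domain_start:domain_end]`` equals the embedded domain.
    ``flank_sources`` records the (db index, window start, window) each
    flank was shuffled from, for provenance checks.
    """

    family: str
    domain_id: str
    full_seq: str
    domain_start: int
    domain_end: int
    flank_sources: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    @property
    def segment_lengths(self) -> tuple[int, int, int]:
        return (
            self.domain_start,
            self.domain_end - self.domain_start,
            len(self.full_seq) - self.domain_end,
        )


@dataclass(frozen=True)
class NegativeRecord:
    """A decoy: three shuffled background segments, no embedded domain."""

    id: str
    full_seq: str
    segment_lengths: tuple[int, int, int]

    def __post_init__(self):
        if sum(self.segment_lengths) != len(self.full_seq):
            raise ValueError("segment lengths must sum to the sequence length")


@dataclass(frozen=True)
class BenchmarkSet:
    positives: tuple[PositiveRecord, ...]
    negatives: tuple[NegativeRecord, ...]
    seed: int | None = None


def downsample_test(test_ids: Sequence, max_n: int = 10, rng=None) -> list:
    """Uniform sample without replacement of at most ``max_n`` test ids,
    keeping the original relative order."""
    if max_n <= 0:
        return []
    if len(test_ids) <= max_n:
        return list(test_ids)
    picked = sorted(rng.choice(len(test_ids), size=max_n, replace=False))
    return [test_ids[i] for i in picked]


def _draw_window(db: BackgroundDB, length: int, rng) -> tuple[int, int, str]:
    """Pick a window of ``length`` uniformly over all feasible (entry, start)
    positions in the database."""
    starts_per_entry = np.array([len(s) - length + 1 for s in db.seqs])
    feasible = np.flatnonzero(starts_per_entry > 0)
    if len(feasible) == 0:
        raise ValueError(f"no background entry is at least {length} residues long")
    weights = starts_per_entry[feasible]
    entry = int(feasible[rng.choice(len(feasible), p=weights / weights.sum())])
    start = int(rng.integers(starts_per_entry[entry]))
    return entry, start, db.seqs[entry][start : start + length]


def shuffle_subsequence(db: BackgroundDB, length: int, rng) -> str:
    """A uniformly shuffled window of the requested length cut from the
    background database.  Composition is preserved exactly; order is not."""
    if length == 0:
        return ""
    _, _, window = _draw_window(db, length, rng)
    return "".join(np.array(list(window))[rng.permutation(length)])


def make_positive(
    domain: str,
    db: BackgroundDB,
    rng,
    family: str = "",
    domain_id: str = "",
) -> PositiveRecord:
    """Embed one test domain in a synthetic nonhomologous sequence.

    The total length is drawn from the database's empirical length
    distribution conditioned to be at least the domain length (rejection),
    the domain start is uniform over valid offsets, and the two flanks are
    independently shuffled background windows.
    """
    if not domain:
        raise ValueError("domain must be nonempty")
    lengths = db.lengths
    feasible = lengths[lengths >= len(domain)]
    if len(feasible) == 0:
        raise ValueError("domain is longer than every background entry")
    total = int(feasible[rng.integers(len(feasible))])
    start = int(rng.integers(total - len(domain) + 1))
    end = start + len(domain)

    sources: list[tuple[int, int, str]] = []

    def flank(length: int) -> str:
        if length == 0:
            return ""
        entry, win_start, window = _draw_window(db, length, rng)
        sources.append((entry, win_start, window))
        return "".join(np.array(list(window))[rng.permutation(length)])

    left = flank(start)
    right = flank(total - end)
    return PositiveRecord(
        family=family,
        domain_id=domain_id,
        full_seq=left + domain + right,
        domain_start=start,
        domain_end=end,
        flank_sources=tuple(sources),
    )


def make_negatives(
    positives: Sequence[PositiveRecord],
    db: BackgroundDB,
    count: int = 200_000,
    rng=None,
) -> list[NegativeRecord]:
    """Build ``count`` decoys mirroring the positives' segment lengths.

    Each decoy samples one positive uniformly, copies its (left, domain,
    right) segment lengths, and fills all three segments independently with
    shuffled background windows — so no homologous content is embedded.
    """
    if not positives:
        raise ValueError("need at least one positive to model decoys on")
    negatives: list[NegativeRecord] = []
    for i in range(count):
        pos = positives[int(rng.integers(len(positives)))]
        segs = pos.segment_lengths
        seq = "".join(shuffle_subsequence(db, length, rng) for length in segs)
        negatives.append(NegativeRecord(id=f"decoy{i}", full_seq=seq, segment_lengths=segs))
    return negatives
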