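"""Per-position fragment-end profiles over a (circular) bacterial genome.

The cleavage-mapping protocol sequences each strand of the recovered
fragments independently, so the informative signal is the per-position,
per-orientation count of fragment 3'- and 5'-ends rather than coverage
depth.  This module turns alignments into those end-count tracks and
round-trips them through standard browser formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:  # pysam is only needed for SAM/BAM and FASTA I/O, not for array work
    import pysam
except ImportError:  # pragma: no cover
    pysam = None

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class GenomeSequence:
    """A single-contig genome (bacterial chromosome model)."""

    contig_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"genome contains non-ACGTN characters: {sorted(bad)}")
        if len(seq) == 0:
            raise ValueError("empty genome sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence over [start, end); wraps through the origin if circular."""
        n = self.length
        if end - start > n:
            raise ValueError("requested window longer than genome")
        if 0 <= start and end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(
                f"window [{start}, {end}) falls off a linear genome of length {n}"
            )
        idx = np.arange(start, end) % n
        return "".join(self.sequence[i] for i in idx)

    @classmethod
    def from_fasta(cls, path, circular: bool = True) -> "GenomeSequence":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single-contig FASTA, found {len(records)} records"
            )
        rec = records[0]
        return cls(contig_id=rec.id, sequence=str(rec.seq), circular=circular)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig_id}\n")
            for i in range(0, self.length, 80):
                fh.write(self.sequence[i : i + 80] + "\n")


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned sequencing fragment, 0-based half-open coordinates.

    ``end`` may exceed the genome length for fragments wrapping the origin
    of a circular genome; coordinates are reduced modulo the genome length
    when ends are counted.
    """

    contig_id: str
    start: int
    end: int
    orientation: str  # FORWARD or REVERSE

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class EndProfile:
    """Per-position, per-orientation 3'- and 5'-end counts.

    Arrays are integer-valued when built from alignments; library scaling
    produces real-valued copies of the same structure.
    """

    n3e_forward: np.ndarray
    n3e_reverse: np.ndarray
    n5e_forward: np.ndarray
    n5e_reverse: np.ndarray
    total_fragments: float

    def __post_init__(self):
        lengths = {
            len(self.n3e_forward),
            len(self.n3e_reverse),
            len(self.n5e_forward),
            len(self.n5e_reverse),
        }
        if len(lengths) != 1:
            raise ValueError("end-count arrays must share one length")
        for arr in (self.n3e_forward, self.n3e_reverse, self.n5e_forward, self.n5e_reverse):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("end counts must be non-negative")

    @property
    def genome_length(self) -> int:
        return len(self.n3e_forward)

    def scaled(self, factor: float) -> "EndProfile":
        return EndProfile(
            n3e_forward=self.n3e_forward * factor,
            n3e_reverse=self.n3e_reverse * factor,
            n5e_forward=self.n5e_forward * factor,
            n5e_reverse=self.n5e_reverse * factor,
            total_fragments=self.total_fragments * factor,
        )

    @classmethod
    def zeros(cls, genome_length: int) -> "EndProfile":
        return cls(
            n3e_forward=np.zeros(genome_length, dtype=np.int64),
            n3e_reverse=np.zeros(genome_length, dtype=np.int64),
            n5e_forward=np.zeros(genome_length, dtype=np.int64),
            n5e_reverse=np.zeros(genome_length, dtype=np.int64),
            total_fragments=0,
        )


def count_ends_from_arrays(
    starts: np.ndarray,
    ends: np.ndarray,
    is_reverse: np.ndarray,
    genome: GenomeSequence,
) -> EndProfile:
    """Vectorised end counting; the workhorse behind :func:`count_read_ends`.

    A forward fragment [s, e) leaves its 5'-end at s and 3'-end at e-1; a
    reverse fragment leaves its 3'-end at s and 5'-end at e-1.  Circular
    genomes wrap coordinates modulo the genome length.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    is_reverse = np.asarray(is_reverse, dtype=bool)
    n = genome.length

    if np.any(starts < 0) or np.any(ends <= starts):
        raise ValueError("fragments must satisfy 0 <= start < end")
    if not genome.circular:
        bad = (ends > n) | (starts >= n)
        if np.any(bad):
            n_bad = int(bad.sum())
            logger.warning("rejected %d fragments outside linear genome", n_bad)
            keep = ~bad
            starts, ends, is_reverse = starts[keep], ends[keep], is_reverse[keep]
    left = starts % n
    right = (ends - 1) % n

    profile = EndProfile.zeros(n)
    fwd, rev = ~is_reverse, is_reverse
    np.add.at(profile.n3e_forward, right[fwd], 1)
    np.add.at(profile.n5e_forward, left[fwd], 1)
    np.add.at(profile.n3e_reverse, left[rev], 1)
    np.add.at(profile.n5e_reverse, right[rev], 1)
    profile.total_fragments = int(len(starts))
    return profile


def count_read_ends(
    fragments: Iterable[AlignedFragment], genome: GenomeSequence
) -> EndProfile:
    """Count fragment 3'- and 5'-ends per position and orientation."""
    fragments = list(fragments)
    if not fragments:
        return EndProfile.zeros(genome.length)
    starts = np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments))
    ends = np.fromiter((f.end for f in fragments), dtype=np.int64, count=len(fragments))
    rev = np.fromiter(
        (f.orientation == REVERSE for f in fragments), dtype=bool, count=len(fragments)
    )
    return count_ends_from_arrays(starts, ends, rev, genome)


def combined_n3e(profile: EndProfile) -> np.ndarray:
    """Single 3'-end track: elementwise forward + reverse counts."""
    return np.asarray(profile.n3e_forward) + np.asarray(profile.n3e_reverse)


def fragments_from_sam(
    path, genome: GenomeSequence, min_mapq: int = 20
) -> list[AlignedFragment]:
    """Load aligned reads from SAM/BAM as fragments.

    Each mapped read contributes its own ends (the single-strand library
    sequences the two strands independently); duplicates are kept, since
    signal height is the measurement.  Reads with MAPQ below ``min_mapq``
    are discarded.
    """
    if pysam is None:  # pragma: no cover
        raise ImportError("pysam is required to read SAM/BAM")
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_start is None:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            out.append(
                AlignedFragment(
                    contig_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    orientation=REVERSE if rec.is_reverse else FORWARD,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def write_track(values, genome: GenomeSequence, path, format: str = "wig") -> None:
    """Write a per-position track as fixedStep WIG (1-based) or bedGraph."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty track")
    if len(values) != genome.length:
        raise ValueError(
            f"track length {len(values)} does not match genome length {genome.length}"
        )
    path = Path(path)
    if format == "wig":
        with open(path, "w") as fh:
            fh.write(f"track type=wiggle_0 name={path.stem}\n")
            fh.write(f"fixedStep chrom={genome.contig_id} start=1 step=1 span=1\n")
            for v in values:
                fh.write(f"{_fmt(v)}\n")
    elif format == "bedgraph":
        with open(path, "w") as fh:
            # run-length encode identical neighbouring values
            change = np.flatnonzero(np.diff(values)) + 1
            bounds = np.concatenate([[0], change, [len(values)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{genome.contig_id}\t{s}\t{e}\t{_fmt(values[s])}\n")
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(path, format: str = "wig") -> np.ndarray:
    """Read a track written by :func:`write_track` back into an array."""
    path = Path(path)
    if format == "wig":
        vals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "fixedStep", "variableStep")):
                    continue
                vals.append(float(line))
        return np.array(vals)
    elif format == "bedgraph":
        segments = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("track"):
                    continue
                _, s, e, v = line.split("\t")
                segments.append((int(s), int(e), float(v)))
        n = max(e for _, e, _ in segments)
        out = np.zeros(n)
        for s, e, v in segments:
            out[s:e] = v
        return out
    raise ValueError(f"unknown track format {format!r}")


def write_ends_tsv(profile: EndProfile, path) -> None:
    """TSV of (position, n3e_f, n3e_r, n5e_f, n5e_r), one row per position."""
    with open(path, "w") as fh:
        fh.write("position\tn3e_forward\tn3e_reverse\tn5e_forward\tn5e_reverse\n")
        for i in range(profile.genome_length):
            fh.write(
                f"{i}\t{_fmt(profile.n3e_forward[i])}\t{_fmt(profile.n3e_reverse[i])}"
                f"\t{_fmt(profile.n5e_forward[i])}\t{_fmt(profile.n5e_reverse[i])}\n"
            )


def _fmt(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)
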