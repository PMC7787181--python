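"""Core I/O: FASTA, BED/bedGraph, alignment-block tables, contact-matrix
triplets, genome windowing and elementary per-window tracks.

All coordinates are 0-based half-open internally.  The ``coords`` alignment
dialect (1-based fully closed) is converted on read and on write.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

MISSING = np.nan

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome / scaffold name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str or None
        '+', '-' or None when strand is not meaningful.
    """

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class WindowTrack:
    """Fixed-width per-window values along one chromosome.

    ``values[i]`` covers ``[i*window_size, min((i+1)*window_size, length))``.
    Missing windows carry NaN, never 0.
    """

    chrom: str
    window_size: int
    values: np.ndarray
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.chrom_length is not None:
            expected = math.ceil(self.chrom_length / self.window_size)
            if len(self.values) != expected:
                raise ValueError(
                    f"{self.chrom}: expected {expected} windows for length "
                    f"{self.chrom_length}, got {len(self.values)}"
                )

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def window_interval(self, i: int) -> GenomicInterval:
        start = i * self.window_size
        end = start + self.window_size
        if self.chrom_length is not None:
            end = min(end, self.chrom_length)
        return GenomicInterval(self.chrom, start, end)

    def defined(self) -> np.ndarray:
        """Boolean mask of non-missing windows."""
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block (query vs target, half-open coords)."""

    query_chrom: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    aln_len: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("invalid query interval")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("invalid target interval")
        if self.matches > self.aln_len:
            raise ValueError("matches exceed alignment length")

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.query_chrom, self.query_start, self.query_end)

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_chrom, self.target_start, self.target_end)


# ---------------------------------------------------------------------------
# FASTA


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: SEQUENCE}`` mapping.

    Names are the first whitespace-delimited token of the header; sequences
    are uppercased.  Raises :class:`FastaParseError` naming the offending
    line on malformed input.
    """
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                if name in seqs:
                    raise FastaParseError(f"line {lineno}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence before first header"
                    )
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Windows and tracks


def make_windows(
    chrom_lengths: Mapping[str, int], window_size: int
) -> list[GenomicInterval]:
    """Tile every chromosome with non-overlapping windows anchored at 0.

    The last window is truncated at the chromosome end.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    out = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_size):
            out.append(GenomicInterval(chrom, start, min(start + window_size, length)))
    return out


def gc_track(
    seq: str,
    window_size: int,
    chrom: str = "",
    max_n_fraction: float = 0.5,
) -> WindowTrack:
    """Per-window GC fraction, N bases excluded from the denominator.

    Windows that are all N, or whose N fraction is >= ``max_n_fraction``,
    are missing.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    n_win = math.ceil(len(seq) / window_size)
    values = np.full(n_win, MISSING)
    for i in range(n_win):
        lo, hi = i * window_size, min((i + 1) * window_size, len(seq))
        width = hi - lo
        n_count = int(is_n[lo:hi].sum())
        denom = width - n_count
        if denom == 0 or n_count / width >= max_n_fraction:
            continue
        values[i] = is_gc[lo:hi].sum() / denom
    return WindowTrack(chrom, window_size, values, chrom_length=len(seq))


# ---------------------------------------------------------------------------
# Alignment blocks (PAF / nucmer-coords-like TSV)


def read_alignment_blocks(path: str | Path, dialect: str = "paf") -> list[AlignmentBlock]:
    """Read alignment blocks from PAF (columns 1-12) or a ``coords`` TSV.

    The coords dialect carries 1-based fully-closed coordinates in columns
    (qname, qstart, qend, tname, tstart, tend, strand, matches, aln_len)
    and is converted to the internal 0-based half-open convention.
    """
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "paf":
                    if len(f) < 12:
                        raise ValueError("fewer than 12 PAF columns")
                    blk = AlignmentBlock(
                        query_chrom=f[0],
                        query_start=int(f[2]),
                        query_end=int(f[3]),
                        target_chrom=f[5],
                        target_start=int(f[7]),
                        target_end=int(f[8]),
                        strand=f[4],
                        matches=int(f[9]),
                        aln_len=int(f[10]),
                    )
                else:
                    if len(f) < 9:
                        raise ValueError("fewer than 9 coords columns")
                    blk = AlignmentBlock(
                        query_chrom=f[0],
                        query_start=int(f[1]) - 1,
                        query_end=int(f[2]),
                        target_chrom=f[3],
                        target_start=int(f[4]) - 1,
                        target_end=int(f[5]),
                        strand=f[6],
                        matches=int(f[7]),
                        aln_len=int(f[8]),
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            blocks.append(blk)
    return blocks


def write_alignment_blocks(
    path: str | Path,
    blocks: Iterable[AlignmentBlock],
    dialect: str = "paf",
    query_lengths: Mapping[str, int] | None = None,
    target_lengths: Mapping[str, int] | None = None,
) -> None:
    if dialect not in ("paf", "coords"):
        raise ValueError(f"unknown dialect {dialect!r}")
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            if dialect == "paf":
                qlen = query_lengths.get(b.query_chrom, b.query_end)
                tlen = target_lengths.get(b.target_chrom, b.target_end)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            b.query_chrom, qlen, b.query_start, b.query_end,
                            b.strand,
                            b.target_chrom, tlen, b.target_start, b.target_end,
                            b.matches, b.aln_len, 60,
                        )
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            b.query_chrom, b.query_start + 1, b.query_end,
                            b.target_chrom, b.target_start + 1, b.target_end,
                            b.strand, b.matches, b.aln_len,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/4/6; strand taken from column 6 when present."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand is not None:
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                if iv.strand is not None:
                    cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(path: str | Path, tracks: Iterable[WindowTrack]) -> None:
    """Write one or more window tracks as bedGraph; missing windows skipped."""
    with open(path, "w") as fh:
        for t in tracks:
            for i, v in enumerate(t.values):
                if np.isnan(v):
                    continue
                iv = t.window_interval(i)
                fh.write(f"{t.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def read_bedgraph(
    path: str | Path, window_size: int, chrom_lengths: Mapping[str, int]
) -> dict[str, WindowTrack]:
    """Read bedGraph written on a fixed window grid back into tracks."""
    tracks = {
        c: WindowTrack(c, window_size, np.full(math.ceil(n / window_size), MISSING), n)
        for c, n in chrom_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, value = line.split("\t")[:4]
            start = int(start)
            if start % window_size != 0:
                raise ValueError(f"bedGraph interval not on the {window_size}-bp grid")
            tracks[chrom].values[start // window_size] = float(value)
    return tracks


# ---------------------------------------------------------------------------
# Contact matrices (COO triplet text)


def write_coo_matrix(path: str | Path, counts: np.ndarray) -> None:
    """Write the upper triangle (incl. diagonal) as 'bin_i bin_j count' lines,
    preceded by a '#nbins N' header."""
    n = counts.shape[0]
    with open(path, "w") as fh:
        fh.write(f"#nbins\t{n}\n")
        iu, ju = np.nonzero(np.triu(counts))
        for i, j in zip(iu, ju):
            fh.write(f"{i}\t{j}\t{counts[i, j]:.6g}\n")


def read_coo_matrix(path: str | Path) -> np.ndarray:
    """Read a COO triplet file into a dense symmetric matrix."""
    n = None
    triplets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#nbins"):
                n = int(line.split("\t")[1])
                continue
            i, j, v = line.split("\t")
            triplets.append((int(i), int(j), float(v)))
    if n is None:
        n = max(max(i, j) for i, j, _ in triplets) + 1
    m = np.zeros((n, n))
    for i, j, v in triplets:
        m[i, j] = v
        m[j, i] = v
    return m
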