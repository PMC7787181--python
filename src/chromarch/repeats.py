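"""Repeat-enrichment annotation (putative centromeres, telomeres, ITRs) and
inverted-repeat palindrome detection on the W.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .core_io import GenomicInterval, WindowTrack, revcomp


@dataclass(frozen=True)
class RepeatAnnotation:
    kind: str  # centromere / telomere_terminal / ITR
    interval: GenomicInterval
    copy_count: int
    motif: str
    secondary: bool = False


@dataclass(frozen=True)
class PalindromeCall:
    arm1: GenomicInterval
    arm2: GenomicInterval
    spacer: int
    identity: float

    @property
    def total_length(self) -> int:
        return self.arm2.end - self.arm1.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit-packed k-mer codes at every start position; -1 where the k-mer
    contains a non-ACGT base."""
    arr = _encode(seq)
    code = np.full(len(arr), -1, dtype=np.int64)
    for b, c in ((ord("A"), 0), (ord("C"), 1), (ord("G"), 2), (ord("T"), 3)):
        code[arr == b] = c
    bad = code < 0
    code[bad] = 0
    view = np.lib.stride_tricks.sliding_window_view(code, k)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    packed = view @ weights
    bad_win = np.lib.stride_tricks.sliding_window_view(bad, k).any(axis=1)
    packed[bad_win] = -1
    return packed


def count_motif_windows(
    seq: str,
    motif: str,
    window_size: int = 50_000,
    max_mismatch: int = 0,
    chrom: str = "",
    chunk: int = 200_000,
) -> WindowTrack:
    """Count motif occurrences per non-overlapping window, on both strands
    (forward motif + its reverse complement), allowing <= ``max_mismatch``
    mismatches; overlapping occurrences count at distinct start positions."""
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    motif = motif.upper()
    arr = _encode(seq)
    n = len(arr)
    L = len(motif)
    patterns = [_encode(motif)]
    rc = _encode(revcomp(motif))
    if not np.array_equal(rc, patterns[0]):
        patterns.append(rc)

    starts = np.zeros(max(n - L + 1, 0), dtype=np.int64)
    for pat in patterns:
        # chunked sliding comparison keeps the temporary small
        for lo in range(0, n - L + 1, chunk):
            hi = min(lo + chunk, n - L + 1)
            view = np.lib.stride_tricks.sliding_window_view(arr[lo : hi + L - 1], L)
            mism = (view != pat).sum(axis=1)
            starts[lo:hi] += mism <= max_mismatch
    n_win = math.ceil(n / window_size)
    values = np.zeros(n_win)
    if len(starts):
        win_of_start = np.arange(len(starts)) // window_size
        np.add.at(values, win_of_start, starts)
    return WindowTrack(chrom, window_size, values, chrom_length=n)


def _enriched_intervals(
    track: WindowTrack, min_copies: int, merge_gap: int
) -> list[tuple[GenomicInterval, int]]:
    hot = np.flatnonzero(np.nan_to_num(track.values) >= min_copies)
    if len(hot) == 0:
        return []
    groups: list[list[int]] = [[int(hot[0])]]
    for w in hot[1:]:
        if w - groups[-1][-1] <= merge_gap + 1:
            groups[-1].append(int(w))
        else:
            groups.append([int(w)])
    out = []
    for g in groups:
        iv = GenomicInterval(
            track.chrom,
            g[0] * track.window_size,
            min(
                (g[-1] + 1) * track.window_size,
                track.chrom_length or (g[-1] + 1) * track.window_size,
            ),
        )
        total = int(np.nansum(track.values[g[0] : g[-1] + 1]))
        out.append((iv, total))
    return out


def call_centromeres(
    track: WindowTrack,
    monomer: str,
    min_copies: int = 20,
    merge_gap: int = 1,
    one_per_chrom: bool = True,
) -> list[RepeatAnnotation]:
    """Windows with >= ``min_copies`` monomer matches, merged across small
    gaps; with ``one_per_chrom`` the strongest interval is primary and the
    rest are flagged secondary."""
    merged = _enriched_intervals(track, min_copies, merge_gap)
    if not merged:
        return []
    merged.sort(key=lambda t: -t[1])
    out = []
    for rank, (iv, total) in enumerate(merged):
        out.append(
            RepeatAnnotation(
                kind="centromere",
                interval=iv,
                copy_count=total,
                motif=monomer,
                secondary=one_per_chrom and rank > 0,
            )
        )
    out.sort(key=lambda a: a.interval.start)
    return out


def call_telomeres(
    track: WindowTrack,
    motif: str = "TTAGGG",
    min_copies: int = 100,
    terminal_margin: int = 2,
) -> list[RepeatAnnotation]:
    """Telomere-motif-enriched intervals, classified ``telomere_terminal``
    when within ``terminal_margin`` windows of a chromosome end, else
    ``ITR``."""
    merged = _enriched_intervals(track, min_copies, merge_gap=1)
    length = track.chrom_length or track.n_windows * track.window_size
    margin = terminal_margin * track.window_size
    out = []
    for iv, total in merged:
        terminal = iv.start < margin or iv.end > length - margin
        out.append(
            RepeatAnnotation(
                kind="telomere_terminal" if terminal else "ITR",
                interval=iv,
                copy_count=total,
                motif=motif,
            )
        )
    return out


def _xdrop_extend(
    arr: np.ndarray,
    comp: np.ndarray,
    a1s: int,
    a1e: int,
    a2s: int,
    a2e: int,
    match: int = 1,
    mismatch: int = -3,
    xdrop: int = 15,
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of an inverted arm pair, outward (left of
    arm1 / right of arm2) and inward (toward the spacer), keeping the arms
    equal length."""
    n = len(arr)
    # outward
    score = best = best_t = 0
    t = 0
    while a1s - 1 - t >= 0 and a2e + t < n:
        score += match if arr[a1s - 1 - t] == comp[arr[a2e + t]] else mismatch
        if score > best:
            best, best_t = score, t + 1
        if score < best - xdrop:
            break
        t += 1
    a1s -= best_t
    a2e += best_t
    # inward (spacer must stay non-negative)
    score = best = best_t = 0
    t = 0
    while a1e + t < a2s - t:
        score += match if arr[a1e + t] == comp[arr[a2s - 1 - t]] else mismatch
        if score > best:
            best, best_t = score, t + 1
        if score < best - xdrop:
            break
        t += 1
    a1e += best_t
    a2s -= best_t
    return a1s, a1e, a2s, a2e


def find_palindromes(
    seq: str,
    k: int = 21,
    min_arm: int = 2_000,
    max_spacer: int = 50_000,
    min_identity: float = 0.9,
    max_seed_gap: int = 500,
    chrom: str = "",
) -> list[PalindromeCall]:
    """Detect large inverted repeats (palindromes) by inverted k-mer seeding.

    Exact k-mer matches between the sequence and its own reverse complement
    lie on anti-diagonals (constant i + j) of the self-comparison; runs of
    seeds on one anti-diagonal are chained into arm pairs, arm identity is
    computed by gap-free column comparison of arm1 vs revcomp(arm2), and
    calls are filtered by arm length, spacer and identity.  Overlapping
    calls are merged keeping the longest.
    """
    if k > min_arm:
        raise ValueError("k must not exceed min_arm")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packed)")
    n = len(seq)
    if n < 2 * min_arm:
        return []
    seq = seq.upper()

    fwd_codes = _kmer_codes(seq, k)
    rc_codes = _kmer_codes(revcomp(seq), k)

    # seeds: (i, j) with seq[i:i+k] == revcomp(seq[j:j+k]), i < j;
    # grouped by anti-diagonal d = i + j of the self-comparison dot plot
    shared = np.intersect1d(
        fwd_codes[fwd_codes >= 0], rc_codes[rc_codes >= 0]
    )
    antidiag: dict[int, list[int]] = defaultdict(list)
    if len(shared):
        fwd_hit = np.isin(fwd_codes, shared)
        rc_hit = np.isin(rc_codes, shared)
        fwd_pos: dict[int, list[int]] = defaultdict(list)
        for i in np.flatnonzero(fwd_hit):
            fwd_pos[int(fwd_codes[i])].append(int(i))
        for p in np.flatnonzero(rc_hit):
            j = n - int(p) - k  # forward-strand start of this rc k-mer
            for i in fwd_pos[int(rc_codes[p])]:
                if i + k <= j:
                    antidiag[i + j].append(i)

    arr = _encode(seq)
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y

    candidates: list[PalindromeCall] = []
    for d, starts in antidiag.items():
        starts = sorted(set(starts))
        run = [starts[0]]
        runs = []
        for i in starts[1:]:
            if i - run[-1] <= max_seed_gap:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for r in runs:
            if r[-1] - r[0] + k < min_arm // 2:
                continue
            a1s, a1e = r[0], r[0] + (r[-1] - r[0] + k)
            a2s, a2e = d - r[-1], d - r[0] + k
            a1s, a1e, a2s, a2e = _xdrop_extend(arr, comp, a1s, a1e, a2s, a2e)
            arm_len = a1e - a1s
            if arm_len < min_arm:
                continue
            spacer = a2s - a1e
            if spacer < 0 or spacer > max_spacer:
                continue
            a1 = GenomicInterval(chrom or "seq", a1s, a1e)
            a2 = GenomicInterval(chrom or "seq", a2s, a2e)
            s1 = seq[a1s:a1e]
            s2 = revcomp(seq[a2s:a2e])
            identity = sum(x == y for x, y in zip(s1, s2)) / arm_len
            if identity < min_identity:
                continue
            candidates.append(PalindromeCall(a1, a2, spacer, float(identity)))

    # merge overlapping calls, longest first
    candidates.sort(key=lambda c: -c.total_length)
    kept: list[PalindromeCall] = []
    for c in candidates:
        span = (c.arm1.start, c.arm2.end)
        if any(
            span[0] < k2.arm2.end and k2.arm1.start < span[1] for k2 in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.arm1.start)
    return kept
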