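"""Evolutionary-strata analysis: order W scaffolds along the Z, compute
windowed W/Z divergence, and segment the divergence series into strata by
optimal least-squares changepoint detection (exact dynamic programming,
model order selected by BIC).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core_io import AlignmentBlock, GenomicInterval


@dataclass
class WPlacement:
    scaffold: str
    z_start: int
    z_end: int
    score: float  # summed matches at the winning locus
    placed: bool


@dataclass
class DivergenceTrack:
    """Per-window W/Z divergence along the Z, with the contributing W
    scaffold recorded per window.  NaN marks windows without alignment."""

    z_chrom: str
    window_size: int
    divergence: np.ndarray
    scaffold: list[str | None]
    z_length: int


@dataclass
class Stratum:
    index: int  # 0 = oldest (highest divergence)
    z_interval: GenomicInterval
    mean_divergence: float
    scaffolds: list[str] = field(default_factory=list)


def place_w_on_z(
    blocks: list[AlignmentBlock],
    min_unique_margin: float = 1.2,
    locus_gap: int = 100_000,
) -> list[WPlacement]:
    """Place each W scaffold at its best-supported Z location.

    Blocks of one scaffold are clustered into candidate loci (Z gaps >
    ``locus_gap`` split loci); a scaffold is placed only when its best
    locus outscores the runner-up by ``min_unique_margin`` (summed matches).
    Placed scaffolds are returned ordered by Z coordinate, then unplaced.
    """
    targets = {b.target_chrom for b in blocks}
    if len(targets) > 1:
        raise ValueError("blocks must share one Z target")
    by_scaf: dict[str, list[AlignmentBlock]] = defaultdict(list)
    for b in blocks:
        by_scaf[b.query_chrom].append(b)

    placements = []
    for scaf, bs in by_scaf.items():
        bs = sorted(bs, key=lambda b: b.target_start)
        loci: list[list[AlignmentBlock]] = [[bs[0]]]
        for b in bs[1:]:
            if b.target_start - loci[-1][-1].target_end > locus_gap:
                loci.append([b])
            else:
                loci[-1].append(b)
        scores = sorted(
            ((sum(b.matches for b in locus), locus) for locus in loci),
            key=lambda t: -t[0],
        )
        best_score, best_locus = scores[0]
        unique = len(scores) == 1 or (
            scores[1][0] > 0 and best_score / scores[1][0] >= min_unique_margin
        ) or scores[1][0] == 0
        placements.append(
            WPlacement(
                scaffold=scaf,
                z_start=min(b.target_start for b in best_locus),
                z_end=max(b.target_end for b in best_locus),
                score=best_score,
                placed=unique,
            )
        )
    placed = sorted((p for p in placements if p.placed), key=lambda p: p.z_start)
    unplaced = [p for p in placements if not p.placed]
    return placed + unplaced


def windowed_divergence(
    blocks: list[AlignmentBlock],
    z_length: int,
    window_size: int = 10_000,
    min_aligned: int = 1_000,
) -> DivergenceTrack:
    """Per-Z-window divergence = 1 - sum(matches)/sum(aligned columns).

    Block contributions are apportioned pro-rata by overlap length, so the
    track is invariant to splitting a block into adjacent pieces.  Windows
    with fewer than ``min_aligned`` aligned bases are missing.
    """
    z_chroms = {b.target_chrom for b in blocks}
    if len(z_chroms) > 1:
        raise ValueError("blocks must share one Z target")
    z_chrom = z_chroms.pop() if z_chroms else ""
    n_win = math.ceil(z_length / window_size)
    aligned = np.zeros(n_win)
    matched = np.zeros(n_win)
    scaf_aligned: list[dict[str, float]] = [defaultdict(float) for _ in range(n_win)]
    for b in blocks:
        first = b.target_start // window_size
        last = (b.target_end - 1) // window_size
        span = b.target_end - b.target_start
        for w in range(first, last + 1):
            lo = max(b.target_start, w * window_size)
            hi = min(b.target_end, (w + 1) * window_size)
            frac = (hi - lo) / span
            aligned[w] += b.aln_len * frac
            matched[w] += b.matches * frac
            scaf_aligned[w][b.query_chrom] += b.aln_len * frac
    div = np.full(n_win, np.nan)
    ok = aligned >= min_aligned
    div[ok] = 1.0 - matched[ok] / aligned[ok]
    scaffold = [
        max(d, key=d.get) if ok[w] and d else None
        for w, d in enumerate(scaf_aligned)
    ]
    return DivergenceTrack(z_chrom, window_size, div, scaffold, z_length)


def _segment_dp(
    y: np.ndarray, k: int, min_seg: int
) -> tuple[list[tuple[int, int]], float]:
    """Exact optimal k-segmentation of a 1D series minimizing within-segment
    sum of squares, each segment >= ``min_seg`` points.  Returns half-open
    index segments and the total RSS."""
    n = len(y)
    if k * min_seg > n:
        raise ValueError(f"k={k} infeasible for {n} points (min {min_seg}/segment)")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for seg in range(1, k + 1):
        lo = (seg - 1) * min_seg
        for j in range(seg * min_seg, n + 1):
            i = np.arange(lo, j - min_seg + 1)
            s = c1[j] - c1[i]
            sse = (c2[j] - c2[i]) - s * s / (j - i)
            total = cost[seg - 1, i] + sse
            best = int(np.argmin(total))
            if np.isfinite(total[best]):
                cost[seg, j] = total[best]
                back[seg, j] = lo + best
    bounds = [n]
    j = n
    for seg in range(k, 0, -1):
        j = back[seg, j]
        bounds.append(j)
    bounds.reverse()
    segments = [(bounds[i], bounds[i + 1]) for i in range(k)]
    return segments, float(cost[k, n])


def segment_strata(
    track: DivergenceTrack,
    k: int | str = "auto",
    min_seg_windows: int = 5,
    k_max: int = 8,
) -> list[Stratum]:
    """Segment the divergence series into strata.

    Missing windows are skipped (the DP runs on the compacted series);
    ``k='auto'`` selects the number of strata by BIC.  Strata are indexed by
    descending mean divergence (S0 = oldest); member scaffolds are assigned
    by majority of their windows' stratum labels.
    """
    defined_idx = np.flatnonzero(~np.isnan(track.divergence))
    y = track.divergence[defined_idx]
    n = len(y)
    if n == 0:
        raise ValueError("divergence track has no defined windows")

    if k == "auto":
        best = None
        for kk in range(1, min(k_max, n // min_seg_windows) + 1):
            segs, rss = _segment_dp(y, kk, min_seg_windows)
            # Gaussian BIC, 3 parameters per segment (mean, boundary,
            # variance share): the heavier changepoint penalty guards
            # against splitting on adjacent noise outliers
            bic = n * math.log(max(rss, 1e-12) / n) + 3 * kk * math.log(n)
            if best is None or bic < best[0]:
                best = (bic, segs)
        segs = best[1]
    else:
        if not isinstance(k, int) or k < 1:
            raise ValueError("k must be a positive integer or 'auto'")
        segs, _ = _segment_dp(y, k, min_seg_windows)

    ws = track.window_size
    raw = []
    for lo, hi in segs:
        win_lo = int(defined_idx[lo])
        win_hi = int(defined_idx[hi - 1]) + 1
        iv = GenomicInterval(
            track.z_chrom or "Z",
            win_lo * ws,
            min(win_hi * ws, track.z_length),
        )
        members: dict[str, int] = defaultdict(int)
        for w in defined_idx[lo:hi]:
            s = track.scaffold[w]
            if s is not None:
                members[s] += 1
        raw.append((iv, float(np.mean(y[lo:hi])), members))

    # index by descending mean divergence: oldest stratum = S0
    order = sorted(range(len(raw)), key=lambda i: -raw[i][1])
    strata = []
    for rank, i in enumerate(order):
        iv, mu, members = raw[i]
        strata.append(Stratum(rank, iv, mu, scaffolds=sorted(members)))
    # a scaffold belongs to the stratum holding the majority of its windows
    scaf_votes: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for rank, i in enumerate(order):
        for s, votes in raw[i][2].items():
            scaf_votes[s][rank] += votes
    for st in strata:
        st.scaffolds = sorted(
            s for s, votes in scaf_votes.items() if max(votes, key=votes.get) == st.index
        )
    return strata
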