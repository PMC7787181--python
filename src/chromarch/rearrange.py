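"""Synteny chaining, inversion calling and outgroup polarization,
breakpoint extraction, and breakpoint/boundary association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_io import AlignmentBlock, GenomicInterval, WindowTrack
from .hic_arch import BoundaryCall


@dataclass
class SyntenyChain:
    blocks: list[AlignmentBlock]
    strand: str
    query_interval: GenomicInterval
    target_interval: GenomicInterval

    @property
    def query_span(self) -> int:
        return len(self.query_interval)


@dataclass(frozen=True)
class Inversion:
    query_interval: GenomicInterval
    target_interval: GenomicInterval
    length: int
    lineage: str = "unpolarized"  # focal / other / unpolarized
    n_blocks: int = 1

    @property
    def marginal(self) -> bool:
        """Single-block calls deserve manual review."""
        return self.n_blocks < 2


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    perm_mean: float
    perm_sd: float
    p_value: float
    n_permutations: int
    seed: int


def chain_synteny(
    blocks: list[AlignmentBlock],
    max_gap: int = 100_000,
    min_block: int = 1_000,
) -> list[SyntenyChain]:
    """Greedily chain strand- and order-consistent blocks along the query.

    Blocks shorter than ``min_block`` on the query are dropped; a chain
    breaks on strand switches or on gaps > ``max_gap`` in either genome.
    Input order does not matter (blocks are sorted by query start).
    """
    qchroms = {b.query_chrom for b in blocks}
    tchroms = {b.target_chrom for b in blocks}
    if len(qchroms) > 1 or len(tchroms) > 1:
        raise ValueError("blocks must come from one chromosome pair")
    kept = sorted(
        (b for b in blocks if b.query_end - b.query_start >= min_block),
        key=lambda b: (b.query_start, b.query_end),
    )
    chains: list[list[AlignmentBlock]] = []
    for b in kept:
        if chains:
            prev = chains[-1][-1]
            q_gap = b.query_start - prev.query_end
            if b.strand == prev.strand and q_gap <= max_gap:
                if b.strand == "+":
                    t_gap = b.target_start - prev.target_end
                    ordered = b.target_start >= prev.target_start
                else:
                    t_gap = prev.target_start - b.target_end
                    ordered = b.target_end <= prev.target_end
                if ordered and -max_gap // 10 <= t_gap <= max_gap:
                    chains[-1].append(b)
                    continue
        chains.append([b])
    out = []
    for ch in chains:
        q0 = min(b.query_start for b in ch)
        q1 = max(b.query_end for b in ch)
        t0 = min(b.target_start for b in ch)
        t1 = max(b.target_end for b in ch)
        out.append(
            SyntenyChain(
                blocks=ch,
                strand=ch[0].strand,
                query_interval=GenomicInterval(ch[0].query_chrom, q0, q1),
                target_interval=GenomicInterval(ch[0].target_chrom, t0, t1),
            )
        )
    return out


def call_inversions(chains: list[SyntenyChain], min_len: int = 10_000) -> list[Inversion]:
    """Every reverse-strand chain with query span >= ``min_len``, flanked by
    forward chains or chromosome ends, is an inversion call; consecutive
    reverse chains are reported individually."""
    ordered = sorted(chains, key=lambda c: c.query_interval.start)
    out = []
    for c in ordered:
        if c.strand != "-" or c.query_span < min_len:
            continue
        out.append(
            Inversion(
                query_interval=c.query_interval,
                target_interval=c.target_interval,
                length=c.query_span,
                n_blocks=len(c.blocks),
            )
        )
    return out


def polarize_inversions(
    inversions: list[Inversion],
    outgroup_blocks: list[AlignmentBlock],
    min_coverage: float = 0.5,
) -> list[Inversion]:
    """Assign each inversion to a lineage by the majority strand of the
    outgroup alignment over its query interval.

    Outgroup '-' (outgroup agrees with species B) -> the inversion happened
    on the focal lineage; outgroup '+' -> it happened on the other lineage;
    coverage below ``min_coverage`` of the interval -> unpolarized.
    """
    out = []
    for inv in inversions:
        iv = inv.query_interval
        cov_plus = cov_minus = 0
        for b in outgroup_blocks:
            if b.query_chrom != iv.chrom:
                continue
            ov = max(0, min(b.query_end, iv.end) - max(b.query_start, iv.start))
            if ov == 0:
                continue
            if b.strand == "+":
                cov_plus += ov
            else:
                cov_minus += ov
        if (cov_plus + cov_minus) / len(iv) < min_coverage:
            lineage = "unpolarized"
        elif cov_minus > cov_plus:
            lineage = "focal"
        elif cov_plus > cov_minus:
            lineage = "other"
        else:
            lineage = "unpolarized"
        out.append(replace(inv, lineage=lineage))
    return out


def breakpoints(
    inversions: list[Inversion],
    pad: int = 0,
    chrom_length: int | None = None,
) -> list[GenomicInterval]:
    """Two intervals per inversion at the query ends (1 bp when pad = 0),
    widened by ``pad`` on both sides and clipped to the chromosome."""
    out = []
    for inv in inversions:
        for p in (inv.query_interval.start, inv.query_interval.end):
            lo = max(0, p - pad)
            hi = p + pad if pad else p + 1
            if chrom_length is not None:
                hi = min(hi, chrom_length)
                lo = min(lo, hi - 1)
            out.append(GenomicInterval(inv.query_interval.chrom, lo, hi))
    return out


def _count_near(points: np.ndarray, anchors: np.ndarray, slack: int) -> int:
    if len(anchors) == 0:
        return 0
    idx = np.searchsorted(anchors, points)
    near = np.zeros(len(points), dtype=bool)
    for shift in (0, 1):
        j = np.clip(idx - shift, 0, len(anchors) - 1)
        near |= np.abs(points - anchors[j]) <= slack
    return int(near.sum())


def breakpoint_boundary_overlap(
    bps: list[GenomicInterval],
    boundaries: list[BoundaryCall],
    slack: int,
    chrom_length: int,
    n_perm: int = 1000,
    seed: int = 0,
    inversions: list[Inversion] | None = None,
) -> tuple[EnrichmentResult, dict[str, int] | None]:
    """Permutation test of breakpoint proximity to TAD boundaries.

    Observed = breakpoints within ``slack`` of any boundary; the null
    re-places the same number of breakpoints uniformly on the chromosome,
    ``n_perm`` times; empirical p = (1 + #{perm >= obs}) / (1 + n_perm).
    When inversions are given, each is classified by how many of its two
    breakpoints hit a boundary ('both' / 'one' / 'neither').
    """
    if not bps:
        raise ValueError("no breakpoints supplied")
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    anchors = np.sort(np.array([b.position for b in boundaries]))
    points = np.array([(iv.start + iv.end) // 2 for iv in bps])
    observed = _count_near(points, anchors, slack)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        rand = rng.integers(0, chrom_length, size=len(points))
        perm[r] = _count_near(rand, anchors, slack)
    p = (1 + int((perm >= observed).sum())) / (1 + n_perm)
    result = EnrichmentResult(
        observed=observed,
        perm_mean=float(perm.mean()),
        perm_sd=float(perm.std()),
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )
    categories = None
    if inversions is not None:
        categories = {"both": 0, "one": 0, "neither": 0}
        for inv in inversions:
            hits = sum(
                _count_near(np.array([p0]), anchors, slack)
                for p0 in (inv.query_interval.start, inv.query_interval.end)
            )
            categories[{2: "both", 1: "one", 0: "neither"}[hits]] += 1
    return result, categories


def _region_values(track: WindowTrack, regions: list[GenomicInterval]) -> np.ndarray:
    ws = track.window_size
    take = np.zeros(track.n_windows, dtype=bool)
    for iv in regions:
        if iv.chrom != track.chrom:
            continue
        first = iv.start // ws
        last = min((iv.end - 1) // ws, track.n_windows - 1)
        take[first : last + 1] = True
    vals = track.values[take]
    return vals[~np.isnan(vals)]


def compare_region_values(
    track: WindowTrack,
    regions_a: list[GenomicInterval],
    regions_b: list[GenomicInterval],
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison (normal approximation, tie-corrected)
    of window values overlapping two disjoint region sets.

    Returns (standardized statistic for group A, two-sided p).
    """
    a = _region_values(track, regions_a)
    b = _region_values(track, regions_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 window values")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    # standardized U (tie-corrected), sign indicates direction of group A
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return float(z), float(res.pvalue)
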