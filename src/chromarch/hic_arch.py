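"""Hi-C architecture: ICE balancing, insulation scores and TAD boundary
calls, A/B compartments, PWM motif scanning, convergent-pair "loop anchor"
detection, boundary annotation, and cross-species boundary sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AlignmentBlock, GenomicInterval, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ContactMatrix:
    """Binned symmetric contact counts for one chromosome.

    ``mask[i]`` is True for bins excluded from all statistics.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(len(self.counts), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class BoundaryCall:
    bin: int
    interval: GenomicInterval
    strength: float

    @property
    def position(self) -> int:
        """Boundary point position (bin midpoint, bp)."""
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    score: float


def ice_normalize(
    m: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction: find diagonal biases B so that B·counts·B has
    equal row sums over unmasked bins.  Bins with zero marginal are masked
    automatically.  Returns the balanced matrix and the bias vector (NaN at
    masked bins)."""
    counts = m.counts.copy()
    mask = m.mask.copy()
    mask |= counts.sum(axis=1) == 0
    if mask.all():
        raise ValueError("no unmasked bins to balance")
    active = ~mask
    w = counts[np.ix_(active, active)]
    bias = np.ones(w.shape[0])
    for _ in range(max_iter):
        s = w.sum(axis=1)
        s = s / s.mean()
        s[s == 0] = 1.0
        bias *= s
        w = w / np.outer(s, s)
        if np.abs(s - 1.0).max() < tol:
            break
    balanced = np.zeros_like(counts)
    balanced[np.ix_(active, active)] = w
    full_bias = np.full(m.n_bins, np.nan)
    full_bias[active] = bias
    return ContactMatrix(m.chrom, m.bin_size, balanced, mask), full_bias


def insulation_score(m: ContactMatrix, window_bins: int) -> np.ndarray:
    """Square insulation score: for each bin i, the mean contact count in
    the w x w square spanning [i-w, i) x (i, i+w], expressed as log2 ratio
    to the chromosomal mean of defined raw scores.  NaN where the square
    leaves the matrix or touches a masked bin."""
    w = window_bins
    n = m.n_bins
    if w < 1 or 2 * w >= n:
        raise ValueError("window must satisfy 1 <= w and 2w < n")
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        if m.mask[i - w : i + w + 1].any():
            continue
        raw[i] = m.counts[i - w : i, i + 1 : i + w + 1].mean()
    defined = ~np.isnan(raw)
    if not defined.any():
        return raw
    mean_raw = raw[defined].mean()
    scores = np.full(n, np.nan)
    with np.errstate(divide="ignore"):
        scores[defined] = np.log2(raw[defined] / mean_raw)
    return scores


def call_tad_boundaries(
    scores: np.ndarray,
    min_strength: float = 0.1,
    chrom: str = "",
    bin_size: int = 1,
) -> list[BoundaryCall]:
    """TAD boundaries = local minima of the insulation track.

    A defined bin is a candidate when it is strictly below its nearest
    defined neighbors (plateaus of equal minima resolve to the central
    bin).  Strength = min over both sides of (nearest local maximum -
    minimum value); candidates below ``min_strength`` are dropped.
    """
    defined_idx = np.flatnonzero(~np.isnan(scores))
    if len(defined_idx) < 3:
        raise ValueError("need at least 3 defined bins")
    v = scores[defined_idx]
    n = len(v)

    calls = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j >= n - 1:
            break
        if v[i - 1] > v[i] and v[j + 1] > v[i]:
            center = (i + j) // 2
            # climb to the nearest local maximum on each side
            left = i - 1
            while left > 0 and v[left - 1] >= v[left]:
                left -= 1
            right = j + 1
            while right < n - 1 and v[right + 1] >= v[right]:
                right += 1
            strength = float(min(v[left] - v[i], v[right] - v[i]))
            if strength >= min_strength:
                b = int(defined_idx[center])
                iv = GenomicInterval(chrom or "chr", b * bin_size, (b + 1) * bin_size)
                calls.append(BoundaryCall(b, iv, strength))
        i = j + 1
    return calls


def boundary_f1(
    called_bins: list[int], true_bins: list[int], tol: int = 1
) -> tuple[float, float, float]:
    """Precision / recall / F1 of called boundary bins vs truth, greedy
    one-to-one matching within ``tol`` bins."""
    remaining = sorted(true_bins)
    tp = 0
    for c in sorted(called_bins):
        hit = next((t for t in remaining if abs(t - c) <= tol), None)
        if hit is not None:
            tp += 1
            remaining.remove(hit)
    precision = tp / len(called_bins) if called_bins else 0.0
    recall = tp / len(true_bins) if true_bins else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def observed_over_expected(m: ContactMatrix) -> np.ndarray:
    """Divide each diagonal by its mean over unmasked entries."""
    n = m.n_bins
    active = ~m.mask
    oe = np.zeros_like(m.counts)
    for d in range(n):
        idx = np.arange(n - d)
        vals = m.counts[idx, idx + d]
        ok = active[idx] & active[idx + d]
        mu = vals[ok].mean() if ok.any() else 0.0
        if mu > 0:
            oe[idx, idx + d] = vals / mu
            oe[idx + d, idx] = vals / mu
    return oe


def ab_compartments(
    m: ContactMatrix,
    orientation: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray | None, bool]:
    """First eigenvector of the O/E Pearson correlation matrix, oriented so
    that bins with above-median orientation-track values load positively.

    Returns (per-bin signed values with NaN at masked bins, per-bin 'A'/'B'
    labels or None when degenerate, degenerate flag).
    """
    active = np.flatnonzero(~m.mask)
    if len(active) < 10:
        raise ValueError("need >= 10 unmasked bins")
    oe = observed_over_expected(m)[np.ix_(active, active)]
    sd = oe.std(axis=1)
    if (sd == 0).all():
        return np.full(m.n_bins, np.nan), None, True
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    # power iteration, deterministic all-ones start
    vec = np.ones(len(active))
    vec /= np.linalg.norm(vec)
    lam = 0.0
    for _ in range(max_iter):
        nxt = corr @ vec
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return np.full(m.n_bins, np.nan), None, True
        nxt /= norm
        if np.abs(nxt - vec).max() < tol or np.abs(nxt + vec).max() < tol:
            vec = nxt
            lam = norm
            break
        vec = nxt
        lam = norm
    if lam == 0 or np.allclose(vec, vec[0]):
        # constant eigenvector carries no compartment signal
        return np.full(m.n_bins, np.nan), None, True
    ori = np.asarray(orientation, dtype=float)[active]
    high = ori > np.nanmedian(ori)
    if high.any() and vec[high].mean() < 0:
        vec = -vec
    values = np.full(m.n_bins, np.nan)
    values[active] = vec
    labels = np.full(m.n_bins, "", dtype="<U1")
    labels[active] = np.where(vec >= 0, "A", "B")
    return values, labels, False


def compartment_transitions(labels: np.ndarray, bin_size: int = 1) -> list[int]:
    """Positions (bp) between adjacent labeled bins whose A/B label flips."""
    out = []
    prev = None
    for i, lab in enumerate(labels):
        if lab not in ("A", "B"):
            continue
        if prev is not None and lab != prev[1]:
            out.append((i) * bin_size)
        prev = (i, lab)
    return out


# ---------------------------------------------------------------------------
# PWM scanning


def _pwm_logodds(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must sum to 1")
    if (pwm == 0).any():
        pwm = pwm + 1e-3
        pwm = pwm / pwm.sum(axis=0)
    return np.log2(pwm / background[:, None])


def scan_pwm(
    seq: str,
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    threshold: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands with a probability PWM; report hits whose log-odds
    score is >= ``threshold`` x the maximum attainable score.  N bases score
    0 (background).  Positions are 0-based starts on the forward strand."""
    if background is None:
        background = np.full(4, 0.25)
    lo = _pwm_logodds(pwm, np.asarray(background, dtype=float))
    L = lo.shape[1]
    max_score = lo.max(axis=0).sum()
    cutoff = threshold * max_score
    seq = seq.upper()
    n = len(seq)
    if n < L:
        return []
    enc = np.full(n, 4, dtype=np.int8)  # 4 = N / other
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, k in _BASE_INDEX.items():
        enc[arr == ord(base)] = k
    lo5 = np.vstack([lo, np.zeros(lo.shape[1])])  # row 4: N contributes 0
    # strided scoring: sum of per-column lookups
    fwd = np.zeros(n - L + 1)
    rev_lo = lo5[[3, 2, 1, 0, 4], ::-1]  # reverse-complement PWM (N row fixed)
    rev = np.zeros(n - L + 1)
    for j in range(L):
        col = enc[j : j + n - L + 1]
        fwd += lo5[col, j]
        rev += rev_lo[col, j]
    hits = [
        MotifHit(int(p), "+", float(fwd[p])) for p in np.flatnonzero(fwd >= cutoff)
    ] + [
        MotifHit(int(p), "-", float(rev[p])) for p in np.flatnonzero(rev >= cutoff)
    ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def convergent_pairs(
    hits: list[MotifHit], max_span: int
) -> list[tuple[MotifHit, MotifHit]]:
    """All (+, -) hit pairs with the + hit upstream and span <= max_span."""
    plus = [h for h in hits if h.strand == "+"]
    minus = [h for h in hits if h.strand == "-"]
    out = []
    for p in plus:
        for q in minus:
            if p.position < q.position and q.position - p.position <= max_span:
                out.append((p, q))
    return out


def annotate_boundaries(
    boundaries: list[BoundaryCall],
    ctcf_hits: list[MotifHit],
    housekeeping_intervals: list[GenomicInterval],
    transitions: list[int],
    flank: int = 10_000,
) -> tuple[list[tuple[bool, bool, bool]], dict[tuple[bool, bool, bool], int]]:
    """Flag each boundary for nearby CTCF hit / housekeeping gene /
    compartment transition, and tally all 2^3 overlap classes."""
    ctcf_pos = np.array([h.position for h in ctcf_hits]) if ctcf_hits else np.array([])
    flags = []
    counts: dict[tuple[bool, bool, bool], int] = {
        (a, b, c): 0 for a in (False, True) for b in (False, True) for c in (False, True)
    }
    for b in boundaries:
        pos = b.position
        has_ctcf = bool(len(ctcf_pos)) and bool(
            (np.abs(ctcf_pos - pos) <= flank).any()
        )
        has_hk = any(
            iv.start - flank <= pos < iv.end + flank for iv in housekeeping_intervals
        )
        has_tr = any(abs(t - pos) <= flank for t in transitions)
        f = (has_ctcf, has_hk, has_tr)
        flags.append(f)
        counts[f] += 1
    return flags, counts


def project_position(pos: int, blocks: list[AlignmentBlock]) -> tuple[str, int] | None:
    """Project a query position to target coordinates through the covering
    synteny block (linear interpolation, strand-aware); None in gaps."""
    for b in blocks:
        if b.query_start <= pos < b.query_end:
            frac = (pos - b.query_start) / (b.query_end - b.query_start)
            if b.strand == "+":
                t = b.target_start + frac * (b.target_end - b.target_start)
            else:
                t = b.target_end - frac * (b.target_end - b.target_start)
            return b.target_chrom, int(round(t))
    return None


def boundary_sharing(
    boundaries_a: list[BoundaryCall],
    boundaries_b: list[BoundaryCall],
    coordinate_map: list[AlignmentBlock],
    slack_bins: int = 1,
    bin_size: int = 10_000,
) -> tuple[float, list[tuple[BoundaryCall, BoundaryCall]], int]:
    """Fraction of A boundaries shared with B after projecting A through the
    synteny map.  A projected boundary is shared when a B boundary on the
    projected chromosome lies within ``slack_bins * bin_size``.  Boundaries
    falling in unaligned gaps are excluded from the denominator.

    Returns (shared fraction, matched pairs, number projectable).
    """
    matched = []
    n_proj = 0
    for ba in boundaries_a:
        proj = project_position(ba.position, coordinate_map)
        if proj is None:
            continue
        n_proj += 1
        chrom, pos = proj
        best = None
        for bb in boundaries_b:
            if bb.interval.chrom != chrom:
                continue
            d = abs(bb.position - pos)
            if d <= slack_bins * bin_size and (best is None or d < best[0]):
                best = (d, bb)
        if best is not None:
            matched.append((ba, best[1]))
    frac = len(matched) / n_proj if n_proj else 0.0
    return frac, matched, n_proj
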