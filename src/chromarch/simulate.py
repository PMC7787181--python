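"""Synthetic genomes with planted, recorded truth.

Generates toy genomes (macro/micro autosomes, a Z with a terminal PAR, a W
derived from the Z at planted divergence levels), sexed depth tracks,
pairwise alignment blocks with planted inversions, Hi-C contact matrices
with planted TADs and compartments, and expression matrices — everything an
analysis stage needs, with the ground truth recorded for recovery tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import AlignmentBlock, GenomicInterval, WindowTrack, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Knobs for every generator; ``seed`` fixes every draw."""

    seed: int = 0
    # genome layout
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000),
        ("chr2", 2_000_000),
        ("chr3", 500_000),
        ("chr4", 500_000),
        ("chrZ", 1_500_000),
    )
    z_name: str = "chrZ"
    w_name: str = "chrW"
    par_len: int = 100_000
    strata_divergences: tuple[float, ...] = (0.24, 0.16, 0.09, 0.03)
    w_segment_len: int = 150_000
    w_scaffolds_per_stratum: int = 2
    # depth model
    mean_depth: float = 30.0
    depth_dispersion: float = 0.1
    depth_window: int = 5_000
    read_len: int = 150
    # Hi-C model
    hic_bin_size: int = 10_000
    hic_decay_exponent: float = 1.0
    hic_scale: float = 300.0
    tad_enrichment: float = 3.0
    tad_size_bins: tuple[int, int] = (20, 60)
    compartment_strength: float = 0.5
    compartment_size_bins: tuple[int, int] = (20, 50)
    # alignment / divergence model
    aln_block_len: int = 5_000
    divergence_window: int = 10_000
    divergence_noise_sd: float = 0.02
    background_identity: float = 0.95
    inversions: tuple[tuple[str, int, int, str], ...] = (
        ("chr1", 200_000, 400_000, "focal"),
        ("chr1", 700_000, 760_000, "other"),
        ("chr1", 1_200_000, 1_220_000, "focal"),
        ("chr2", 100_000, 150_000, "focal"),
        ("chr2", 900_000, 1_100_000, "other"),
        ("chr2", 1_600_000, 1_640_000, "focal"),
    )
    # repeat / palindrome planting
    monomer_len: int = 190
    telomere_motif: str = "TTAGGG"
    centromere_array_len: int = 40_000
    telomere_array_len: int = 3_000
    palindrome_arm_len: int = 3_000
    spacer_len: int = 1_000
    palindrome_arm_divergence: float = 0.02
    n_palindromes: int = 2

    def __post_init__(self):
        for name, v in (
            ("mean_depth", self.mean_depth),
            ("depth_dispersion", self.depth_dispersion),
            ("hic_decay_exponent", self.hic_decay_exponent),
            ("tad_enrichment", self.tad_enrichment),
            ("palindrome_arm_len", self.palindrome_arm_len),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.compartment_strength < 0 or self.divergence_noise_sd < 0:
            raise ValueError("strength/noise parameters must be non-negative")


@dataclass
class WScaffold:
    """A simulated W scaffold: where it came from on Z, and its divergence."""

    name: str
    w_interval: GenomicInterval
    z_interval: GenomicInterval
    stratum: int
    divergence: float


@dataclass
class SyntheticTruth:
    """Every planted feature, for recovery tests."""

    chrom_lengths: dict[str, int]
    sex_copy: dict[str, tuple[int, int]]  # chrom -> (male copies, female copies)
    par_interval: GenomicInterval | None = None
    strata: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    w_scaffolds: list[WScaffold] = field(default_factory=list)
    tads: dict[str, list[tuple[int, int]]] = field(default_factory=dict)  # bin intervals
    compartments: dict[str, np.ndarray] = field(default_factory=dict)  # 'A'/'B' per bin
    inversions: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    centromeres: list[GenomicInterval] = field(default_factory=list)
    telomeres: list[GenomicInterval] = field(default_factory=list)
    itrs: list[GenomicInterval] = field(default_factory=list)
    palindromes: list[tuple[GenomicInterval, GenomicInterval, float]] = field(
        default_factory=list
    )
    monomer: str = ""

    def tad_boundaries(self, chrom: str) -> list[int]:
        """Interior TAD boundary bins (junction = first bin of the next TAD)."""
        tads = self.tads.get(chrom, [])
        return [start for start, _ in tads[1:]]


def _rng(params: SimParams, tag: str) -> np.random.Generator:
    return np.random.default_rng((params.seed, zlib.crc32(tag.encode())))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``
    (always to a different base; no indels)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    if len(idx):
        # shift within the 3 alternative bases
        base_idx = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(base_idx + rng.integers(1, 4, size=len(idx))) % 4]
    return arr.tobytes().decode()


def _plant(seq_arr: bytearray, pos: int, insert: str) -> None:
    seq_arr[pos : pos + len(insert)] = insert.encode()


def _tile_blocks(
    rng: np.random.Generator, n_bins: int, size_range: tuple[int, int]
) -> list[tuple[int, int]]:
    out, pos = [], 0
    while pos < n_bins:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        out.append((pos, min(pos + size, n_bins)))
        pos += size
    # avoid a terminal sliver shorter than half the minimum
    if len(out) > 1 and out[-1][1] - out[-1][0] < size_range[0] // 2:
        out[-2] = (out[-2][0], out[-1][1])
        out.pop()
    return out


def simulate_genome(params: SimParams) -> tuple[dict[str, str], SyntheticTruth]:
    """Build the toy genome and its complete truth record.

    The W is derived from the Z by copy-and-mutate, one segment per stratum,
    so Z/W divergence equals the planted level exactly in expectation;
    centromeric monomer arrays, telomeric arrays, ITRs and W palindromes are
    planted verbatim.  Deterministic under a fixed seed.
    """
    rng = _rng(params, "genome")
    chrom_lengths = dict(params.chrom_lengths)
    z = params.z_name
    if z not in chrom_lengths:
        raise ValueError(f"{z} missing from chrom_lengths")
    z_len = chrom_lengths[z]
    if params.par_len >= z_len:
        raise ValueError("PAR exceeds Z length")

    seqs = {c: bytearray(_random_seq(rng, n).encode()) for c, n in chrom_lengths.items()}
    truth = SyntheticTruth(chrom_lengths=chrom_lengths, sex_copy={})
    for c in chrom_lengths:
        truth.sex_copy[c] = (2, 1) if c == z else (2, 2)

    # --- PAR and strata on Z
    truth.par_interval = GenomicInterval(z, 0, params.par_len)
    sdr_len = z_len - params.par_len
    k = len(params.strata_divergences)
    stratum_len = sdr_len // k
    if params.w_segment_len > stratum_len:
        raise ValueError("w_segment_len exceeds stratum length")
    for i, d in enumerate(params.strata_divergences):
        s0 = params.par_len + i * stratum_len
        s1 = z_len if i == k - 1 else s0 + stratum_len
        truth.strata.append((GenomicInterval(z, s0, s1), d))

    # --- monomer and repeat arrays
    monomer = _random_seq(rng, params.monomer_len)
    truth.monomer = monomer
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        if chrom != z:
            # telomeric arrays at both ends
            n_copies = params.telomere_array_len // len(params.telomere_motif)
            array = params.telomere_motif * n_copies
            _plant(seqs[chrom], 0, array)
            truth.telomeres.append(GenomicInterval(chrom, 0, len(array)))
            _plant(seqs[chrom], length - len(array), array)
            truth.telomeres.append(
                GenomicInterval(chrom, length - len(array), length)
            )
        # centromeric monomer array mid-chromosome
        n_copies = params.centromere_array_len // params.monomer_len
        array = (monomer * n_copies)[: n_copies * params.monomer_len]
        mid = length // 2
        _plant(seqs[chrom], mid, array)
        truth.centromeres.append(GenomicInterval(chrom, mid, mid + len(array)))
    # one interstitial telomeric array on chr-2-like position
    itr_chrom = next(iter(chrom_lengths))
    n_copies = params.telomere_array_len // len(params.telomere_motif)
    array = params.telomere_motif * n_copies
    itr_pos = chrom_lengths[itr_chrom] // 4
    _plant(seqs[itr_chrom], itr_pos, array)
    truth.itrs.append(GenomicInterval(itr_chrom, itr_pos, itr_pos + len(array)))

    # --- W: copy-and-mutate one segment per stratum
    w_parts: list[str] = []
    w_pos = 0
    z_seq = seqs[z].decode()
    for i, (ziv, d) in enumerate(truth.strata):
        src = GenomicInterval(z, ziv.start, ziv.start + params.w_segment_len)
        segment = _mutate(z_seq[src.start : src.end], d, rng)
        n_scaf = params.w_scaffolds_per_stratum
        piece = len(segment) // n_scaf
        for j in range(n_scaf):
            lo = j * piece
            hi = len(segment) if j == n_scaf - 1 else (j + 1) * piece
            truth.w_scaffolds.append(
                WScaffold(
                    name=f"w_s{i}_{j}",
                    w_interval=GenomicInterval(params.w_name, w_pos + lo, w_pos + hi),
                    z_interval=GenomicInterval(z, src.start + lo, src.start + hi),
                    stratum=i,
                    divergence=d,
                )
            )
        w_parts.append(segment)
        w_pos += len(segment)

    # --- palindromes on a dedicated W tail
    pal_region_len = params.n_palindromes * (
        2 * params.palindrome_arm_len + params.spacer_len + 20_000
    )
    tail = bytearray(_random_seq(rng, pal_region_len).encode())
    offset = 10_000
    for _ in range(params.n_palindromes):
        arm1 = _random_seq(rng, params.palindrome_arm_len)
        arm2 = _mutate(revcomp(arm1), params.palindrome_arm_divergence, rng)
        a1 = offset
        a2 = a1 + params.palindrome_arm_len + params.spacer_len
        _plant(tail, a1, arm1)
        _plant(tail, a2, arm2)
        identity = np.mean(
            [x == y for x, y in zip(arm1, revcomp(arm2))]
        )
        truth.palindromes.append(
            (
                GenomicInterval(params.w_name, w_pos + a1, w_pos + a1 + len(arm1)),
                GenomicInterval(params.w_name, w_pos + a2, w_pos + a2 + len(arm2)),
                float(identity),
            )
        )
        offset = a2 + params.palindrome_arm_len + 20_000
    w_parts.append(tail.decode())
    w_seq = "".join(w_parts)
    chrom_lengths[params.w_name] = len(w_seq)
    truth.sex_copy[params.w_name] = (0, 1)
    seqs[params.w_name] = bytearray(w_seq.encode())

    # --- inversions
    for chrom, start, end, lineage in params.inversions:
        if end > chrom_lengths[chrom]:
            raise ValueError(f"inversion exceeds {chrom} length")
        truth.inversions.append((GenomicInterval(chrom, start, end), lineage))

    # --- Hi-C truth: TAD tiling + compartment blocks per chromosome
    rng_hic = _rng(params, "hic-truth")
    for chrom, length in chrom_lengths.items():
        if chrom == params.w_name:
            continue
        n_bins = math.ceil(length / params.hic_bin_size)
        truth.tads[chrom] = _tile_blocks(rng_hic, n_bins, params.tad_size_bins)
        comp = np.empty(n_bins, dtype="<U1")
        label = "A"
        for lo, hi in _tile_blocks(rng_hic, n_bins, params.compartment_size_bins):
            comp[lo:hi] = label
            label = "B" if label == "A" else "A"
        truth.compartments[chrom] = comp

    return {c: s.decode() for c, s in seqs.items()}, truth


def make_scaffold_cohort(
    params: SimParams,
    n_autosomal: int = 20,
    n_z: int = 20,
    n_w: int = 20,
    min_len: int = 50_000,
    max_len: int = 150_000,
) -> SyntheticTruth:
    """A truth record of many independent scaffolds with known sex-linkage
    (no sequences) — input for depth simulation and classifier benchmarks."""
    rng = _rng(params, "cohort")
    truth = SyntheticTruth(chrom_lengths={}, sex_copy={})
    spec = [("auto", n_autosomal, (2, 2)), ("z", n_z, (2, 1)), ("w", n_w, (0, 1))]
    for prefix, n, copies in spec:
        for i in range(n):
            name = f"{prefix}_scaf{i}"
            length = int(rng.integers(min_len, max_len + 1))
            truth.chrom_lengths[name] = length
            truth.sex_copy[name] = copies
    return truth


def simulate_depth(
    truth: SyntheticTruth,
    params: SimParams,
    sex: str,
    window_size: int | None = None,
) -> dict[str, WindowTrack]:
    """Per-chromosome window depth (depth-per-bp proxy), marginally
    negative-binomial with mean ``mean_depth * copies / 2`` and dispersion
    ``depth_dispersion``; PAR windows on Z are diploid in both sexes.

    The overdispersion is realized as a per-window Gamma factor SHARED
    between the sexes (mappability/GC bias of the common assembly) times
    per-sex Poisson read sampling, so — as in real data — the bias largely
    cancels in M/F ratios while each sex's marginal stays NB.
    ``sex`` is 'M' or 'F'.
    """
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    window_size = window_size or params.depth_window
    rng = _rng(params, f"depth-{sex}-{window_size}")
    rng_bias = _rng(params, f"depth-bias-{window_size}")  # same for both sexes
    a = params.depth_dispersion
    tracks: dict[str, WindowTrack] = {}
    for chrom, length in truth.chrom_lengths.items():
        if chrom not in truth.sex_copy:
            raise ValueError(f"no sex_copy entry for {chrom}")
        copies_m, copies_f = truth.sex_copy[chrom]
        copies = copies_m if sex == "M" else copies_f
        n_win = math.ceil(length / window_size)
        widths = np.full(n_win, window_size, dtype=float)
        if length % window_size:
            widths[-1] = length % window_size
        bias = rng_bias.gamma(shape=1.0 / a, scale=a, size=n_win)
        copy_vec = np.full(n_win, copies, dtype=float)
        par = truth.par_interval
        if par is not None and par.chrom == chrom:
            first = par.start // window_size
            last = (par.end - 1) // window_size
            copy_vec[first : last + 1] = 2.0
        # expected reads per window; depth value = reads * read_len / width
        lam = params.mean_depth * (copy_vec / 2.0) * bias * widths / params.read_len
        values = rng.poisson(lam) * params.read_len / widths
        tracks[chrom] = WindowTrack(chrom, window_size, values, chrom_length=length)
    return tracks


def simulate_hic(truth: SyntheticTruth, params: SimParams, chrom: str) -> np.ndarray:
    """Symmetric Poisson-sampled contact matrix with power-law distance decay,
    intra-TAD enrichment, and compartment checkerboard structure."""
    if chrom not in truth.tads:
        raise ValueError(f"no Hi-C truth for {chrom}")
    rng = _rng(params, f"hic-{chrom}")
    n = math.ceil(truth.chrom_lengths[chrom] / params.hic_bin_size)
    tad_id = np.zeros(n, dtype=int)
    for t, (lo, hi) in enumerate(truth.tads[chrom]):
        tad_id[lo:hi] = t
    comp = truth.compartments[chrom]

    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = params.hic_scale * (dist + 1.0) ** (-params.hic_decay_exponent)
    same_tad = tad_id[:, None] == tad_id[None, :]
    expected = expected * np.where(same_tad, params.tad_enrichment, 1.0)
    same_comp = comp[:, None] == comp[None, :]
    expected = expected * (1.0 + params.compartment_strength * same_comp)

    upper = rng.poisson(np.triu(expected))
    counts = upper + np.triu(upper, 1).T
    return counts.astype(float)


def simulate_alignments(
    truth: SyntheticTruth, params: SimParams
) -> tuple[list[AlignmentBlock], list[AlignmentBlock], list[AlignmentBlock]]:
    """Alignment-block inputs for inversion and strata analyses.

    Returns (focal vs species B, focal vs outgroup, W scaffolds vs outgroup
    Z).  Focal-lineage inversions flip strand in both of the first two sets;
    B-lineage inversions flip only focal-vs-B.  W blocks carry identities
    matching each stratum's planted divergence.
    """
    rng = _rng(params, "alignments")

    def _blocks_for(flip_lineages: set[str]) -> list[AlignmentBlock]:
        out = []
        for chrom, length in truth.chrom_lengths.items():
            if truth.sex_copy.get(chrom, (2, 2)) == (0, 1):
                continue  # W has no cross-species autosomal panel here
            invs = [
                iv
                for iv, lineage in truth.inversions
                if iv.chrom == chrom and lineage in flip_lineages
            ]
            for start in range(0, length, params.aln_block_len):
                end = min(start + params.aln_block_len, length)
                host = next(
                    (iv for iv in invs if iv.start <= start and end <= iv.end), None
                )
                aln_len = end - start
                ident = min(
                    1.0,
                    params.background_identity + rng.normal(0, 0.005),
                )
                matches = int(round(aln_len * max(0.0, ident)))
                if host is None:
                    t_start, t_end, strand = start, end, "+"
                else:
                    t_start = host.start + (host.end - end)
                    t_end = host.start + (host.end - start)
                    strand = "-"
                out.append(
                    AlignmentBlock(
                        chrom, start, end, chrom, t_start, t_end, strand,
                        matches, aln_len,
                    )
                )
        return out

    focal_vs_b = _blocks_for({"focal", "other"})
    focal_vs_outgroup = _blocks_for({"focal"})

    w_vs_z: list[AlignmentBlock] = []
    for scaf in truth.w_scaffolds:
        s_len = len(scaf.z_interval)
        for off in range(0, s_len, params.divergence_window):
            end_off = min(off + params.divergence_window, s_len)
            aln_len = end_off - off
            d = scaf.divergence + rng.normal(0, params.divergence_noise_sd)
            matches = int(round(aln_len * min(1.0, max(0.0, 1.0 - d))))
            w_vs_z.append(
                AlignmentBlock(
                    scaf.name, off, end_off,
                    scaf.z_interval.chrom,
                    scaf.z_interval.start + off,
                    scaf.z_interval.start + end_off,
                    "+", matches, aln_len,
                )
            )
    return focal_vs_b, focal_vs_outgroup, w_vs_z


def simulate_expression(
    truth: SyntheticTruth,
    params: SimParams,
    n_tissues: int = 5,
    n_per_sex: int = 2,
    n_genes: int = 300,
    z_fraction: float = 0.3,
    tissue_specific_fraction: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal expression matrix (genes x samples) plus gene metadata.

    Z-SDR genes have twice the male mean; housekeeping genes are uniform
    across tissues; tissue-specific genes are expressed in one tissue only.
    Sample names are ``t<tissue>_<sex><replicate>``.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _rng(params, "expression")
    z = next((c for c, cp in truth.sex_copy.items() if cp == (2, 1)), None)
    autosomes = [c for c, cp in truth.sex_copy.items() if cp == (2, 2)]
    if not autosomes:
        raise ValueError("truth has no autosomes")

    genes = []
    for g in range(n_genes):
        on_z = z is not None and rng.random() < z_fraction
        chrom = z if on_z else autosomes[int(rng.integers(len(autosomes)))]
        specific = rng.random() < tissue_specific_fraction
        genes.append(
            {
                "gene": f"g{g:04d}",
                "chrom": chrom,
                "gene_class": "tissue_specific" if specific else "housekeeping",
                "tissue": int(rng.integers(n_tissues)) if specific else -1,
            }
        )
    meta = pd.DataFrame(genes).set_index("gene")

    samples = [
        f"t{t}_{sex}{r}"
        for t in range(n_tissues)
        for sex in ("M", "F")
        for r in range(n_per_sex)
    ]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    mat = np.zeros((n_genes, len(samples)))
    for j, name in enumerate(samples):
        tissue = int(name.split("_")[0][1:])
        sex = name.split("_")[1][0]
        level = base.copy()
        ts = meta["gene_class"].to_numpy() == "tissue_specific"
        off_tissue = ts & (meta["tissue"].to_numpy() != tissue)
        level[off_tissue] = 0.01
        if z is not None and sex == "M":
            level[meta["chrom"].to_numpy() == z] *= 2.0
        noise = rng.lognormal(mean=0.0, sigma=0.2, size=n_genes)
        mat[:, j] = level * noise
    expr = pd.DataFrame(mat, index=meta.index, columns=samples)
    return expr, meta
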