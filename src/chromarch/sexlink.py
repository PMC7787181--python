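"""Sex-linkage classification from sexed read-depth tracks, PAR boundary
detection, and expression sex-bias / tissue-specificity statistics.

Scaffolds are called Z-linked when the male/female depth ratio falls in
[1.5, 2.5] with at least 80% of windows covered in both sexes, and W-linked
when either the depth ratio or the coverage ratio falls in [0, 0.25].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, WindowTrack


@dataclass(frozen=True)
class SexCall:
    scaffold: str
    label: str  # Z / W / autosomal / unassigned
    mf_depth_ratio: float
    mf_coverage_ratio: float
    covered_fraction_m: float
    covered_fraction_f: float


@dataclass(frozen=True)
class ParCall:
    boundary: int  # bp on Z
    par_interval: GenomicInterval
    mean_ratio_par: float
    mean_ratio_sdr: float


def genome_median_depth(tracks: dict[str, WindowTrack]) -> float:
    """Median per-window depth value over all covered windows of the genome
    (the per-bp normalizer, since values are depth-per-bp proxies)."""
    values = np.concatenate([t.values for t in tracks.values()])
    values = values[~np.isnan(values) & (values > 0)]
    if len(values) == 0:
        raise ValueError("no covered windows in any track")
    return float(np.median(values))


def paired_genome_medians(
    tracks_m: dict[str, WindowTrack], tracks_f: dict[str, WindowTrack]
) -> tuple[float, float]:
    """Per-sex median depth over windows covered in BOTH sexes.

    Restricting both medians to the mutually covered window set keeps the
    two normalizers comparable (sex-specific sequence, e.g. the W, would
    otherwise depress only one of them).
    """
    vals_m, vals_f = [], []
    for chrom, tm in tracks_m.items():
        tf = tracks_f.get(chrom)
        if tf is None:
            continue
        both = (
            tm.defined() & (tm.values > 0) & tf.defined() & (tf.values > 0)
        )
        vals_m.append(tm.values[both])
        vals_f.append(tf.values[both])
    vm = np.concatenate(vals_m) if vals_m else np.array([])
    if len(vm) == 0:
        raise ValueError("no mutually covered windows")
    vf = np.concatenate(vals_f)
    return float(np.median(vm)), float(np.median(vf))


def normalize_depth(track: WindowTrack, genome_median_per_bp: float) -> WindowTrack:
    """Divide every window value by the genome-wide median; missing
    propagates."""
    if genome_median_per_bp <= 0:
        raise ValueError("genome median must be positive")
    return WindowTrack(
        track.chrom,
        track.window_size,
        track.values / genome_median_per_bp,
        chrom_length=track.chrom_length,
    )


def classify_sex_linkage(
    norm_m: WindowTrack,
    norm_f: WindowTrack,
    z_range: tuple[float, float] = (1.5, 2.5),
    w_max: float = 0.25,
    coverage_floor: float = 0.80,
) -> SexCall:
    """Classify one scaffold from its normalized M and F depth tracks.

    A window is covered when it is non-missing with depth > 0.  The depth
    ratio is mean(M)/mean(F) over mutually covered windows.  W calls use
    depth ratio OR coverage ratio <= ``w_max``; Z and autosomal calls
    require >= ``coverage_floor`` covered fraction in both sexes.
    """
    if norm_m.chrom != norm_f.chrom or norm_m.window_size != norm_f.window_size:
        raise ValueError("tracks must share scaffold and window grid")
    if norm_m.n_windows != norm_f.n_windows:
        raise ValueError("tracks must share the window grid")

    cov_m = norm_m.defined() & (norm_m.values > 0)
    cov_f = norm_f.defined() & (norm_f.values > 0)
    frac_m = float(cov_m.mean()) if len(cov_m) else 0.0
    frac_f = float(cov_f.mean()) if len(cov_f) else 0.0
    both = cov_m & cov_f

    if both.any():
        mean_f = float(norm_f.values[both].mean())
        mean_m = float(norm_m.values[both].mean())
        depth_ratio = mean_m / mean_f if mean_f > 0 else float("inf")
    else:
        depth_ratio = float("nan")
    coverage_ratio = frac_m / frac_f if frac_f > 0 else float("inf")

    if (np.isfinite(depth_ratio) and depth_ratio <= w_max) or coverage_ratio <= w_max:
        label = "W"
    elif min(frac_m, frac_f) < coverage_floor:
        label = "unassigned"
    elif np.isfinite(depth_ratio) and z_range[0] <= depth_ratio <= z_range[1]:
        label = "Z"
    else:
        label = "autosomal"
    return SexCall(norm_m.chrom, label, depth_ratio, coverage_ratio, frac_m, frac_f)


def mf_ratio_track(norm_m: WindowTrack, norm_f: WindowTrack) -> WindowTrack:
    """Per-window M/F ratio; missing where either side is missing or F = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = norm_m.values / norm_f.values
    ratio[~np.isfinite(ratio)] = np.nan
    return WindowTrack(norm_m.chrom, norm_m.window_size, ratio, norm_m.chrom_length)


def detect_par(
    ratio_track: WindowTrack,
    tol_par: tuple[float, float] = (0.75, 1.25),
    tol_sdr: tuple[float, float] = (1.5, 2.5),
) -> ParCall | None:
    """Locate the PAR boundary on Z by a least-squares two-segment fit.

    The fit runs on log2 ratios (the M/F ratio is right-skewed with
    SDR-windows roughly 4x noisier than PAR windows on the linear scale;
    the log transform stabilizes both, removing a boundary drift into the
    SDR).  Both orientations are tried (PAR at the left or right terminus);
    the changepoint minimizing total within-segment sum of squares wins,
    and the two segment means (geometric, back-transformed) must fall in
    ``tol_par`` and ``tol_sdr`` respectively.  Returns None when no
    admissible changepoint exists (no PAR).
    """
    raw = ratio_track.values
    n = len(raw)
    if ratio_track.n_windows < 4:
        raise ValueError("need at least 4 windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    filled = np.nan_to_num(v)
    defined = (~np.isnan(v)).astype(float)
    # prefix sums over defined values only
    c0 = np.concatenate([[0.0], np.cumsum(defined)])
    c1 = np.concatenate([[0.0], np.cumsum(filled)])
    c2 = np.concatenate([[0.0], np.cumsum(filled * filled)])
    cuts = np.arange(1, n)
    nl, nr = c0[cuts], c0[n] - c0[cuts]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_l = c1[cuts] / nl
        mu_r = (c1[n] - c1[cuts]) / nr
        ss_l = c2[cuts] - nl * mu_l**2
        ss_r = (c2[n] - c2[cuts]) - nr * mu_r**2
    cost = np.where((nl > 0) & (nr > 0), ss_l + ss_r, np.inf)

    best = None  # (cost, boundary_window, par_on_left, mean_par, mean_sdr)
    for ci, c in enumerate(cuts):
        if not np.isfinite(cost[ci]):
            continue
        for par_on_left in (True, False):
            mu_par, mu_sdr = (
                (mu_l[ci], mu_r[ci]) if par_on_left else (mu_r[ci], mu_l[ci])
            )
            g_par, g_sdr = 2.0**mu_par, 2.0**mu_sdr
            if tol_par[0] <= g_par <= tol_par[1] and tol_sdr[0] <= g_sdr <= tol_sdr[1]:
                if best is None or cost[ci] < best[0]:
                    best = (cost[ci], int(c), par_on_left, float(g_par), float(g_sdr))
    if best is None:
        return None
    _, c, par_on_left, mu_par, mu_sdr = best
    ws = ratio_track.window_size
    length = ratio_track.chrom_length or n * ws
    if par_on_left:
        boundary = c * ws
        par_iv = GenomicInterval(ratio_track.chrom, 0, boundary)
    else:
        boundary = c * ws
        par_iv = GenomicInterval(ratio_track.chrom, boundary, length)
    return ParCall(boundary, par_iv, mu_par, mu_sdr)


def mf_expression_ratio(
    expr: pd.DataFrame,
    sex_labels: dict[str, str] | pd.Series,
    pseudocount: float = 0.1,
    gene_chrom: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Per-gene (mean male + pc)/(mean female + pc) expression ratio, plus
    per-chromosome medians when a gene->chromosome mapping is supplied."""
    sex = pd.Series(sex_labels)
    males = [s for s in expr.columns if sex[s] == "M"]
    females = [s for s in expr.columns if sex[s] == "F"]
    if not males or not females:
        raise ValueError("need at least one sample of each sex")
    ratio = (expr[males].mean(axis=1) + pseudocount) / (
        expr[females].mean(axis=1) + pseudocount
    )
    ratio.name = "mf_ratio"
    by_chrom = None
    if gene_chrom is not None:
        by_chrom = ratio.groupby(gene_chrom.reindex(ratio.index)).median()
    return ratio, by_chrom


def tau(tissue_medians) -> float:
    """Tissue-specificity index: sum(1 - x_i / x_max) / (n - 1).

    0 for perfectly uniform expression, 1 for single-tissue expression.
    """
    x = np.asarray(tissue_medians, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector of >= 2 tissue values")
    if (x < 0).any():
        raise ValueError("tissue values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("all-zero expression: tau undefined")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))
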