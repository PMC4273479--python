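"""Extended-CNV calling: GC correction, Z scores, circular binary segmentation.

Pipeline for joining neighboring windows into extended CNV segments:

1.  GC-correct each sample's depths:  D_corrected = D_global · D_raw / D_GC,
    where D_global is the sample's median depth over analyzed windows and
    D_GC the median within the window's GC group (20 groups, 5% increments).
2.  Form the corrected ratio r = D_t-corrected / D_c-corrected per window.
3.  Standardize:  Z = (ln r − mean ln r) / sd ln r  over all analyzed windows
    of the test sample (sample sd, n−1 denominator).
4.  Run circular binary segmentation (CBS) on Z per chromosome: recursively
    find the arc (i, j] of the circularized sequence maximizing the
    two-sample t-like statistic between arc and complement, accept the split
    when its permutation p-value is below ``alpha``, and recurse into the
    resulting pieces.
5.  Classify each segment by its mean Z:  gain when Z ≥ +z_threshold, loss
    when Z ≤ −z_threshold (0.2 by default, inclusive on both sides).

A high Pearson correlation between the test and control depth profiles is a
prerequisite for meaningful segmentation; :func:`qc_correlation` computes it
as a QC metric.

Permutation significance uses a sequential scheme: permutations are drawn in
blocks and the test stops early once the split can no longer be significant
at the configured permutation budget (or once zero exceedances over at least
500 permutations make p conclusively small).  This leaves decisions at the
nominal level while keeping deep recursions fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .template import ReferenceTemplate, common_windows, gc_group_index
from .windows import DepthProfile

__all__ = [
    "Segment",
    "CBSConfig",
    "gc_correct",
    "corrected_depths",
    "corrected_ratio",
    "z_scores",
    "cbs_segment",
    "classify_segments",
    "qc_correlation",
    "segment_extended",
]

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


class DegenerateSignalError(ValueError):
    """All log-ratios identical; Z scores undefined."""


@dataclass
class CBSConfig:
    alpha: float = 0.01          # permutation significance for accepting a split
    n_perm: int = 10000          # permutation budget per split test
    min_width: int = 2           # minimum windows per emitted segment
    z_threshold: float = 0.2     # |mean Z| at/above which a segment is gain/loss


@dataclass
class Segment:
    chrom: str
    start: int                   # first window index on the chromosome (inclusive)
    end: int                     # last window index (inclusive)
    mean_z: float
    state: str = NEUTRAL
    n_windows: int = 0


def gc_correct(d_raw, d_global: float, d_gc) -> np.ndarray:
    """D_corrected = D_global · D_raw / D_GC (window excluded when D_GC == 0)."""
    d_raw = np.asarray(d_raw, dtype=float)
    d_gc = np.asarray(d_gc, dtype=float)
    if np.any(d_gc <= 0):
        raise ValueError("D_GC must be positive; exclude zero-median groups first")
    return d_global * d_raw / d_gc


def corrected_depths(depth: np.ndarray, gc_groups: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """GC-corrected depths over an analysis set (median-based, per sample).

    D_global is the median depth of the analyzed windows, D_GC the median of
    the window's GC group within the analyzed set.  Windows whose group has a
    zero median (or undefined GC) keep their raw depth scaled by D_global /
    D_global = 1, i.e. pass through uncorrected.
    """
    depth = np.asarray(depth, dtype=float)[mask]
    groups = np.asarray(gc_groups)[mask]
    d_global = float(np.median(depth))
    out = depth.copy()
    for g in np.unique(groups):
        if g < 0:
            continue
        sel = groups == g
        d_gc = float(np.median(depth[sel]))
        if d_gc > 0:
            out[sel] = d_global * depth[sel] / d_gc
    return out


def corrected_ratio(test_corrected, control_corrected) -> np.ndarray:
    """r = D_t-corrected / D_c-corrected (caller excludes zero denominators)."""
    t = np.asarray(test_corrected, dtype=float)
    c = np.asarray(control_corrected, dtype=float)
    if np.any(c <= 0):
        raise ValueError("control corrected depth must be positive")
    return t / c


def z_scores(r) -> np.ndarray:
    """Standardized log-ratios: Z = (ln r − mean ln r)/sd ln r, sample sd."""
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 windows for Z scores")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive to take logarithms")
    lr = np.log(r)
    sd = lr.std(ddof=1)
    if sd == 0:
        raise DegenerateSignalError("all log-ratios identical; Z undefined")
    return (lr - lr.mean()) / sd


# ---------------------------------------------------------------- CBS core


def _max_arc_stat(x: np.ndarray, min_width: int):
    """Best circular split of one segment.

    Returns (stat, i, j): the maximal |t|-like statistic over arcs (i, j]
    with both arc and complement at least ``min_width`` long, where

        stat(i, j) = |S_j − S_i| / (s · sqrt(l (n−l) / n)),   l = j − i,

    on the centered sequence (S = prefix sums, s = sample sd of x).  This is
    the pooled-variance two-sample statistic comparing arc mean with
    complement mean under a fixed per-segment scale.
    """
    n = x.size
    s = x.std(ddof=1)
    if s == 0 or n < 2 * min_width:
        return 0.0, 0, n
    xc = x - x.mean()
    S = np.concatenate([[0.0], np.cumsum(xc)])
    best, bi, bj = -1.0, 0, n
    for l in range(min_width, n - min_width + 1):
        d = np.abs(S[l:] - S[: n - l + 1])
        scale = s * np.sqrt(l * (n - l) / n)
        k = int(np.argmax(d))
        stat = d[k] / scale
        if stat > best:
            best, bi, bj = stat, k, k + l
    return best, bi, bj


def _perm_max_stats(x: np.ndarray, min_width: int, rng, n_block: int) -> np.ndarray:
    """Max arc statistic for a block of random permutations of x (vectorized)."""
    n = x.size
    s = x.std(ddof=1)
    xc = x - x.mean()
    P = rng.permuted(np.tile(xc, (n_block, 1)), axis=1)
    S = np.concatenate([np.zeros((n_block, 1)), np.cumsum(P, axis=1)], axis=1)
    best = np.zeros(n_block)
    for l in range(min_width, n - min_width + 1):
        d = np.abs(S[:, l:] - S[:, : n - l + 1]).max(axis=1)
        scale = s * np.sqrt(l * (n - l) / n)
        np.maximum(best, d / scale, out=best)
    return best


def _split_significant(
    x: np.ndarray, observed: float, cfg: CBSConfig, rng
) -> bool:
    """Sequential permutation test of the observed max arc statistic."""
    if observed <= 0:
        return False
    n_perm = cfg.n_perm
    reject_at = int(np.ceil(cfg.alpha * (n_perm + 1)))  # exceedances making p >= alpha
    exceed, done = 0, 0
    block = 200
    while done < n_perm:
        b = min(block, n_perm - done)
        stats = _perm_max_stats(x, cfg.min_width, rng, b)
        exceed += int((stats >= observed).sum())
        done += b
        if exceed >= reject_at:
            return False
        if exceed == 0 and done >= 500:
            return True
    return (exceed + 1) / (n_perm + 1) < cfg.alpha


def _segment_indices(x: np.ndarray, cfg: CBSConfig, rng) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns [start, end) index runs."""
    n = x.size
    if n < 2 * cfg.min_width:
        return [(0, n)]
    stat, i, j = _max_arc_stat(x, cfg.min_width)
    if not _split_significant(x, stat, cfg, rng):
        return [(0, n)]
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    bounds = [0, *cuts, n]
    out: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        for s0, s1 in _segment_indices(x[a:b], cfg, rng):
            out.append((a + s0, a + s1))
    return out


def cbs_segment(
    z: np.ndarray,
    chrom: str = "chr1",
    config: CBSConfig | None = None,
    seed: int | None = 0,
) -> list[Segment]:
    """Segment one chromosome's Z-score track by circular binary segmentation.

    Deterministic for a fixed seed; adjacent segments emitted in order and
    covering every window exactly once.
    """
    cfg = config or CBSConfig()
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(seed)
    runs = _segment_indices(z, cfg, rng)
    return [
        Segment(
            chrom=chrom,
            start=a,
            end=b - 1,
            mean_z=float(z[a:b].mean()),
            n_windows=b - a,
        )
        for a, b in runs
    ]


def classify_segments(segments: list[Segment], z_threshold: float = 0.2) -> list[Segment]:
    """Assign gain/loss/neutral by mean Z against the (inclusive) threshold."""
    for seg in segments:
        if seg.mean_z >= z_threshold:
            seg.state = GAIN
        elif seg.mean_z <= -z_threshold:
            seg.state = LOSS
        else:
            seg.state = NEUTRAL
    return segments


def qc_correlation(
    test: DepthProfile, control: Union[DepthProfile, ReferenceTemplate]
) -> float:
    """Pearson correlation of test vs control depths over common windows.

    High correlation between the two depth distributions is the prerequisite
    for ratio-based segmentation; emit this before trusting extended calls.
    """
    mask = common_windows(test, control)
    a = test.depth[mask]
    b = control.depth[mask]
    if a.size < 3:
        raise ValueError("need at least 3 common windows for a correlation")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a depth vector; correlation undefined")
    return float(pearsonr(a, b)[0])


def segment_extended(
    test: DepthProfile,
    control: Union[DepthProfile, ReferenceTemplate],
    config: CBSConfig | None = None,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full extended-CNV pipeline on a test/control pair.

    GC-corrects both sides over the common-window analysis set, forms Z
    scores from the corrected ratios, runs CBS per chromosome and classifies
    segments.  Returns ``(segments, z_track)`` where segments has genomic
    coordinates (chrom, start, end, n_windows, mean_z, state) and z_track is
    the window-level Z score table.
    """
    cfg = config or CBSConfig()
    mask = common_windows(test, control)
    win = test.windows
    if "gc" in win.columns:
        groups = gc_group_index(win["gc"].to_numpy())
    else:
        groups = np.full(len(win), -1, dtype=np.int64)
    t_corr = corrected_depths(test.depth, groups, mask)
    c_corr = corrected_depths(control.depth, groups, mask)
    r = corrected_ratio(t_corr, c_corr)
    z = z_scores(r)

    ztab = win.loc[mask, ["chrom", "start", "end"]].reset_index(drop=True)
    ztab["z"] = z

    rows = []
    rng_seed = seed
    for k, (chrom, grp) in enumerate(ztab.groupby("chrom", sort=False)):
        zc = grp["z"].to_numpy()
        segs = cbs_segment(
            zc, chrom=chrom, config=cfg, seed=None if seed is None else seed + k
        )
        classify_segments(segs, cfg.z_threshold)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for s in segs:
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[s.start]),
                    "end": int(ends[s.end]),
                    "n_windows": s.n_windows,
                    "mean_z": s.mean_z,
                    "state": s.state,
                }
            )
    return pd.DataFrame(rows), ztab
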