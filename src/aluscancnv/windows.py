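"""Genome windowing and per-window read-depth profiles.

The unit of every depth statistic in this package is a fixed-size genomic
window.  Windows are kept as a plain :class:`pandas.DataFrame` with columns
``chrom``, ``start``, ``end`` and (after :func:`annotate_gc`) ``gc`` —
0-based, half-open BED convention throughout.  A sample's evidence is a
:class:`DepthProfile`: one non-negative depth per window, where depth is the
count of read 5' start positions falling in the window.

Alu-anchored capture leaves most of the genome uncovered, so profiles are
strongly zero-inflated; the winsorization and merging helpers here operate
with that in mind (the capping quantile is taken over *positive* depths
only, at the base window size, before any merging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "make_windows",
    "annotate_gc",
    "count_depth",
    "winsorize",
    "merge_windows",
    "window_size_of",
]

#: chromosomes kept by default: human autosomes (sex chromosomes and
#: unplaced contigs are excluded unless the caller opts in).
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + tuple(str(i) for i in range(1, 23))


class MalformedIntervalError(ValueError):
    """A read interval with end <= start; carries the offending record index."""


@dataclass
class DepthProfile:
    """Per-sample vector of window read depths.

    Parameters
    ----------
    sample_id
        Free-form sample label.
    windows
        Window table (``chrom``, ``start``, ``end``, optionally ``gc``);
        shared — not copied — between profiles built on the same tiling.
    depth
        Non-negative depth per window, same length and order as ``windows``.
        Integer counts on ingestion; may become fractional after
        winsorization.
    """

    sample_id: str
    windows: pd.DataFrame
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) != len(self.windows):
            raise ValueError(
                f"depth vector length {len(self.depth)} != window count {len(self.windows)}"
            )
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    @property
    def total_reads(self) -> float:
        """N: sum of depths over all windows."""
        return float(self.depth.sum())

    def __len__(self) -> int:
        return len(self.depth)


def make_windows(chrom_sizes: Mapping[str, int], window_size: int) -> pd.DataFrame:
    """Tile each chromosome with contiguous fixed-size windows.

    The last window per chromosome is truncated at the chromosome end, so
    every base is covered exactly once.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bases.  Iteration order is
        preserved and defines window order.
    window_size
        Window length in bases (default pipelines use 5 kb for segmentation
        inputs and 500 kb for localized calling).
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    chroms, starts, ends = [], [], []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        s = np.arange(0, length, window_size, dtype=np.int64)
        e = np.minimum(s + window_size, length)
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="object"),
            "start": np.concatenate(starts) if starts else np.array([], dtype=np.int64),
            "end": np.concatenate(ends) if ends else np.array([], dtype=np.int64),
        }
    )


def window_size_of(windows: pd.DataFrame) -> int:
    """Base window size of a tiling (modal width; robust to truncated tails)."""
    widths = windows["end"].to_numpy() - windows["start"].to_numpy()
    return int(np.bincount(widths).argmax()) if len(widths) else 0


def annotate_gc(windows: pd.DataFrame, sequence_source) -> pd.DataFrame:
    """Attach a ``gc`` column: fraction of G+C among unambiguous bases.

    ``sequence_source`` is anything indexable as ``source[chrom][start:end]``
    yielding a string-convertible slice — a plain ``dict`` of sequences or a
    :class:`pyfaidx.Fasta` both work.  Ambiguous (non-ACGT) bases are ignored
    in numerator and denominator; a window with no unambiguous base gets
    ``gc = NaN`` and is excluded from GC-stratified statistics downstream.
    """
    gc = np.full(len(windows), np.nan)
    for i, (chrom, start, end) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        try:
            seq = str(sequence_source[chrom][start:end]).upper()
        except KeyError as exc:
            raise KeyError(f"no sequence for chromosome {chrom!r}") from exc
        if len(seq) < end - start:
            raise IndexError(
                f"window {chrom}:{start}-{end} extends past the available sequence"
            )
        ngc = seq.count("G") + seq.count("C")
        nat = seq.count("A") + seq.count("T")
        denom = ngc + nat
        if denom > 0:
            gc[i] = ngc / denom
    out = windows.copy()
    out["gc"] = gc
    return out


def count_depth(
    read_intervals: Iterable[tuple[str, int, int]],
    windows: pd.DataFrame,
    sample_id: str = "sample",
) -> DepthProfile:
    """Count reads into windows by their 5' start coordinate.

    Each read contributes to exactly one window (the one containing its start
    position); reads on chromosomes absent from the tiling, or starting past
    the chromosome end, are dropped.  ``total_reads`` of the result therefore
    equals the number of reads landing inside any window.
    """
    size = window_size_of(windows)
    # per-chromosome window offsets and extents
    offsets: dict[str, tuple[int, int, int]] = {}  # chrom -> (first_row, n_win, chrom_len)
    for chrom, grp in windows.groupby("chrom", sort=False):
        offsets[chrom] = (int(grp.index[0]), len(grp), int(grp["end"].iloc[-1]))
    depth = np.zeros(len(windows), dtype=np.int64)
    for lineno, rec in enumerate(read_intervals, start=1):
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        if end <= start:
            raise MalformedIntervalError(
                f"record {lineno}: interval end {end} <= start {start}"
            )
        info = offsets.get(chrom)
        if info is None:
            continue
        first, nwin, chrom_len = info
        if not (0 <= start < chrom_len):
            continue
        idx = start // size
        if idx >= nwin:  # truncated-tail guard (cannot happen with full tiling)
            idx = nwin - 1
        depth[first + idx] += 1
    return DepthProfile(sample_id=sample_id, windows=windows, depth=depth)


def winsorize(profile: DepthProfile, upper_quantile: float = 0.95) -> DepthProfile:
    """Cap depths above the upper quantile of the positive-depth distribution.

    The quantile is computed over windows with depth > 0 (the covered part of
    a sparse-capture profile), with linear interpolation between order
    statistics; depths at or below the quantile are untouched.  Idempotent.
    """
    if not (0.0 < upper_quantile < 1.0):
        raise ValueError(f"upper_quantile must be in (0, 1), got {upper_quantile}")
    positive = profile.depth[profile.depth > 0]
    if positive.size == 0:
        raise ValueError("profile has no positive depths to winsorize")
    cap = float(np.quantile(positive, upper_quantile))
    return DepthProfile(
        sample_id=profile.sample_id,
        windows=profile.windows,
        depth=np.minimum(profile.depth, cap),
    )


def merge_windows(profile: DepthProfile, factor: int) -> DepthProfile:
    """Merge runs of ``factor`` consecutive windows, summing their depths.

    Merging is per chromosome; a trailing run shorter than ``factor`` becomes
    one final (short) merged window, so the depth total is preserved exactly.
    Merged GC is the length-weighted mean of constituent GC fractions.
    """
    if not isinstance(factor, (int, np.integer)):
        raise ValueError(f"factor must be an integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return DepthProfile(profile.sample_id, profile.windows, profile.depth.copy())
    win = profile.windows
    has_gc = "gc" in win.columns
    rows = {"chrom": [], "start": [], "end": []}
    if has_gc:
        rows["gc"] = []
    merged_depth = []
    for chrom, grp in win.groupby("chrom", sort=False):
        n = len(grp)
        first = int(grp.index[0])
        bounds = np.arange(0, n, factor)
        d = np.add.reduceat(profile.depth[first : first + n], bounds)
        merged_depth.append(d)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        rows["chrom"].extend([chrom] * len(bounds))
        rows["start"].extend(starts[bounds].tolist())
        last = np.minimum(bounds + factor - 1, n - 1)
        rows["end"].extend(ends[last].tolist())
        if has_gc:
            gc = grp["gc"].to_numpy()
            lengths = (ends - starts).astype(float)
            w = np.where(np.isnan(gc), 0.0, lengths)
            num = np.add.reduceat(np.where(np.isnan(gc), 0.0, gc) * w, bounds)
            den = np.add.reduceat(w, bounds)
            with np.errstate(invalid="ignore"):
                rows["gc"].extend((num / den).tolist())
    merged = pd.DataFrame(rows)
    merged["start"] = merged["start"].astype(np.int64)
    merged["end"] = merged["end"].astype(np.int64)
    return DepthProfile(
        sample_id=profile.sample_id,
        windows=merged,
        depth=np.concatenate(merged_depth) if merged_depth else np.array([]),
    )
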