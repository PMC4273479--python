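"""Pooled reference templates and GC-group utilities.

Window read depths are modeled Poisson, and a sum of independent Poisson
counts is again Poisson; pooling reference samples window-by-window therefore
yields a single "reference template" whose depths play the role of a paired
control in unpaired analysis.  The pooling is exact integer addition — no
averaging, no rescaling — so the Poisson-sum closure holds by construction.

GC stratification used across the package: the GC range [0, 1] is split into
20 groups of 5% width, and per-group mean (or median) depths stand in for the
global rate parameter wherever GC normalization is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .windows import DepthProfile

__all__ = [
    "ReferenceTemplate",
    "build_template",
    "gc_group_index",
    "gc_group_means",
    "common_windows",
    "AnalysisImpossibleError",
    "IncompatibleProfilesError",
    "N_GC_GROUPS",
]

N_GC_GROUPS = 20
NO_GC_GROUP = -1  # sentinel for windows with undefined GC


class IncompatibleProfilesError(ValueError):
    """Profiles do not share an identical window tiling."""


class AnalysisImpossibleError(ValueError):
    """No window has positive depth in both test and control."""


@dataclass
class ReferenceTemplate:
    """Per-window pooled depths of a set of reference samples."""

    windows: pd.DataFrame
    pooled_depth: np.ndarray = field(repr=False)
    n_samples: int = 1
    sample_id: str = "template"

    @property
    def total_reads(self) -> float:
        return float(self.pooled_depth.sum())

    @property
    def depth(self) -> np.ndarray:
        """Alias so a template can stand wherever a control profile is expected."""
        return self.pooled_depth

    def __len__(self) -> int:
        return len(self.pooled_depth)


def _same_windows(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return bool(
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        and (a["end"].to_numpy() == b["end"].to_numpy()).all()
    )


def build_template(profiles: Sequence[DepthProfile]) -> ReferenceTemplate:
    """Sum reference profiles window-by-window into a template.

    All profiles must share one window tiling; the pooled depth of a window
    is the exact sum of the constituent depths.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one reference profile")
    base = profiles[0]
    pooled = np.array(base.depth, dtype=float)
    for p in profiles[1:]:
        if not _same_windows(base.windows, p.windows):
            raise IncompatibleProfilesError(
                f"profile {p.sample_id!r} is not on the same window set as {base.sample_id!r}"
            )
        pooled = pooled + p.depth
    return ReferenceTemplate(
        windows=base.windows, pooled_depth=pooled, n_samples=len(profiles)
    )


def gc_group_index(gc_fraction) -> np.ndarray:
    """Map GC fraction(s) in [0, 1] to group indices 0..19 (5% bins).

    ``floor(gc / 0.05)`` with gc == 1.0 clamped into group 19; undefined
    (NaN) GC maps to the sentinel -1.
    """
    gc = np.asarray(gc_fraction, dtype=float)
    scalar = gc.ndim == 0
    gc = np.atleast_1d(gc)
    valid = ~np.isnan(gc)
    if np.any((gc[valid] < 0) | (gc[valid] > 1)):
        raise ValueError("gc_fraction must lie in [0, 1]")
    idx = np.full(gc.shape, NO_GC_GROUP, dtype=np.int64)
    idx[valid] = np.minimum((gc[valid] / 0.05).astype(np.int64), N_GC_GROUPS - 1)
    return int(idx[0]) if scalar else idx


def gc_group_means(
    depth: np.ndarray, gc_groups: np.ndarray, mask: np.ndarray | None = None
) -> dict[int, float]:
    """Arithmetic mean depth per GC group over an analysis window set.

    Groups with no windows in the analysis set are absent from the mapping;
    windows with undefined GC (group -1) never contribute.
    """
    depth = np.asarray(depth, dtype=float)
    gc_groups = np.asarray(gc_groups)
    if mask is not None:
        depth = depth[mask]
        gc_groups = gc_groups[mask]
    out: dict[int, float] = {}
    for g in range(N_GC_GROUPS):
        sel = gc_groups == g
        if sel.any():
            out[g] = float(depth[sel].mean())
    return out


def common_windows(
    test: DepthProfile, control: Union[DepthProfile, ReferenceTemplate]
) -> np.ndarray:
    """Boolean mask of windows with positive depth in both test and control.

    Only these windows enter ratio statistics — a zero depth on either side
    leaves the read-depth ratio undefined or uninformative.
    """
    if not _same_windows(test.windows, control.windows):
        raise IncompatibleProfilesError(
            "test and control are not on the same window tiling"
        )
    mask = (test.depth > 0) & (control.depth > 0)
    if not mask.any():
        raise AnalysisImpossibleError(
            "no window has positive depth in both test and control"
        )
    return mask
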