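"""Synthetic depth profiles and cohorts with known ground truth.

Emulates the data regime of sparse Alu-anchored capture sequencing at the
depth level (no reads are simulated): most windows carry no capture at all,
covered windows have Poisson-distributed counts, the Poisson rate carries a
smooth GC-dependent multiplicative bias, and copy-number variants enter as
multiplicative fold changes over window runs.

Defaults define the study conditions used throughout the test-suite:
``base_lambda = 100`` (well inside the λ ≥ 50 regime where the normal
approximation behind the GHT caller holds), ``coverage_fraction = 0.3``
(inter-Alu capture leaves most windows empty), and a unimodal GC bias
multiplier 0.5 + exp(−((gc − 0.45)/0.10)²) ranging over [0.5, 1.5] and
peaking near GC 0.45.  Window GC values are drawn from a clipped
normal(0.41, 0.07), so typical windows sit on the rising limb of the bias
curve and raw depth correlates positively with GC.

Everything is deterministic given the seed carried in the truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import DepthProfile, make_windows

__all__ = [
    "SimulationTruth",
    "default_gc_bias",
    "synthetic_windows",
    "simulate_profile",
    "simulate_pair",
    "simulate_cohort",
]


def default_gc_bias(gc) -> np.ndarray:
    """Smooth unimodal capture-efficiency multiplier, range [0.5, 1.5]."""
    gc = np.asarray(gc, dtype=float)
    return 0.5 + np.exp(-(((gc - 0.45) / 0.10) ** 2))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated sample (or pair).

    cnv_regions: list of (start_index, end_index_exclusive, fold) window runs
    carried by the *test* sample; fold > 1 is a gain, fold < 1 a loss.
    gc_bias: None for flat capture, or a callable gc -> rate multiplier.
    """

    cnv_regions: list[tuple[int, int, float]] = field(default_factory=list)
    base_lambda: float = 100.0
    coverage_fraction: float = 0.3
    gc_bias: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must be in (0, 1]")
        for a, b, fold in self.cnv_regions:
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            if b <= a:
                raise ValueError("empty CNV region")


def synthetic_windows(
    n_windows: int, window_size: int = 5000, seed: int = 0, with_gc: bool = True
) -> pd.DataFrame:
    """A single-chromosome tiling with simulated GC fractions."""
    win = make_windows({"chr1": n_windows * window_size}, window_size)
    if with_gc:
        rng = np.random.default_rng(seed)
        win = win.copy()
        win["gc"] = np.clip(rng.normal(0.41, 0.07, size=n_windows), 0.25, 0.65)
    return win


def _rates(windows: pd.DataFrame, truth: SimulationTruth, with_folds: bool) -> np.ndarray:
    lam = np.full(len(windows), float(truth.base_lambda))
    if truth.gc_bias is not None:
        if "gc" not in windows.columns:
            raise ValueError("gc_bias requires GC-annotated windows")
        lam = lam * np.asarray(truth.gc_bias(windows["gc"].to_numpy()), dtype=float)
    if with_folds:
        for a, b, fold in truth.cnv_regions:
            lam[a:b] *= fold
    return lam


def _coverage_mask(n: int, fraction: float, rng) -> np.ndarray:
    return rng.random(n) < fraction


def simulate_profile(
    windows: pd.DataFrame, truth: SimulationTruth, sample_id: str = "sim"
) -> DepthProfile:
    """Draw one profile: Poisson counts on a random coverage mask."""
    rng = np.random.default_rng(truth.seed)
    mask = _coverage_mask(len(windows), truth.coverage_fraction, rng)
    lam = _rates(windows, truth, with_folds=True)
    depth = np.where(mask, rng.poisson(lam), 0)
    return DepthProfile(sample_id=sample_id, windows=windows, depth=depth)


def simulate_pair(
    windows: pd.DataFrame, truth: SimulationTruth, shared_coverage: bool = True
) -> tuple[DepthProfile, DepthProfile]:
    """A (test, control) pair: control without CNV folds, test with them.

    With ``shared_coverage`` the two samples share one capture mask, as when
    the same primer set drives both libraries; otherwise masks are drawn
    independently.
    """
    rng = np.random.default_rng(truth.seed)
    n = len(windows)
    mask_t = _coverage_mask(n, truth.coverage_fraction, rng)
    mask_c = mask_t if shared_coverage else _coverage_mask(n, truth.coverage_fraction, rng)
    lam_c = _rates(windows, truth, with_folds=False)
    lam_t = _rates(windows, truth, with_folds=True)
    test = np.where(mask_t, rng.poisson(lam_t), 0)
    control = np.where(mask_c, rng.poisson(lam_c), 0)
    return (
        DepthProfile("test", windows, test),
        DepthProfile("control", windows, control),
    )


def simulate_cohort(
    n_samples: int,
    windows: pd.DataFrame,
    recurrent_regions: list[tuple[int, int, float]],
    background_rate: float = 0.1,
    seed: int = 0,
    fold: float = 2.0,
    truth_template: SimulationTruth | None = None,
) -> tuple[list[DepthProfile], np.ndarray]:
    """A cohort with injected recurrent CNV regions and background noise.

    ``recurrent_regions`` are (start_index, end_index_exclusive, penetrance)
    runs: each sample carries the region's CNV with probability penetrance;
    every other window flips to CNV-present independently at
    ``background_rate``.  Returns the depth profiles plus the binary truth
    matrix (windows × samples) of CNV presence.
    """
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError("background_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_win = len(windows)
    base = truth_template or SimulationTruth()
    truth = np.zeros((n_win, n_samples), dtype=np.int8)
    profiles = []
    in_region = np.zeros(n_win, dtype=bool)
    for a, b, _pen in recurrent_regions:
        in_region[a:b] = True
    for j in range(n_samples):
        carried = np.zeros(n_win, dtype=bool)
        for a, b, pen in recurrent_regions:
            if rng.random() < pen:
                carried[a:b] = True
        bg = (rng.random(n_win) < background_rate) & ~in_region
        carried |= bg
        truth[:, j] = carried
        lam = np.full(n_win, base.base_lambda)
        if base.gc_bias is not None and "gc" in windows.columns:
            lam = lam * np.asarray(base.gc_bias(windows["gc"].to_numpy()), dtype=float)
        lam = np.where(carried, lam * fold, lam)
        mask = _coverage_mask(n_win, base.coverage_fraction, rng)
        depth = np.where(mask, rng.poisson(lam), 0)
        profiles.append(DepthProfile(f"s{j}", windows, depth))
    return profiles, truth
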