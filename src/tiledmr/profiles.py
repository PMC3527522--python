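"""Signal-track metaprofiles around regions.

Tracks are held at a fixed bin step; per-region profiles are sampled at
signed offsets (default +/- 10 kb) from the region midpoint, aggregated per
direction class with a missing-aware column mean, and smoothed with a
centred moving average. A matched control re-places the same number and
lengths of regions at random over the array coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import covered_segments, place_regions


@dataclass
class GenomicTrack:
    """Fixed-step binned signal per chromosome: {chrom: (start, step, values)}."""

    data: dict[str, tuple[int, int, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, (start, step, values) in self.data.items():
            if step <= 0:
                raise ValueError(f"track step must be > 0 on {chrom!r}")
            self.data[chrom] = (int(start), int(step), np.asarray(values, float))

    def step(self) -> int:
        steps = {step for _, step, _ in self.data.values()}
        if len(steps) != 1:
            raise ValueError("track has inconsistent bin steps across chromosomes")
        return steps.pop()

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal of the bin containing each position; NaN outside coverage."""
        out = np.full(len(positions), np.nan)
        if chrom not in self.data:
            return out
        start, step, values = self.data[chrom]
        ix = (np.asarray(positions) - start) // step
        ok = (ix >= 0) & (ix < len(values))
        out[ok] = values[ix[ok].astype(int)]
        return out

    @classmethod
    def from_bedgraph(cls, path, step: int = 50) -> "GenomicTrack":
        """Resample bedGraph intervals onto fixed bins by coverage-weighted mean."""
        bg = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#")
        data = {}
        for chrom, g in bg.groupby("chrom", sort=True):
            lo = (int(g["start"].min()) // step) * step
            hi = int(np.ceil(g["end"].max() / step)) * step
            n = (hi - lo) // step
            wsum = np.zeros(n)
            wtot = np.zeros(n)
            for s, e, v in zip(g["start"], g["end"], g["value"]):
                first = (s - lo) // step
                last = (e - 1 - lo) // step
                for b in range(first, last + 1):
                    b_lo, b_hi = lo + b * step, lo + (b + 1) * step
                    w = min(e, b_hi) - max(s, b_lo)
                    wsum[b] += w * v
                    wtot[b] += w
            values = np.where(wtot > 0, wsum / np.maximum(wtot, 1), np.nan)
            data[chrom] = (lo, step, values)
        return cls(data)


@dataclass
class ProfileMatrix:
    """Per-region signal at signed offsets from the region reference point."""

    offsets: np.ndarray
    matrix: np.ndarray  # regions x offsets, NaN where outside track coverage
    labels: np.ndarray  # per-region class label (e.g. direction)


def extract_profiles(
    regions: pd.DataFrame,
    track: GenomicTrack,
    flank: int = 10000,
    label_col: str = "direction",
) -> ProfileMatrix:
    """Sample the track at every offset in [-flank, +flank] around midpoints."""
    step = track.step()
    if flank % step != 0:
        raise ValueError(f"track step {step} does not divide flank {flank}")
    offsets = np.arange(-flank, flank + step, step)
    mids = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    mat = np.full((len(regions), len(offsets)), np.nan)
    for i, (chrom, mid) in enumerate(zip(regions["chrom"].to_numpy(), mids)):
        mat[i] = track.values_at(chrom, mid + offsets)
    if label_col in regions:
        labels = regions[label_col].to_numpy()
    else:
        labels = np.repeat("all", len(regions))
    return ProfileMatrix(offsets=offsets, matrix=mat, labels=labels)


def moving_average(x: np.ndarray, window_bins: int = 11) -> np.ndarray:
    """Centred moving average, edge-truncated and NaN-aware."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be a positive odd integer")
    s = pd.Series(x)
    return s.rolling(window_bins, center=True, min_periods=1).mean().to_numpy()


def aggregate_moving_average(pm: ProfileMatrix, window_bins: int = 11) -> dict[str, np.ndarray]:
    """Per-class metaprofile: missing-aware column mean, then moving average."""
    curves: dict[str, np.ndarray] = {}
    for label in pd.unique(pm.labels):
        rows = pm.matrix[pm.labels == label]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_mean = np.nanmean(rows, axis=0)
        if np.isnan(col_mean).all():
            warnings.warn(f"class {label!r} has no observed values; omitted", stacklevel=2)
            continue
        curves[str(label)] = moving_average(col_mean, window_bins)
    return curves


def random_region_control(
    layout: pd.DataFrame,
    lengths: np.ndarray,
    track: GenomicTrack,
    flank: int = 10000,
    window_bins: int = 11,
    seed: int = 0,
) -> np.ndarray:
    """Metaprofile of length-matched regions placed at random over coverage."""
    rng = np.random.default_rng(seed)
    segments = covered_segments(layout)
    placed = place_regions(np.asarray(lengths, int), segments, rng)
    pm = extract_profiles(placed, track, flank=flank)
    return aggregate_moving_average(pm, window_bins=window_bins)["all"]
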