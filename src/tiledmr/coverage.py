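"""Probe-coverage model and coverage-respecting random region placement.

Several analyses compare observed regions against regions placed at random
over the array's footprint, so that uneven probe coverage is taken into
account. The covered footprint is the union of probe intervals merged across
inter-probe gaps up to ``merge_gap`` (probes tile promoters with small gaps
between adjacent footprints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def covered_segments(layout: pd.DataFrame, merge_gap: int = 100) -> pd.DataFrame:
    """Union of probe intervals, merging gaps <= merge_gap, per chromosome.

    Returns a frame (chrom, start, end) sorted by (chrom, start).
    """
    segs = []
    for chrom, grp in layout.groupby("chrom", sort=True):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order]
        ends = np.maximum.accumulate(grp["end"].to_numpy()[order])
        # new segment wherever the gap to the previous probe exceeds merge_gap
        brk = np.flatnonzero(starts[1:] - ends[:-1] > merge_gap) + 1
        seg_starts = starts[np.concatenate([[0], brk])]
        seg_ends = ends[np.concatenate([brk - 1, [len(starts) - 1]])]
        for s, e in zip(seg_starts, seg_ends):
            segs.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(segs, columns=["chrom", "start", "end"])


@dataclass
class PlacementSampler:
    """Uniform-over-covered-bases region placement, precomputed for reuse.

    Sampling a region start means drawing a covered base uniformly from the
    union of segments; regions running past their segment's end are shifted
    left to fit, and regions longer than the segment are truncated with a
    warning.
    """

    chroms: np.ndarray  # per segment
    seg_start: np.ndarray
    seg_end: np.ndarray

    @classmethod
    def from_segments(cls, segments: pd.DataFrame) -> "PlacementSampler":
        if segments.empty:
            raise ValueError("no covered segments to place regions on")
        return cls(
            chroms=segments["chrom"].to_numpy(),
            seg_start=segments["start"].to_numpy(int),
            seg_end=segments["end"].to_numpy(int),
        )

    def __post_init__(self) -> None:
        seg_len = self.seg_end - self.seg_start
        self._cum = np.concatenate([[0], np.cumsum(seg_len)])
        self._seg_len = seg_len

    def sample_arrays(
        self, lengths: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample placements; returns (segment indices, starts, ends)."""
        lengths = np.asarray(lengths, dtype=int)
        draws = rng.integers(0, self._cum[-1], size=len(lengths))
        seg_ix = np.searchsorted(self._cum, draws, side="right") - 1
        starts = self.seg_start[seg_ix] + (draws - self._cum[seg_ix])
        ends = starts + lengths
        over = ends > self.seg_end[seg_ix]
        starts[over] = np.maximum(
            self.seg_end[seg_ix][over] - lengths[over], self.seg_start[seg_ix][over]
        )
        ends = starts + lengths
        too_long = lengths > self._seg_len[seg_ix]
        if too_long.any():
            warnings.warn(
                f"{int(too_long.sum())} region(s) longer than their covered segment; "
                "truncated to fit",
                stacklevel=2,
            )
            ends[too_long] = self.seg_end[seg_ix][too_long]
        return seg_ix, starts, ends

    def sample(self, lengths: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        seg_ix, starts, ends = self.sample_arrays(lengths, rng)
        return pd.DataFrame({"chrom": self.chroms[seg_ix], "start": starts, "end": ends})


def place_regions(
    lengths: np.ndarray,
    segments: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place regions of the given lengths uniformly over covered bases.

    Returns (chrom, start, end) in placement order. See PlacementSampler for
    the edge rules.
    """
    return PlacementSampler.from_segments(segments).sample(lengths, rng)
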