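"""Normalization of raw probe intensities.

Stages are applied in a fixed order: log2 transform, per-array spatial
normalization against a running-median surface on the physical grid, then
cross-array quantile normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import SignalMatrix


def log2_transform(m: SignalMatrix) -> SignalMatrix:
    """Elementwise log2. Rejects nonpositive values, naming the offender."""
    if m.stage != "raw":
        raise ValueError(f"log2_transform expects stage 'raw', got {m.stage!r}")
    vals = m.values.to_numpy(float)
    bad = ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity at probe {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}: {vals[i, j]}"
        )
    return SignalMatrix(pd.DataFrame(np.log2(vals), index=m.values.index, columns=m.values.columns), stage="logged")


def spatial_normalize(m: SignalMatrix, layout: pd.DataFrame, window: int = 15) -> SignalMatrix:
    """Remove smooth per-array spatial bias on the (row, col) grid.

    For each array a running-median surface (window x window, edges handled
    by nearest-value extension) is estimated on the physical grid and
    subtracted; the array is then re-centred so its median is exactly
    preserved. Arrays smaller than the filter window fall back to a
    median-only centring with a warning.
    """
    if m.stage != "logged":
        raise ValueError(f"spatial_normalize expects stage 'logged', got {m.stage!r}")
    if not layout["probe_id"].is_unique:
        raise ValueError("layout probe ids not unique")
    lay = layout.set_index("probe_id").loc[m.values.index]
    rows = lay["array_row"].to_numpy(int)
    cols = lay["array_col"].to_numpy(int)
    nrow, ncol = rows.max() + 1, cols.max() + 1

    out = np.empty_like(m.values.to_numpy(float))
    small = nrow * ncol < window * window
    if small:
        warnings.warn(
            f"array grid {nrow}x{ncol} smaller than {window}x{window} filter window; "
            "skipping surface estimation",
            stacklevel=2,
        )
    for j in range(m.values.shape[1]):
        x = m.values.iloc[:, j].to_numpy(float)
        med = np.median(x)
        if small:
            out[:, j] = x
            continue
        grid = np.full((nrow, ncol), med)
        grid[rows, cols] = x
        surface = ndimage.median_filter(grid, size=window, mode="nearest")
        resid = x - surface[rows, cols]
        out[:, j] = resid + (med - np.median(resid))
    return SignalMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), stage="spatial")


def quantile_normalize(m: SignalMatrix) -> SignalMatrix:
    """Map every sample onto the across-sample mean of sorted values.

    Ties within a sample receive the mean of the reference values over the
    tied ranks, so all samples end up with exactly equal sorted vectors and
    within-sample rank order is preserved.
    """
    if m.stage != "spatial":
        raise ValueError(f"quantile_normalize expects stage 'spatial', got {m.stage!r}")
    vals = m.values.to_numpy(float)
    if vals.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if np.isnan(vals).any():
        raise ValueError("missing values not supported")
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        o = order[:, j]
        xs = vals[o, j]
        grp = np.concatenate([[0], np.cumsum(xs[1:] != xs[:-1])])
        means = np.bincount(grp, weights=ref) / np.bincount(grp)
        out[o, j] = means[grp]
    return SignalMatrix(pd.DataFrame(out, index=m.values.index, columns=m.values.columns), stage="quantile")


def normalize(m: SignalMatrix, layout: pd.DataFrame, window: int = 15) -> SignalMatrix:
    """Full raw -> quantile pipeline."""
    return quantile_normalize(spatial_normalize(log2_transform(m), layout, window=window))
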