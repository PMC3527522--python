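"""Comparison of two region sets: Venn partition, placement permutation test,
and category-count summary arithmetic.

A region is "shared" when it overlaps at least 1 bp of any region in the
other set; because the two sets can differ in granularity the shared count is
evaluated per set and both are reported. The permutation null re-places set
A's regions (lengths preserved) uniformly over probe-covered bases while
holding set B fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import PlacementSampler, covered_segments


def _check_chrom_compat(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ca, cb = set(a["chrom"]), set(b["chrom"])
    if ca and cb and not (ca & cb):
        raise ValueError(
            f"no shared chromosome names between sets ({sorted(ca)[:3]} vs {sorted(cb)[:3]}); "
            "mixed naming schemes?"
        )


def _subject_index(subjects: pd.DataFrame) -> dict:
    """Per chromosome: (sorted starts, running max of ends) for stab queries."""
    by_chrom = {}
    for chrom, g in subjects.groupby("chrom", sort=False):
        starts = g["start"].to_numpy()
        order = np.argsort(starts, kind="stable")
        ends = g["end"].to_numpy()[order]
        # running max of ends lets a single searchsorted answer interval stabs
        by_chrom[chrom] = (starts[order], np.maximum.accumulate(ends))
    return by_chrom


def _stab(index: dict, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
    if chrom not in index:
        return np.zeros(len(qs), dtype=bool)
    starts, maxends = index[chrom]
    j = np.searchsorted(starts, qe, side="left")  # subjects with start < query end
    hit = j > 0
    hit[hit] = maxends[j[hit] - 1] > qs[hit]
    return hit


def overlaps_any(queries: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean per query region: does it overlap >= 1 bp of any subject region?"""
    out = np.zeros(len(queries), dtype=bool)
    if subjects.empty or queries.empty:
        return out
    index = _subject_index(subjects)
    chroms = queries["chrom"].to_numpy()
    qs = queries["start"].to_numpy()
    qe = queries["end"].to_numpy()
    for chrom in pd.unique(chroms):
        ix = np.flatnonzero(chroms == chrom)
        out[ix] = _stab(index, chrom, qs[ix], qe[ix])
    return out


@dataclass
class OverlapResult:
    """Venn partition of two region sets, optionally with a permutation null."""

    n_only_a: int
    n_only_b: int
    n_shared_a: int  # regions of A overlapping B
    n_shared_b: int  # regions of B overlapping A
    probes_only_a: int = 0
    probes_only_b: int = 0
    probes_shared: int = 0
    null_overlaps: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iterations: int = 0
    p_emp: float = float("nan")


def venn(setA: pd.DataFrame, setB: pd.DataFrame, layout: pd.DataFrame | None = None) -> OverlapResult:
    """Partition both sets by >= 1 bp overlap; count probes per partition class."""
    _check_chrom_compat(setA, setB)
    a_hits = overlaps_any(setA, setB)
    b_hits = overlaps_any(setB, setA)
    res = OverlapResult(
        n_only_a=int((~a_hits).sum()),
        n_only_b=int((~b_hits).sum()),
        n_shared_a=int(a_hits.sum()),
        n_shared_b=int(b_hits.sum()),
    )
    if layout is not None:
        probes = layout.rename(columns={"probe_id": "name"})[["chrom", "start", "end"]]
        shared_regions = pd.concat([setA[a_hits], setB[b_hits]], ignore_index=True)
        res.probes_only_a = int(overlaps_any(probes, setA[~a_hits]).sum())
        res.probes_only_b = int(overlaps_any(probes, setB[~b_hits]).sum())
        res.probes_shared = int(overlaps_any(probes, shared_regions).sum())
    return res


def overlap_permutation(
    setA: pd.DataFrame,
    setB: pd.DataFrame,
    layout: pd.DataFrame,
    n_iter: int = 5000,
    seed: int = 0,
) -> OverlapResult:
    """Placement permutation test of the observed A-overlapping-B count.

    Each iteration re-places set A's regions (lengths preserved) uniformly
    over probe-covered bases, holding set B fixed, and records the shared
    count. The empirical p uses the add-one correction
    (1 + #{null >= observed}) / (n_iter + 1).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    res = venn(setA, setB, layout)
    sampler = PlacementSampler.from_segments(covered_segments(layout))
    index = _subject_index(setB)
    lengths = (setA["end"] - setA["start"]).to_numpy()
    rng = np.random.default_rng(seed)
    null = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        seg_ix, starts, ends = sampler.sample_arrays(lengths, rng)
        hits = 0
        for chrom in pd.unique(sampler.chroms[seg_ix]):
            sel = sampler.chroms[seg_ix] == chrom
            hits += int(_stab(index, chrom, starts[sel], ends[sel]).sum())
        null[it] = hits
    res.null_overlaps = null
    res.n_iterations = n_iter
    res.p_emp = (1 + int((null >= res.n_shared_a).sum())) / (n_iter + 1)
    return res


def total_count(counts) -> int:
    """Sum of the per-category region counts of one DMR set."""
    total = int(sum(int(c) for c in counts))
    if total <= 0:
        raise ValueError("category counts must sum to a positive total")
    return total


def relative_excess(counts_a, counts_b) -> tuple[float, int]:
    """Percent excess of set B's total over set A's total.

    Returns (exact percent, percent rounded to the nearest integer with
    ties away from zero).
    """
    ta = total_count(counts_a)
    tb = total_count(counts_b)
    pct = 100.0 * (tb - ta) / ta
    rounded = int(np.sign(pct) * np.floor(abs(pct) + 0.5))
    return pct, rounded
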