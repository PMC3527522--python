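"""Differential methylation region (DMR) detection.

Per-probe paired t-statistics over genotype pairs are scanned with a 300 bp
sliding window: probes whose t exceeds the global 95th (or falls below the
5th) percentile are counted per window and scored with a one-sided binomial
tail, separately per direction. The window p-value cutoff is calibrated by
permutation — t-values are shuffled over fixed probe positions and the whole
scan re-run — so that the empirical false-positive rate of the reported
regions stays below the configured level. Significant windows are merged
into directional regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EPI_METH, EPITHELIAL, FIB_METH, FIBROBLAST

DEFAULT_THRESHOLD_GRID = np.logspace(-1, -13, 25)


def paired_t(m, sheet: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """Per-probe paired t across genotypes (epithelial minus fibroblast).

    The sample sheet must pair every genotype across both cell types.
    The paired-difference standard deviation is floored at ``eps`` so
    zero-variance probes give finite statistics (t = 0 when the mean
    difference is also 0). Returns a frame indexed by probe id with columns
    ``t``, ``d_mean`` and ``df`` (= n_pairs - 1).
    """
    pivot = sheet.pivot(index="genotype", columns="cell_type", values="sample_id")
    if EPITHELIAL not in pivot or FIBROBLAST not in pivot or pivot.isna().any().any():
        raise ValueError("sample sheet is not a complete paired design")
    n = len(pivot)
    if n < 2:
        raise ValueError("need >= 2 complete genotype pairs")
    epi = m.values[pivot[EPITHELIAL].tolist()].to_numpy(float)
    fib = m.values[pivot[FIBROBLAST].tolist()].to_numpy(float)
    d = epi - fib
    d_mean = d.mean(axis=1)
    sd = np.maximum(d.std(axis=1, ddof=1), eps)
    t = d_mean / (sd / np.sqrt(n))
    return pd.DataFrame({"t": t, "d_mean": d_mean, "df": n - 1}, index=m.values.index)


def _sorted_layout(layout: pd.DataFrame) -> pd.DataFrame:
    return layout.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def window_scan(
    tstat: pd.DataFrame,
    layout: pd.DataFrame,
    window_bp: int = 300,
    q: float = 0.95,
) -> pd.DataFrame:
    """Binomial exceedance score of the window centred on every probe.

    Exceedance sets are global: E+ = {t > Q(q)}, E- = {t < Q(1-q)} over all
    probes. For each probe, the window collects probes whose centre lies
    within +/- window_bp/2 of its centre (same chromosome) and the one-sided
    p is P(X >= k) with X ~ Binomial(n_window, 1-q), per direction.

    Returns a frame aligned to ``layout`` row order with columns
    ``probe_id, chrom, start, end, p_pos, p_neg, k_pos, k_neg, n_window``.
    """
    t = tstat.loc[layout["probe_id"], "t"].to_numpy()
    thr_hi = np.quantile(t, q)
    thr_lo = np.quantile(t, 1.0 - q)
    exc_pos = t > thr_hi
    exc_neg = t < thr_lo
    pr = 1.0 - q
    half = window_bp / 2.0

    n = len(layout)
    k_pos = np.zeros(n, dtype=int)
    k_neg = np.zeros(n, dtype=int)
    n_win = np.zeros(n, dtype=int)
    chroms = layout["chrom"].to_numpy()
    centers = (layout["start"].to_numpy() + layout["end"].to_numpy()) / 2.0
    for chrom in pd.unique(chroms):
        ix = np.flatnonzero(chroms == chrom)
        if ix.size == 0:
            warnings.warn(f"chromosome {chrom!r} has no probes", stacklevel=2)
            continue
        order = ix[np.argsort(centers[ix], kind="stable")]
        c = centers[order]
        lo = np.searchsorted(c, c - half, side="left")
        hi = np.searchsorted(c, c + half, side="right")
        cp = np.concatenate([[0], np.cumsum(exc_pos[order])])
        cn = np.concatenate([[0], np.cumsum(exc_neg[order])])
        k_pos[order] = cp[hi] - cp[lo]
        k_neg[order] = cn[hi] - cn[lo]
        n_win[order] = hi - lo

    p_pos = stats.binom.sf(k_pos - 1, n_win, pr)
    p_neg = stats.binom.sf(k_neg - 1, n_win, pr)
    return pd.DataFrame(
        {
            "probe_id": layout["probe_id"].to_numpy(),
            "chrom": chroms,
            "start": layout["start"].to_numpy(),
            "end": layout["end"].to_numpy(),
            "p_pos": p_pos,
            "p_neg": p_neg,
            "k_pos": k_pos,
            "k_neg": k_neg,
            "n_window": n_win,
        }
    )


def call_regions(
    scores: pd.DataFrame,
    threshold_p: float,
    min_probes: int = 4,
    merge_gap_bp: int = 300,
) -> pd.DataFrame:
    """Merge window-significant probes into directional regions.

    Consecutive probes significant in the same direction and separated by at
    most ``merge_gap_bp`` are merged; runs with fewer than ``min_probes``
    probes are discarded. Positive-t significance maps to the
    epithelial-methylated direction. Probes significant in both directions
    (vanishingly rare) are assigned to the smaller p.
    """
    s = scores.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    sig_pos = s["p_pos"].to_numpy() < threshold_p
    sig_neg = s["p_neg"].to_numpy() < threshold_p
    both = sig_pos & sig_neg
    if both.any():
        pos_smaller = s["p_pos"].to_numpy() <= s["p_neg"].to_numpy()
        sig_pos[both] = pos_smaller[both]
        sig_neg[both] = ~pos_smaller[both]

    regions = []
    for direction, mask, pcol in ((EPI_METH, sig_pos, "p_pos"), (FIB_METH, sig_neg, "p_neg")):
        ix = np.flatnonzero(mask)
        if ix.size == 0:
            continue
        starts = s["start"].to_numpy()[ix]
        ends = s["end"].to_numpy()[ix]
        chroms = s["chrom"].to_numpy()[ix]
        pv = s[pcol].to_numpy()[ix]
        # split runs on chromosome change or genomic gap
        brk = np.flatnonzero((chroms[1:] != chroms[:-1]) | (starts[1:] - ends[:-1] > merge_gap_bp)) + 1
        for grp in np.split(np.arange(ix.size), brk):
            if grp.size < min_probes:
                continue
            regions.append(
                {
                    "chrom": chroms[grp[0]],
                    "start": int(starts[grp].min()),
                    "end": int(ends[grp].max()),
                    "direction": direction,
                    "n_probes": int(grp.size),
                    "best_p": float(pv[grp].min()),
                }
            )
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "direction", "n_probes", "best_p"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass
class CalibrationResult:
    """Outcome of permutation calibration of the window p-value cutoff."""

    threshold_p: float | None
    n_observed: int
    n_null_mean: float
    efdr: float
    n_permutations: int
    attainable: bool
    mode: str = "efdr"
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def realized_estimate(self) -> float:
        """False-positive estimate at the operating point actually used.

        When no cutoff attains the target level the detector reports zero
        regions, so the realized estimate is 0.
        """
        return self.efdr if self.attainable else 0.0


def calibrate_threshold(
    tstat: pd.DataFrame,
    layout: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 20,
    seed: int = 0,
    window_bp: int = 300,
    q: float = 0.95,
    min_probes: int = 4,
    merge_gap_bp: int = 300,
    thresholds: np.ndarray | None = None,
    mode: str = "efdr",
) -> CalibrationResult:
    """Choose the loosest window p cutoff controlling false positives.

    Each permutation shuffles the probe t-values over the fixed probe
    positions (equivalent, for window statistics, to randomly repositioning
    the probes) and re-runs the scan and region merging. Over a descending
    grid of candidate cutoffs, the largest cutoff whose empirical FDR
    (mean permutation region count / observed region count) is below
    ``alpha`` is returned; in ``mode="fpr"`` the criterion is instead that
    the mean permutation region count itself is below ``alpha``. When no
    cutoff qualifies the result is flagged unattainable and zero regions
    are reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("efdr", "fpr"):
        raise ValueError(f"unknown mode {mode!r}")
    thresholds = DEFAULT_THRESHOLD_GRID if thresholds is None else np.asarray(thresholds, float)
    thresholds = np.sort(thresholds)[::-1]

    def region_counts(ts: pd.DataFrame) -> np.ndarray:
        scores = window_scan(ts, layout, window_bp=window_bp, q=q)
        return np.array(
            [len(call_regions(scores, thr, min_probes=min_probes, merge_gap_bp=merge_gap_bp)) for thr in thresholds]
        )

    n_obs = region_counts(tstat)
    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_perm, len(thresholds)))
    t_vals = tstat["t"].to_numpy()
    for p in range(n_perm):
        perm = tstat.copy()
        perm["t"] = rng.permutation(t_vals)
        null_counts[p] = region_counts(perm)
    null_mean = null_counts.mean(axis=0)
    efdr = null_mean / np.maximum(n_obs, 1)

    table = pd.DataFrame(
        {"threshold_p": thresholds, "n_observed": n_obs, "n_null_mean": null_mean, "efdr": efdr}
    )
    if mode == "efdr":
        # alpha >= 1 is a vacuous constraint: any nonempty call set qualifies
        ok = (n_obs > 0) if alpha >= 1.0 else (efdr < alpha) & (n_obs > 0)
    else:
        ok = null_mean < alpha
    if not ok.any():
        return CalibrationResult(None, 0, float(null_mean[-1]), float("nan"), n_perm, False, mode, table)
    best = int(np.flatnonzero(ok)[0])  # grid is descending: first hit is loosest
    return CalibrationResult(
        float(thresholds[best]),
        int(n_obs[best]),
        float(null_mean[best]),
        float(efdr[best]),
        n_perm,
        True,
        mode,
        table,
    )


def detect_dmrs(
    m,
    sheet: pd.DataFrame,
    layout: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 20,
    seed: int = 0,
    window_bp: int = 300,
    q: float = 0.95,
    min_probes: int = 4,
    merge_gap_bp: int = 300,
    mode: str = "efdr",
) -> tuple[pd.DataFrame, CalibrationResult]:
    """Normalized matrix -> calibrated directional region calls."""
    tstat = paired_t(m, sheet)
    calib = calibrate_threshold(
        tstat,
        layout,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        window_bp=window_bp,
        q=q,
        min_probes=min_probes,
        merge_gap_bp=merge_gap_bp,
        mode=mode,
    )
    if not calib.attainable:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "direction", "n_probes", "best_p"])
        return empty, calib
    scores = window_scan(tstat, layout, window_bp=window_bp, q=q)
    regions = call_regions(scores, calib.threshold_p, min_probes=min_probes, merge_gap_bp=merge_gap_bp)
    return regions, calib
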