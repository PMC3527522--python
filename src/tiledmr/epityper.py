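"""Validation statistics on CpG-unit methylation matrices.

Per region, CpG-unit methylation fractions are pooled over units and samples
within each class; the two classes are compared with a rank-sum test (exact
by enumeration for small groups, tie-corrected normal approximation
otherwise) alongside the plain difference of class means. Heatmap row and
column orders come from average-linkage hierarchical clustering on
pairwise-complete Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

REQUIRED_COLUMNS = ["region_id", "unit_id", "sample_id", "fraction"]


@dataclass
class CpGUnitMatrix:
    """Long-format (region, unit, sample) methylation fractions with NaN missing."""

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["region_id", "unit_id", "sample_id"])
        if dup.any():
            first = self.data[dup].iloc[0]
            raise ValueError(
                "duplicate (region, unit, sample) entry: "
                f"({first['region_id']}, {first['unit_id']}, {first['sample_id']})"
            )
        frac = self.data["fraction"]
        bad = frac.notna() & ((frac < 0) | (frac > 1))
        if bad.any():
            raise ValueError("fractions outside [0, 1] present; use load_cpg_matrix to QC-filter")


def load_cpg_matrix(path) -> CpGUnitMatrix:
    """Load a long-format TSV, dropping out-of-range values and counting them.

    Missing values (empty or NA) are kept as NaN. Non-numeric fractions are
    malformed and rejected with their line numbers; duplicate keys are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"fraction": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    raw = df["fraction"].astype(str).str.strip()
    is_missing = df["fraction"].isna() | raw.isin({"", "NA", "NaN", "nan"})
    frac = pd.to_numeric(raw.where(~is_missing), errors="coerce")
    malformed = ~is_missing & frac.isna()
    if malformed.any():
        lines = (df.index[malformed] + 2).tolist()  # 1-based, after header
        raise ValueError(f"malformed fraction values on lines {lines[:20]}")
    df = df.assign(fraction=frac)
    out_of_range = frac.notna() & ((frac < 0) | (frac > 1))
    n_dropped = int(out_of_range.sum())
    df = df[~out_of_range].reset_index(drop=True)
    return CpGUnitMatrix(df[REQUIRED_COLUMNS], n_dropped=n_dropped)


def rank_sum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided rank-sum p-value.

    Exact by full enumeration of rank assignments (ties handled by midranks)
    when both groups have <= ``exact_max_n`` values; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:na].sum()
    n = na + nb
    if na <= exact_max_n and nb <= exact_max_n:
        ge = le = total = 0
        for comb in combinations(range(n), na):
            ws = ranks[list(comb)].sum()
            total += 1
            if ws >= w - 1e-9:
                ge += 1
            if ws <= w + 1e-9:
                le += 1
        return min(1.0, 2.0 * min(ge / total, le / total))
    mean = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def region_tests(
    m: CpGUnitMatrix,
    sheet: pd.DataFrame,
    class_a: str = "epithelial",
    class_b: str = "fibroblast",
    class_col: str = "cell_type",
    min_values: int = 3,
) -> pd.DataFrame:
    """Per-region class mean difference and rank-sum p on pooled unit values.

    Values are pooled over units and samples within each class; regions with
    fewer than ``min_values`` observed values in either class are flagged
    insufficient (NaN p and mean_diff). Returns columns ``region_id,
    mean_diff, p, n_a, n_b, sufficient``.
    """
    sample_class = sheet.set_index("sample_id")[class_col]
    df = m.data.copy()
    df["class"] = df["sample_id"].map(sample_class)
    if not set([class_a, class_b]) <= set(df["class"].dropna()):
        raise ValueError(f"classes {class_a!r}/{class_b!r} not both present")
    rows = []
    for region_id, g in df.groupby("region_id", sort=True):
        va = g.loc[g["class"] == class_a, "fraction"].dropna().to_numpy()
        vb = g.loc[g["class"] == class_b, "fraction"].dropna().to_numpy()
        if len(va) < min_values or len(vb) < min_values:
            rows.append(
                {"region_id": region_id, "mean_diff": np.nan, "p": np.nan,
                 "n_a": len(va), "n_b": len(vb), "sufficient": False}
            )
            continue
        rows.append(
            {
                "region_id": region_id,
                "mean_diff": float(va.mean() - vb.mean()),
                "p": rank_sum_p(va, vb),
                "n_a": len(va),
                "n_b": len(vb),
                "sufficient": True,
            }
        )
    return pd.DataFrame(rows, columns=["region_id", "mean_diff", "p", "n_a", "n_b", "sufficient"])


def _order(mat: np.ndarray) -> np.ndarray:
    if mat.shape[0] == 1:
        return np.array([0])
    d = nan_euclidean_distances(mat)
    finite = np.isfinite(d)
    if not finite.all():
        # pairs with no complete coordinate: push them maximally apart
        fill = (d[finite].max() if finite.any() else 1.0) * 2.0
        d[~finite] = fill
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return leaves_list(z)


def cluster_order(m: CpGUnitMatrix) -> tuple[list[str], list[tuple[str, str]], dict]:
    """Hierarchical-clustering orderings of samples (rows) and CpG units (columns).

    The matrix is samples x (region, unit); all-missing rows and columns are
    excluded and reported. Average linkage on pairwise-complete Euclidean
    distances; deterministic for fixed input.
    """
    wide = m.data.pivot(index="sample_id", columns=["region_id", "unit_id"], values="fraction")
    wide = wide.sort_index(axis=0).sort_index(axis=1)  # canonical order: input row order must not matter
    dropped_rows = wide.index[wide.isna().all(axis=1)].tolist()
    dropped_cols = wide.columns[wide.isna().all(axis=0)].tolist()
    wide = wide.drop(index=dropped_rows, columns=dropped_cols)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 non-missing rows and columns to cluster")
    row_order = [wide.index[i] for i in _order(wide.to_numpy())]
    col_order = [tuple(wide.columns[i]) for i in _order(wide.to_numpy().T)]
    report = {"dropped_rows": dropped_rows, "dropped_columns": dropped_cols}
    return row_order, col_order, report
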