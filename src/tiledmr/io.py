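"""Readers and writers for the plain-text formats used by the pipeline.

Layouts are BED6 plus two grid columns; signal matrices, sample sheets and
CpG-unit tables are TSV; region sets are BED; signal tracks are bedGraph.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SignalMatrix

LAYOUT_COLUMNS = ["chrom", "start", "end", "probe_id", "score", "strand", "array_row", "array_col"]


def write_layout(layout: pd.DataFrame, path) -> None:
    out = layout.assign(score=0, strand="+")[LAYOUT_COLUMNS]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_layout(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=LAYOUT_COLUMNS)
    return df[["probe_id", "chrom", "start", "end", "array_row", "array_col"]]


def write_signal(m: SignalMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id")


def read_signal(path, stage: str = "raw") -> SignalMatrix:
    values = pd.read_csv(path, sep="\t", index_col="probe_id")
    return SignalMatrix(values, stage=stage)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Region set to BED: name = direction (if present), score = -log10 best_p."""
    df = regions.copy()
    name = df["direction"] if "direction" in df else "."
    if "best_p" in df:
        score = -np.log10(np.clip(df["best_p"].to_numpy(float), 1e-300, None))
    else:
        score = 0.0
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": name,
            "score": np.round(score, 4),
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction"])
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "direction"})
        return df[["chrom", "start", "end", "direction"]]
    return df[["chrom", "start", "end"]]


def write_tss(tss: pd.DataFrame, path) -> None:
    """TSS table to BED6 (zero-length feature at the TSS position)."""
    out = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["position"],
            "end": tss["position"] + 1,
            "name": tss["name"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score", "strand"]
    )
    return pd.DataFrame(
        {"chrom": df["chrom"], "position": df["start"], "strand": df["strand"], "name": df["name"]}
    )


def write_islands(islands: pd.DataFrame, path) -> None:
    islands[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_islands(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    if "name" not in df:
        df["name"] = [f"island{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def write_bedgraph(track, path) -> None:
    with open(path, "w") as fh:
        for chrom, (start, step, values) in track.data.items():
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{start + i * step}\t{start + (i + 1) * step}\t{v:.6g}\n")


def write_cpg_units(units: pd.DataFrame, path) -> None:
    units.to_csv(path, sep="\t", index=False, na_rep="NA")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
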