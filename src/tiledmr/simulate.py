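"""Seeded synthetic data generators for the tiling-array methylation pipeline.

Produces a paired-design promoter tiling dataset: a probe layout on a
synthetic chromosome, raw hybridization intensities with genotype baselines,
smooth spatial array bias and embedded directional DMRs, plus the companion
fixtures used downstream (TSS / CpG-island tables, histone-like signal
tracks, CpG-unit methylation matrices) and the ground-truth region set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EPITHELIAL = "epithelial"
FIBROBLAST = "fibroblast"
CELL_TYPES = (EPITHELIAL, FIBROBLAST)

#: direction labels for regions: which cell type carries the methylation
EPI_METH = "epithelial_methylated"
FIB_METH = "fibroblast_methylated"
DIRECTIONS = (EPI_METH, FIB_METH)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    The promoter span defaults mirror a promoter tiling design covering
    7.5 kb upstream through 2.45 kb downstream of each TSS. Identical
    config + seed gives bit-identical output from every generator.
    """

    n_promoters: int = 100
    upstream_bp: int = 7500
    downstream_bp: int = 2450
    probe_spacing: int = 35
    probe_length: int = 25
    n_genotypes: int = 3
    dmr_fraction: float = 0.1
    dmr_length_min: int = 300
    dmr_length_max: int = 1500
    effect_size_log2: float = 1.0
    direction_prob: float = 0.5
    noise_sd: float = 0.5
    spatial_bias_amp: float = 0.3
    baseline_log2: float = 10.0
    genotype_sd: float = 0.25
    promoter_gap_bp: int = 5000
    chrom: str = "chr1"
    seed: int = 0

    @property
    def span(self) -> int:
        return self.upstream_bp + self.downstream_bp

    @property
    def probes_per_promoter(self) -> int:
        return math.ceil(self.span / self.probe_spacing)

    def validate(self) -> None:
        counts = {
            "n_promoters": self.n_promoters,
            "upstream_bp": self.upstream_bp,
            "downstream_bp": self.downstream_bp,
            "probe_spacing": self.probe_spacing,
            "probe_length": self.probe_length,
            "n_genotypes": self.n_genotypes,
            "dmr_length_min": self.dmr_length_min,
            "dmr_length_max": self.dmr_length_max,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0.0 <= self.dmr_fraction <= 1.0:
            raise ValueError(f"dmr_fraction must be in [0, 1], got {self.dmr_fraction}")
        if not 0.0 <= self.direction_prob <= 1.0:
            raise ValueError(f"direction_prob must be in [0, 1], got {self.direction_prob}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.dmr_length_min > self.dmr_length_max:
            raise ValueError("dmr_length_min must be <= dmr_length_max")
        if self.span < self.probe_length:
            raise ValueError(
                f"promoter span ({self.span} bp) shorter than probe_length "
                f"({self.probe_length} bp)"
            )

    def null(self) -> "SimConfig":
        """Copy of this config with no embedded DMRs."""
        return replace(self, dmr_fraction=0.0)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([cfg.seed, stream])


def promoter_tss_positions(cfg: SimConfig) -> np.ndarray:
    """Genomic TSS coordinate of each synthetic promoter (all + strand)."""
    stride = cfg.span + cfg.promoter_gap_bp
    return cfg.upstream_bp + stride * np.arange(cfg.n_promoters)


def generate_layout(cfg: SimConfig) -> pd.DataFrame:
    """Tile every promoter from -upstream to +downstream at probe_spacing.

    Returns a layout frame with columns ``probe_id, chrom, start, end,
    array_row, array_col``. Physical grid positions are assigned in a
    deterministic row-major order over a near-square grid, so genomic
    neighbours sit next to each other along grid rows.
    """
    cfg.validate()
    per = cfg.probes_per_promoter
    tss = promoter_tss_positions(cfg)
    offsets = -cfg.upstream_bp + cfg.probe_spacing * np.arange(per)
    starts = (tss[:, None] + offsets[None, :]).ravel()
    n = starts.size
    ncol = math.ceil(math.sqrt(n))
    idx = np.arange(n)
    layout = pd.DataFrame(
        {
            "probe_id": [f"p{prom:05d}_{j:04d}" for prom in range(cfg.n_promoters) for j in range(per)],
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + cfg.probe_length,
            "array_row": idx // ncol,
            "array_col": idx % ncol,
        }
    )
    return layout


def generate_sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    """Paired design sheet: each genotype appears once per cell type."""
    rows = []
    for g in range(cfg.n_genotypes):
        genotype = f"G{g + 1}"
        for ct in CELL_TYPES:
            rows.append({"sample_id": f"{genotype}_{ct}", "genotype": genotype, "cell_type": ct})
    return pd.DataFrame(rows)


@dataclass
class SignalMatrix:
    """Probes x samples intensity matrix with a processing-stage tag."""

    values: pd.DataFrame
    stage: str = "raw"

    STAGES = ("raw", "logged", "spatial", "quantile")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index


def _spatial_bias_surface(
    rng: np.random.Generator, nrow: int, ncol: int, amp: float
) -> np.ndarray:
    """Smooth low-frequency 2-D bias: sinusoid plus a couple of Gaussian blobs."""
    if amp == 0:
        return np.zeros((nrow, ncol))
    r = np.arange(nrow)[:, None] / max(nrow, 1)
    c = np.arange(ncol)[None, :] / max(ncol, 1)
    ph = rng.uniform(0, 2 * np.pi, size=4)
    surf = 0.5 * (np.sin(2 * np.pi * r + ph[0]) + np.sin(2 * np.pi * c + ph[1]))
    for _ in range(2):
        cr, cc = rng.uniform(0, 1), rng.uniform(0, 1)
        width = rng.uniform(0.15, 0.35)
        sign = rng.choice([-1.0, 1.0])
        surf = surf + sign * np.exp(-(((r - cr) ** 2 + (c - cc) ** 2) / (2 * width**2)))
    return amp * surf


def generate_truth(cfg: SimConfig) -> pd.DataFrame:
    """Embed one directional DMR in a ``dmr_fraction`` of promoters.

    Returns BED-like frame (chrom, start, end, direction); empty when
    dmr_fraction is zero. Regions always lie within the probe-covered
    promoter span.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    tss = promoter_tss_positions(cfg)
    carries = rng.random(cfg.n_promoters) < cfg.dmr_fraction
    rows = []
    for prom in np.flatnonzero(carries):
        max_len = min(cfg.dmr_length_max, cfg.span)
        min_len = min(cfg.dmr_length_min, max_len)
        length = int(rng.integers(min_len, max_len + 1))
        span_start = tss[prom] - cfg.upstream_bp
        start = int(span_start + rng.integers(0, cfg.span - length + 1))
        direction = EPI_METH if rng.random() < cfg.direction_prob else FIB_METH
        rows.append({"chrom": cfg.chrom, "start": start, "end": start + length, "direction": direction})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])


def _probe_dmr_indicator(layout: pd.DataFrame, truth: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean per-probe indicator of overlap with a DMR of each direction."""
    out = {d: np.zeros(len(layout), dtype=bool) for d in DIRECTIONS}
    if truth.empty:
        return out
    starts = layout["start"].to_numpy()
    ends = layout["end"].to_numpy()
    for _, reg in truth.iterrows():
        hit = (starts < reg["end"]) & (ends > reg["start"]) & (layout["chrom"].to_numpy() == reg["chrom"])
        out[reg["direction"]] |= hit
    return out


def generate_signal(
    cfg: SimConfig, layout: pd.DataFrame, truth: pd.DataFrame | None = None
) -> tuple[SignalMatrix, pd.DataFrame]:
    """Raw intensities 2^(baseline + genotype + spatial bias + effect + noise).

    The methylation effect adds ``effect_size_log2`` to probes inside a DMR,
    in the cell type the DMR direction names. Paired samples share a
    genotype-level baseline offset, so a paired comparison is the correct
    analysis. Returns (raw SignalMatrix, truth table).
    """
    cfg.validate()
    if truth is None:
        truth = generate_truth(cfg)
    rng = _rng(cfg, 2)
    sheet = generate_sample_sheet(cfg)
    n = len(layout)
    rows = layout["array_row"].to_numpy()
    cols = layout["array_col"].to_numpy()
    nrow, ncol = int(rows.max()) + 1, int(cols.max()) + 1

    geno_offset = {f"G{g + 1}": v for g, v in enumerate(rng.normal(0.0, cfg.genotype_sd, cfg.n_genotypes))}
    indicator = _probe_dmr_indicator(layout, truth)
    effect = {
        EPITHELIAL: cfg.effect_size_log2 * indicator[EPI_METH].astype(float),
        FIBROBLAST: cfg.effect_size_log2 * indicator[FIB_METH].astype(float),
    }

    data = {}
    for _, s in sheet.iterrows():
        surface = _spatial_bias_surface(rng, nrow, ncol, cfg.spatial_bias_amp)
        log2_signal = (
            cfg.baseline_log2
            + geno_offset[s["genotype"]]
            + surface[rows, cols]
            + effect[s["cell_type"]]
            + rng.normal(0.0, cfg.noise_sd, n)
        )
        data[s["sample_id"]] = np.exp2(log2_signal)
    values = pd.DataFrame(data, index=pd.Index(layout["probe_id"], name="probe_id"))
    return SignalMatrix(values, stage="raw"), truth


def generate_tracks(
    cfg: SimConfig,
    layout: pd.DataFrame,
    truth: pd.DataFrame,
    *,
    association: float = 1.0,
    island_fraction: float = 0.7,
    island_halfwidth: int = 500,
    track_baseline: float = 1.0,
    track_noise_sd: float = 0.2,
    step: int = 50,
    track_names: tuple[str, ...] = ("mark",),
):
    """TSS table, CpG-island table and histone-like signal tracks.

    Track enrichment is elevated by ``association`` over truth regions that
    are unmethylated in epithelium (i.e. fibroblast-methylated), emulating
    permissive histone marks; 0 makes tracks independent of the truth.
    """
    from .profiles import GenomicTrack  # local import to avoid a cycle

    cfg.validate()
    rng = _rng(cfg, 3)
    tss_pos = promoter_tss_positions(cfg)
    tss = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "position": tss_pos,
            "strand": "+",
            "name": [f"gene{ix:05d}" for ix in range(cfg.n_promoters)],
        }
    )
    has_island = rng.random(cfg.n_promoters) < island_fraction
    islands = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": np.maximum(tss_pos[has_island] - island_halfwidth, 0),
            "end": tss_pos[has_island] + island_halfwidth,
            "name": [f"cgi{ix:05d}" for ix in np.flatnonzero(has_island)],
        }
    )

    lo = int(layout["start"].min()) - 15000
    hi = int(layout["end"].max()) + 15000
    bin_start = max(0, (lo // step) * step)
    n_bins = (hi - bin_start) // step + 1
    centers = bin_start + step * np.arange(n_bins) + step / 2.0

    enrich = np.zeros(n_bins)
    if association != 0 and not truth.empty:
        fib = truth[truth["direction"] == FIB_METH]
        for _, reg in fib.iterrows():
            enrich[(centers >= reg["start"]) & (centers < reg["end"])] = association

    tracks = {}
    for name in track_names:
        values = track_baseline + enrich + rng.normal(0.0, track_noise_sd, n_bins)
        tracks[name] = GenomicTrack({cfg.chrom: (bin_start, step, values)})
    return tracks, tss, islands


def generate_cpg_units(
    cfg: SimConfig,
    truth: pd.DataFrame,
    *,
    n_units: int = 8,
    delta: float = 0.3,
    base_level: float = 0.45,
    noise_sd: float = 0.05,
    missing_rate: float = 0.05,
) -> pd.DataFrame:
    """CpG-unit methylation fractions for every truth region.

    Long-format frame (region_id, unit_id, sample_id, fraction). Group means
    are separated by ``delta`` in the region's direction; noise is a
    truncated Gaussian clipped to [0, 1]; a ``missing_rate`` fraction of
    entries is set to NaN, mirroring quality-filtered measurements.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    sheet = generate_sample_sheet(cfg)
    rows = []
    for ridx, reg in truth.reset_index(drop=True).iterrows():
        region_id = f"region{ridx:04d}"
        high = EPITHELIAL if reg["direction"] == EPI_METH else FIBROBLAST
        for u in range(n_units):
            for _, s in sheet.iterrows():
                mean = base_level + (delta / 2.0 if s["cell_type"] == high else -delta / 2.0)
                frac = float(np.clip(mean + rng.normal(0.0, noise_sd), 0.0, 1.0)) if noise_sd > 0 else float(np.clip(mean, 0.0, 1.0))
                if rng.random() < missing_rate:
                    frac = np.nan
                rows.append(
                    {"region_id": region_id, "unit_id": f"unit{u:02d}", "sample_id": s["sample_id"], "fraction": frac}
                )
    return pd.DataFrame(rows, columns=["region_id", "unit_id", "sample_id", "fraction"])
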