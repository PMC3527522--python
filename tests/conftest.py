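"""Shared fixtures. Expensive synthetic datasets are session-scoped."""

import numpy as np
import pandas as pd
import pytest

from tiledmr import (
    SimConfig,
    calibrate_threshold,
    call_regions,
    generate_layout,
    generate_sample_sheet,
    generate_signal,
    normalize,
    paired_t,
    window_scan,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_promoters=20, dmr_fraction=0.3, effect_size_log2=1.0, noise_sd=0.3, seed=5)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Strong-signal dataset at the scale used for detector recovery checks.

    Returns a dict with layout, sheet, truth, normalized matrix, t-stats,
    calibration and called regions (shared across the detection and
    acceptance tests to avoid recomputing ~20 s of work).
    """
    cfg = SimConfig(
        n_promoters=500, dmr_fraction=0.2, effect_size_log2=1.0, noise_sd=0.3, seed=7
    )
    layout = generate_layout(cfg)
    raw, truth = generate_signal(cfg, layout)
    sheet = generate_sample_sheet(cfg)
    norm = normalize(raw, layout)
    tstat = paired_t(norm, sheet)
    calib = calibrate_threshold(tstat, layout, alpha=0.05, n_perm=20, seed=1)
    scores = window_scan(tstat, layout)
    regions = call_regions(scores, calib.threshold_p)
    return {
        "cfg": cfg,
        "layout": layout,
        "sheet": sheet,
        "truth": truth,
        "norm": norm,
        "tstat": tstat,
        "scores": scores,
        "calib": calib,
        "regions": regions,
    }


def make_signal_matrix(diffs_by_probe, base=10.0):
    """Quantile-stage matrix with prescribed epithelial-fibroblast differences.

    ``diffs_by_probe``: array (n_probes, n_genotypes) of paired log2
    differences; fibroblast samples sit at ``base``, epithelial at
    ``base + diff``.
    """
    from tiledmr import SignalMatrix

    diffs = np.asarray(diffs_by_probe, float)
    n_probes, n_geno = diffs.shape
    data = {}
    for g in range(n_geno):
        data[f"G{g + 1}_epithelial"] = base + diffs[:, g]
        data[f"G{g + 1}_fibroblast"] = np.full(n_probes, base)
    values = pd.DataFrame(data, index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"))
    return SignalMatrix(values, stage="quantile")


def make_sheet(n_geno=3):
    rows = []
    for g in range(n_geno):
        for ct in ("epithelial", "fibroblast"):
            rows.append({"sample_id": f"G{g + 1}_{ct}", "genotype": f"G{g + 1}", "cell_type": ct})
    return pd.DataFrame(rows)
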