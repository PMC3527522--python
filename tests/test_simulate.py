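"""Synthetic-data generator tests: determinism, tiling arithmetic, embedded effects."""

import numpy as np
import pandas as pd
import pytest

from tiledmr import (
    EPI_METH,
    FIB_METH,
    SimConfig,
    generate_cpg_units,
    generate_layout,
    generate_sample_sheet,
    generate_signal,
    generate_tracks,
    generate_truth,
)
from tiledmr.simulate import promoter_tss_positions


class TestLayout:
    def test_probes_per_promoter_default_spacing(self):
        # span 7500 + 2450 = 9950 bp at 35 bp spacing -> ceil = 285
        cfg = SimConfig(n_promoters=100, probe_spacing=35)
        layout = generate_layout(cfg)
        assert cfg.probes_per_promoter == 285
        assert len(layout) == 100 * 285

    def test_single_probe_when_spacing_spans_promoter(self):
        cfg = SimConfig(n_promoters=1, probe_spacing=9950)
        assert len(generate_layout(cfg)) == 1

    def test_deterministic(self):
        cfg = SimConfig(n_promoters=5, seed=3)
        pd.testing.assert_frame_equal(generate_layout(cfg), generate_layout(cfg))

    def test_rejects_span_shorter_than_probe(self):
        cfg = SimConfig(upstream_bp=5, downstream_bp=5, probe_length=25)
        with pytest.raises(ValueError, match="probe_length"):
            generate_layout(cfg)

    def test_probe_ids_unique_and_sorted(self):
        layout = generate_layout(SimConfig(n_promoters=10))
        assert layout["probe_id"].is_unique
        assert (layout["start"] < layout["end"]).all()
        assert layout["start"].is_monotonic_increasing  # single chrom

    def test_every_probe_has_grid_position(self):
        layout = generate_layout(SimConfig(n_promoters=7))
        assert layout[["array_row", "array_col"]].notna().all().all()
        assert not layout.duplicated(["array_row", "array_col"]).any()

    def test_coverage_confined_to_promoter_span(self):
        cfg = SimConfig(n_promoters=10)
        layout = generate_layout(cfg)
        tss = promoter_tss_positions(cfg)
        rel = layout["start"].to_numpy() - np.repeat(tss, cfg.probes_per_promoter)
        assert rel.min() == -cfg.upstream_bp
        assert rel.max() < cfg.downstream_bp


class TestSampleSheet:
    def test_paired_design(self):
        sheet = generate_sample_sheet(SimConfig(n_genotypes=3))
        counts = sheet.groupby(["genotype", "cell_type"]).size()
        assert (counts == 1).all()
        assert len(sheet) == 6


class TestSignal:
    def test_null_config_has_empty_truth_and_zero_expected_diff(self):
        cfg = SimConfig(n_promoters=5, dmr_fraction=0.0, noise_sd=0.0, spatial_bias_amp=0.0, seed=2)
        layout = generate_layout(cfg)
        m, truth = generate_signal(cfg, layout)
        assert truth.empty
        logged = np.log2(m.values.to_numpy())
        for g in range(3):
            d = logged[:, 2 * g] - logged[:, 2 * g + 1]
            np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_noise_free_in_dmr_difference_is_exact_delta(self):
        cfg = SimConfig(
            n_promoters=20, dmr_fraction=0.5, effect_size_log2=1.0,
            noise_sd=0.0, spatial_bias_amp=0.0, direction_prob=1.0, seed=4,
        )
        layout = generate_layout(cfg)
        m, truth = generate_signal(cfg, layout)
        logged = np.log2(m.values.to_numpy())
        starts, ends = layout["start"].to_numpy(), layout["end"].to_numpy()
        in_dmr = np.zeros(len(layout), bool)
        for _, r in truth.iterrows():
            in_dmr |= (starts < r["end"]) & (ends > r["start"])
        assert in_dmr.any()
        epi = logged[:, [0, 2, 4]]
        fib = logged[:, [1, 3, 5]]
        d = epi - fib
        np.testing.assert_allclose(d[in_dmr], 1.0, atol=1e-9)
        np.testing.assert_allclose(d[~in_dmr], 0.0, atol=1e-9)

    def test_mean_in_dmr_difference_clt(self):
        cfg = SimConfig(
            n_promoters=500, dmr_fraction=0.2, effect_size_log2=1.0,
            noise_sd=0.5, spatial_bias_amp=0.0, seed=11,
        )
        layout = generate_layout(cfg)
        m, truth = generate_signal(cfg, layout)
        logged = np.log2(m.values.to_numpy())
        starts, ends = layout["start"].to_numpy(), layout["end"].to_numpy()
        diffs = []
        for _, r in truth.iterrows():
            hit = (starts < r["end"]) & (ends > r["start"])
            epi = logged[hit][:, [0, 2, 4]]
            fib = logged[hit][:, [1, 3, 5]]
            d = epi - fib
            if r["direction"] == FIB_METH:
                d = -d
            diffs.append(d.ravel())
        d = np.concatenate(diffs)
        # paired difference sd is sqrt(2) * noise_sd
        se = np.sqrt(2) * cfg.noise_sd / np.sqrt(len(d))
        assert abs(d.mean() - 1.0) < 1.96 * se

    def test_bit_identical_reruns(self):
        cfg = SimConfig(n_promoters=5, seed=9)
        layout = generate_layout(cfg)
        m1, t1 = generate_signal(cfg, layout)
        m2, t2 = generate_signal(cfg, layout)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_regions_inside_promoter_spans(self):
        cfg = SimConfig(n_promoters=50, dmr_fraction=0.5, seed=6)
        truth = generate_truth(cfg)
        tss = promoter_tss_positions(cfg)
        span_starts = tss - cfg.upstream_bp
        span_ends = tss + cfg.downstream_bp
        for _, r in truth.iterrows():
            inside = (span_starts <= r["start"]) & (r["end"] <= span_ends)
            assert inside.any()


class TestTracks:
    def test_one_tss_per_promoter(self):
        cfg = SimConfig(n_promoters=1, seed=0)
        layout = generate_layout(cfg)
        _, tss, _ = generate_tracks(cfg, layout, generate_truth(cfg))
        assert len(tss) == 1

    def test_zero_association_independent_of_truth(self):
        cfg = SimConfig(n_promoters=50, dmr_fraction=0.5, direction_prob=0.0, seed=13)
        layout = generate_layout(cfg)
        truth = generate_truth(cfg)
        tracks, _, _ = generate_tracks(cfg, layout, truth, association=0.0, track_noise_sd=0.2)
        start, step, values = tracks["mark"].data[cfg.chrom]
        centers = start + step * np.arange(len(values)) + step / 2
        in_reg = np.zeros(len(values), bool)
        for _, r in truth.iterrows():
            in_reg |= (centers >= r["start"]) & (centers < r["end"])
        # no planted association: means agree within Monte-Carlo error
        se = 0.2 * np.sqrt(1 / in_reg.sum() + 1 / (~in_reg).sum())
        assert abs(values[in_reg].mean() - values[~in_reg].mean()) < 4 * se

    def test_max_association_no_noise_exact_shift(self):
        cfg = SimConfig(n_promoters=30, dmr_fraction=0.5, direction_prob=0.0, seed=14)
        layout = generate_layout(cfg)
        truth = generate_truth(cfg)
        assert (truth["direction"] == FIB_METH).all()
        tracks, _, _ = generate_tracks(cfg, layout, truth, association=2.0, track_noise_sd=0.0)
        start, step, values = tracks["mark"].data[cfg.chrom]
        centers = start + step * np.arange(len(values)) + step / 2
        in_reg = np.zeros(len(values), bool)
        for _, r in truth.iterrows():
            in_reg |= (centers >= r["start"]) & (centers < r["end"])
        assert np.allclose(values[in_reg] - values[~in_reg].mean(), 2.0, atol=1e-9)


class TestCpGUnits:
    def _truth(self, n, direction=EPI_METH):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 10000,
             "end": np.arange(n) * 10000 + 500, "direction": direction}
        )

    def test_zero_delta_equal_means(self):
        cfg = SimConfig(n_promoters=5, seed=21)
        units = generate_cpg_units(cfg, self._truth(10), delta=0.0, noise_sd=0.0, missing_rate=0.0)
        epi = units[units["sample_id"].str.endswith("epithelial")]["fraction"]
        fib = units[units["sample_id"].str.endswith("fibroblast")]["fraction"]
        assert epi.mean() == pytest.approx(fib.mean(), abs=1e-12)

    def test_noise_free_delta_is_exact(self):
        # mirrors a 10% minimal group separation
        cfg = SimConfig(n_promoters=5, seed=22)
        units = generate_cpg_units(cfg, self._truth(6), delta=0.10, noise_sd=0.0, missing_rate=0.0)
        for _, g in units.groupby("region_id"):
            epi = g[g["sample_id"].str.endswith("epithelial")]["fraction"].mean()
            fib = g[g["sample_id"].str.endswith("fibroblast")]["fraction"].mean()
            assert epi - fib == pytest.approx(0.10, abs=1e-12)

    def test_full_missingness_flags_insufficient_downstream(self):
        from tiledmr import CpGUnitMatrix, region_tests

        cfg = SimConfig(n_promoters=5, seed=23)
        units = generate_cpg_units(cfg, self._truth(3), missing_rate=1.0)
        assert units["fraction"].isna().all()
        res = region_tests(CpGUnitMatrix(units), generate_sample_sheet(cfg))
        assert (~res["sufficient"]).all()
        assert res["p"].isna().all()

    def test_fractions_in_unit_interval(self):
        cfg = SimConfig(n_promoters=5, seed=24)
        units = generate_cpg_units(cfg, self._truth(5), delta=0.6, noise_sd=0.3, missing_rate=0.1)
        obs = units["fraction"].dropna()
        assert ((obs >= 0) & (obs <= 1)).all()

    def test_deterministic(self):
        cfg = SimConfig(n_promoters=5, seed=25)
        a = generate_cpg_units(cfg, self._truth(4))
        b = generate_cpg_units(cfg, self._truth(4))
        pd.testing.assert_frame_equal(a, b)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_promoters": 0},
            {"probe_spacing": -1},
            {"dmr_fraction": 1.5},
            {"noise_sd": -0.1},
            {"dmr_length_min": 500, "dmr_length_max": 300},
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()

    def test_null_variant(self):
        assert SimConfig(dmr_fraction=0.4).null().dmr_fraction == 0.0
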