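"""Synthetic generators: attachment tracks, fluorescence, lineages, maps."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from attachkin import (
    ChannelMap,
    FluorGenConfig,
    LineageGenConfig,
    ParameterError,
    PhenotypeMix,
    SimConfig,
    classify_fates,
    mean_thickness,
    model_nb,
    presets,
    roughness_coefficient,
    simulate_attachment,
    simulate_fluorescence,
    simulate_heightmap,
    simulate_lineage,
)


class TestPhenotypeMix:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            PhenotypeMix((0.8, 0.1), (1e-2, 1e-3))

    def test_rates_must_decrease(self):
        with pytest.raises(ParameterError):
            PhenotypeMix((0.5, 0.5), (1e-3, 1e-2))

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            PhenotypeMix((1.0,), (-1e-3,))


class TestSimulateAttachment:
    def test_zero_rate_never_attaches(self):
        mix = PhenotypeMix((1.0,), (0.0,))
        tracks = simulate_attachment(mix, SimConfig(n_cells=50, duration=300.0, seed=1))
        assert not any(t.attached.any() for t in tracks)

    def test_half_life_symmetry(self):
        # ln2/alpha = 300 s: half the cells are attached at t = 300 s
        alpha = np.log(2) / 300.0
        mix = PhenotypeMix((1.0,), (alpha,))
        cfg = SimConfig(n_cells=10_000, duration=600.0, seed=2)
        tracks = simulate_attachment(mix, cfg)
        idx = int(round(300.0 / cfg.frame_interval))
        frac = np.mean([t.attached[idx] for t in tracks])
        se = np.sqrt(0.25 / cfg.n_cells)
        assert abs(frac - 0.5) < 3 * se

    def test_ensemble_mean_matches_closed_form_at_every_frame(self, late_exp_params):
        f, a = late_exp_params
        mix = PhenotypeMix(tuple(f), tuple(a))
        cfg = SimConfig(n_cells=10_000, duration=3600.0, seed=3)
        tracks = simulate_attachment(mix, cfg)
        attached = np.stack([t.attached for t in tracks])
        emp_bulk = 1.0 - attached.mean(axis=0)
        expected = model_nb(cfg.times, f, a)
        se = np.sqrt(np.clip(expected * (1 - expected), 1e-12, None) / cfg.n_cells)
        # allow 3 MC standard errors everywhere (tiny floor where p -> 0/1)
        assert np.all(np.abs(emp_bulk - expected) <= 3 * se + 5e-4)

    def test_attached_flag_monotone_without_detachment(self):
        mix = presets.LATE_EXPONENTIAL_MIX
        tracks = simulate_attachment(mix, SimConfig(n_cells=200, duration=900.0, seed=4))
        for t in tracks:
            assert np.all(np.diff(t.attached.astype(int)) >= 0)

    def test_phenotype_fractions_converge(self):
        mix = presets.LATE_EXPONENTIAL_MIX
        tracks = simulate_attachment(mix, SimConfig(n_cells=10_000, duration=30.0, seed=5))
        frac_fast = np.mean([t.phenotype == 0 for t in tracks])
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(frac_fast - 0.8) < 3 * se

    def test_same_seed_bit_identical_different_seed_differs(self):
        mix = presets.LATE_EXPONENTIAL_MIX
        cfg = SimConfig(n_cells=30, duration=300.0, seed=6)
        t1 = simulate_attachment(mix, cfg)
        t2 = simulate_attachment(mix, cfg)
        t3 = simulate_attachment(mix, SimConfig(n_cells=30, duration=300.0, seed=7))
        assert all(np.array_equal(a.xy, b.xy) for a, b in zip(t1, t2))
        assert all(np.array_equal(a.attached, b.attached) for a, b in zip(t1, t2))
        assert any(not np.array_equal(a.attached, b.attached) for a, b in zip(t1, t3))

    def test_detachment_produces_on_off_cycles(self):
        mix = PhenotypeMix((1.0,), (5e-3,), (2e-3,))
        tracks = simulate_attachment(mix, SimConfig(n_cells=300, duration=3600.0, seed=8))
        detaches = sum(
            int(np.sum(np.diff(t.attached.astype(int)) == -1)) for t in tracks
        )
        assert detaches > 0

    def test_positions_stay_inside_field(self):
        mix = presets.LATE_EXPONENTIAL_MIX
        cfg = SimConfig(n_cells=100, duration=3600.0, seed=9, diffusion_bulk=2.0)
        tracks = simulate_attachment(mix, cfg)
        for t in tracks:
            assert t.xy[:, 0].min() >= 0 and t.xy[:, 0].max() <= cfg.field[0]
            assert t.xy[:, 1].min() >= 0 and t.xy[:, 1].max() <= cfg.field[1]


class TestSimulateFluorescence:
    def test_perfect_copula_zero_noise_is_antimonotone(self):
        maps = {
            "egfp": ChannelMap(direction=-1, scale=300.0, noise_sd=0.0),
            "lectin": ChannelMap(direction=+1, scale=300.0, noise_sd=0.0),
        }
        cfg = FluorGenConfig(n_cells=500, channel_maps=maps, target_pearson=None, seed=1)
        table = simulate_fluorescence(cfg)
        rho_s = spearmanr(table.data.egfp_au, table.data.lectin_au).statistic
        assert rho_s == pytest.approx(-1.0)
        assert np.corrcoef(table.data.egfp_au, table.data.lectin_au)[0, 1] < 0

    def test_calibrated_pearson_hits_published_anticorrelation(self):
        table = simulate_fluorescence(presets.fluorescence_config(n_cells=2000, seed=11))
        r = table.meta["realized_pearson"]
        assert -0.50 <= r <= -0.40

    def test_all_intensities_positive(self):
        table = simulate_fluorescence(presets.fluorescence_config(n_cells=2000, seed=12))
        assert (table.data[["egfp_au", "lectin_au", "latent_au"]] > 0).all().all()

    def test_degenerate_sample_flags_skipped_calibration(self):
        table = simulate_fluorescence(FluorGenConfig(n_cells=2, seed=1))
        assert table.meta["calibration_checked"] is False
        assert "flag" in table.meta

    def test_target_outside_open_interval_rejected(self):
        with pytest.raises(ParameterError):
            FluorGenConfig(n_cells=10, target_pearson=-1.0)

    def test_unattainable_target_rejected(self):
        # heavy multiplicative noise caps how negative the correlation can be
        maps = {
            "egfp": ChannelMap(direction=-1, scale=300.0, noise_sd=2.5),
            "lectin": ChannelMap(direction=+1, scale=300.0, noise_sd=2.5),
        }
        with pytest.raises(ParameterError):
            simulate_fluorescence(
                FluorGenConfig(n_cells=10, channel_maps=maps, target_pearson=-0.9)
            )

    def test_marginal_scale_matches_published_moments(self):
        # inverted-reporter channel: arithmetic mean ~312 a.u., SD ~308 a.u.
        table = simulate_fluorescence(presets.fluorescence_config(n_cells=50_000, seed=13))
        e = table.data.egfp_au
        assert e.mean() == pytest.approx(312.0, rel=0.05)
        assert e.std(ddof=1) == pytest.approx(308.0, rel=0.10)


class TestSimulateLineage:
    def test_all_stay_grows_geometrically(self):
        cfg = LineageGenConfig(1, (1.0, 0.0, 0.0), 100.0, 700.0, seed=1)
        forest = simulate_lineage(cfg)
        counts = classify_fates(forest)
        assert counts.n_both_stay == counts.n_div
        assert counts.n_div > 10  # ~2^(T/interval) divisions from one founder

    def test_all_leave_gives_one_division_per_founder(self):
        cfg = LineageGenConfig(50, (0.0, 0.0, 1.0), 100.0, 1e6, seed=2)
        forest = simulate_lineage(cfg)
        counts = classify_fates(forest)
        assert counts.n_div == 50
        assert counts.n_both_leave == 50

    def test_fate_frequencies_within_binomial_error(self):
        probs = (0.1, 0.3, 0.6)
        cfg = presets.lineage_config(probs, seed=3)
        counts = classify_fates(simulate_lineage(cfg))
        n = counts.n_div
        assert n >= 300
        for observed, p in zip(
            (counts.n_both_stay, counts.n_one_stays, counts.n_both_leave), probs
        ):
            assert abs(observed / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_short_duration_yields_zero_divisions(self):
        cfg = LineageGenConfig(5, (0.5, 0.3, 0.2), 1e9, 10.0, seed=4)
        counts = classify_fates(simulate_lineage(cfg))
        assert counts.n_div == 0

    def test_seed_reproducibility(self):
        cfg = presets.lineage_config(presets.FATE_WILD_TYPE, seed=5)
        f1, f2 = simulate_lineage(cfg), simulate_lineage(cfg)
        assert {n.id: (n.t_division, n.fate) for n in f1.nodes.values()} == {
            n.id: (n.t_division, n.fate) for n in f2.nodes.values()
        }


class TestSimulateHeightmap:
    def test_zero_target_gives_constant_map(self):
        h = simulate_heightmap(10.0, 0.0, (8, 8), seed=1)
        assert np.all(h.grid == 10.0)
        assert mean_thickness(h) == 10.0

    def test_calibrated_roughness_within_band(self):
        h = simulate_heightmap(10.0, 0.5, (64, 64), seed=2)
        assert 0.45 <= roughness_coefficient(h) <= 0.55
        assert mean_thickness(h) == pytest.approx(10.0, rel=1e-9)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ParameterError):
            simulate_heightmap(10.0, 5.0, (32, 32), seed=3)

    def test_thicker_smoother_vs_thinner_rougher_ordering(self):
        # a uniform-matrix-like biofilm: thicker and smoother than wild-type-like
        uniform_like = simulate_heightmap(20.0, 0.2, (48, 48), seed=4)
        wildtype_like = simulate_heightmap(10.0, 0.6, (48, 48), seed=4)
        assert mean_thickness(uniform_like) > mean_thickness(wildtype_like)
        assert roughness_coefficient(uniform_like) < roughness_coefficient(wildtype_like)
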