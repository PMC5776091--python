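"""Generator-level tests: composition, conservation, kinetics, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from polefocus import SimulationConfig, simulate_population
from polefocus.config import ConfigurationError, FrapSettings
from polefocus.simulate import (
    StateError,
    _render_frames,
    cluster_footprint_area,
    gaussian_copula_pair,
    render_cell_frame,
    simulate_frap_stack,
    simulate_quiescence_exit,
    simulate_reporter_channel,
)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(pattern_weights=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ConfigurationError):
        SimulationConfig(cluster_fraction_range=(-0.1, 0.5))
    with pytest.raises(ConfigurationError):
        SimulationConfig(reporter_rank_corr=1.5)
    with pytest.raises(ConfigurationError):
        FrapSettings(bleach_efficiency=1.5).validate()


def test_degenerate_weights_yield_only_diffuse_cells():
    cfg = SimulationConfig(n_cells=20, n_frames=4,
                           pattern_weights=(0, 0, 0, 1.0), nucleation_rate=0.0,
                           seed=3)
    stack, truth = simulate_population(cfg)
    assert (truth.cells.pattern == "UC").all()
    assert not truth.frames.cluster_present.any()


def test_pattern_fractions_match_weights_within_three_binomial_sds():
    weights = (0.09, 0.43, 0.11, 0.37)
    cfg = SimulationConfig(n_cells=1000, n_frames=2, pattern_weights=weights,
                           nucleation_rate=0.0, seed=5)
    _, truth = simulate_population(cfg)
    frac = truth.cells.pattern.value_counts(normalize=True)
    for w, name in zip(weights, ("non-Dyn", "Dyn-1P", "Dyn-OP", "UC")):
        sd = math.sqrt(w * (1 - w) / 1000)
        assert abs(frac.get(name, 0.0) - w) <= 3 * sd


def test_budget_conserved_across_formation_noise_free():
    """Summed per-cell intensity is unchanged by cluster formation: the new
    cluster is built from the pre-existing diffuse pool."""
    cfg = SimulationConfig(n_cells=20, n_frames=15, frame_interval=180.0,
                           pattern_weights=(0, 0, 0, 1.0), nucleation_rate=0.03,
                           growth_rate=0.0, background_level=0.0,
                           read_noise_sd=0.0, seed=5)
    stack, truth = simulate_population(cfg)
    fluor = stack.channel("mcherry")
    formed = truth.cells.dropna(subset=["nucleation_min"])
    formed = formed[formed.formation_complete_min
                    < (cfg.n_frames - 1) * cfg.frame_interval / 60]
    assert len(formed) >= 3
    for cid in formed.cell_id:
        sums = []
        for f in range(stack.n_frames):
            mask = truth.true_mask(int(cid), f, fluor.shape[1:])
            sums.append(float(fluor[f][mask].sum()))
        sums = np.asarray(sums)
        assert (sums.max() - sums.min()) / sums.mean() < 1e-3


def test_nucleation_times_are_exponential_and_length_independent():
    cfg = SimulationConfig(n_cells=500, n_frames=2,
                           pattern_weights=(0, 0, 0, 1.0),
                           nucleation_rate=0.008, seed=4)
    _, truth = simulate_population(cfg)
    t = truth.cells.nucleation_min.dropna().to_numpy()
    assert len(t) == 500
    _, p = lilliefors(t, dist="exp")
    assert p > 0.01
    rho, _ = sps.spearmanr(t, truth.cells.birth_length_um.to_numpy())
    assert abs(rho) < 3.0 / math.sqrt(len(t))


def test_true_speed_follows_configured_power_law():
    cfg = SimulationConfig(n_cells=400, n_frames=2, nucleation_rate=0.0,
                           pattern_weights=(0, 0.5, 0.5, 0), seed=8)
    _, truth = simulate_population(cfg)
    cells = truth.cells
    x = np.log(cells.cluster_area_um2.to_numpy())
    y = np.log(cells.speed_um_s.to_numpy())
    res = sps.linregress(x, y)
    assert abs(res.slope - (-cfg.speed_exponent)) < 2 * res.stderr


def test_fixed_seed_reruns_are_bit_identical():
    cfg = SimulationConfig(n_cells=12, n_frames=5, seed=42)
    s1, t1 = simulate_population(cfg)
    s2, t2 = simulate_population(cfg)
    assert np.array_equal(s1.data, s2.data)
    pd.testing.assert_frame_equal(t1.frames, t2.frames)


class TestRenderCellFrame:
    def test_uniform_cell_has_zero_pixel_sd(self):
        cfg = SimulationConfig(read_noise_sd=0.0, background_level=0.0)
        st = dict(cx_um=2.0, cy_um=1.0, length_um=3.0, phi=0.0, budget=1000.0)
        phase, fluor = render_cell_frame(st, cfg)
        mask = phase > 0
        assert mask.sum() > 0
        assert float(fluor[mask].std()) == pytest.approx(0.0, abs=1e-6)
        assert float(fluor[mask].sum()) == pytest.approx(1000.0, rel=1e-6)

    def test_cluster_receives_configured_budget_share(self):
        cfg = SimulationConfig(read_noise_sd=0.0, background_level=0.0)
        st = dict(cx_um=2.0, cy_um=1.0, length_um=3.0, phi=0.5, budget=1000.0,
                  cluster_x_um=1.0, cluster_y_um=1.0, sigma_um=0.15)
        phase, fluor = render_cell_frame(st, cfg)
        mask = phase > 0
        n = mask.sum()
        diffuse_total = 0.5 * 1000.0
        spot = fluor[mask].sum() - diffuse_total
        assert spot == pytest.approx(500.0, rel=1e-3)

    def test_cluster_centroid_outside_mask_raises(self):
        cfg = SimulationConfig(read_noise_sd=0.0)
        st = dict(cx_um=2.0, cy_um=1.0, length_um=3.0, phi=0.5, budget=1000.0,
                  cluster_x_um=3.9, cluster_y_um=1.0, sigma_um=0.15)
        with pytest.raises(StateError):
            render_cell_frame(st, cfg)

    def test_overlapping_cells_raise_state_error(self):
        cfg = SimulationConfig(read_noise_sd=0.0)
        rows = []
        for cid, cx in enumerate((2.0, 3.0)):  # overlapping rods
            rows.append(dict(cell_id=cid, frame=0, time_min=0.0, cx_um=cx,
                             cy_um=1.0, length_um=3.0, budget=1000.0, phi=0.0,
                             cluster_present=False, cluster_x_um=np.nan,
                             cluster_y_um=np.nan, sigma_um=0.15,
                             cluster_area_um2=np.nan, axial_s=np.nan,
                             speed_um_s=0.0))
        records = pd.DataFrame(rows)
        with pytest.raises(StateError):
            _render_frames(records, cfg, (20, 70),
                           np.random.default_rng(0))


class TestReporterChannel:
    def _truth(self, n, seed, rank_corr):
        cfg = SimulationConfig(n_cells=n, n_frames=1, growth_rate=0.0,
                               qx_phi_continuous=(0.05, 0.7),
                               reporter_rank_corr=rank_corr, seed=seed)
        _, truth = simulate_quiescence_exit(cfg)
        return truth, cfg

    def test_zero_rank_corr_gives_independence(self):
        truth, cfg = self._truth(300, 2, 0.0)
        rep = truth.reporter
        rho, _ = sps.spearmanr(rep.clustering_level, rep.reporter_mean)
        assert abs(rho) < 3.0 / math.sqrt(len(rep))

    def test_perfect_anticorrelation_is_antimonotone(self):
        truth, cfg = self._truth(100, 3, -1.0)
        rep = truth.reporter
        rho, _ = sps.spearmanr(rep.clustering_level, rep.reporter_mean)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_configured_rank_correlation_recovered(self):
        truth, cfg = self._truth(500, 4, -0.16)
        rep = truth.reporter
        rho, _ = sps.spearmanr(rep.clustering_level, rep.reporter_mean)
        assert abs(rho - (-0.16)) < 3.0 / math.sqrt(len(rep))

    def test_copula_requires_configured_correlation(self):
        cfg = SimulationConfig(n_cells=10, n_frames=1)
        _, truth = simulate_quiescence_exit(cfg)
        with pytest.raises(ConfigurationError):
            simulate_reporter_channel(truth, cfg)


class TestFrapGenerator:
    def test_zero_exchange_rate_gives_flat_curve(self):
        fs = FrapSettings(exchange_rate=0.0, recovery_asymptote=5.0,
                          synthesis_asymptote=0.0, n_postbleach_frames=10)
        cfg = SimulationConfig(n_cells=2, frame_interval=10.0, frap=fs,
                               read_noise_sd=0.0, seed=1)
        stack, truth = simulate_frap_stack(cfg)
        assert np.allclose(truth.frap_truth.recovery_pct, 0.0)
        fluor = stack.channel("mcherry")
        post = fluor[fs.bleach_frame:]
        assert np.allclose(post, post[0], atol=1e-3)

    def test_analytic_curve_at_one_over_k(self):
        fs = FrapSettings.for_endpoint(6.0, k=0.005)
        val = fs.analytic_recovery(1.0 / 0.005)
        assert val == pytest.approx(fs.total_asymptote * (1 - math.exp(-1)),
                                    rel=1e-12)

    def test_endpoint_constructor_hits_requested_level(self):
        fs = FrapSettings.for_endpoint(6.0, k=0.005, t_end=600.0)
        assert fs.analytic_recovery(600.0) == pytest.approx(6.0, rel=1e-12)
        cm = FrapSettings.for_endpoint(4.0, k=0.005, synthesis_fraction=0.0)
        assert cm.synthesis_asymptote == 0.0
        assert cm.analytic_recovery(600.0) == pytest.approx(4.0, rel=1e-12)


def test_cluster_footprint_area_roundtrip():
    from polefocus.simulate import sigma_for_area

    for sigma in (0.08, 0.15, 0.22):
        assert sigma_for_area(cluster_footprint_area(sigma)) == pytest.approx(sigma)


def test_copula_pair_hits_extreme_ranks(rng):
    x = rng.uniform(size=200)
    z = gaussian_copula_pair(x, 1.0, rng)
    assert sps.spearmanr(x, z)[0] == pytest.approx(1.0)
    z = gaussian_copula_pair(x, -1.0, rng)
    assert sps.spearmanr(x, z)[0] == pytest.approx(-1.0)
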