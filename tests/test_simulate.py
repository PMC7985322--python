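"""Simulator contracts: conservation, determinism, kinetics, noise statistics."""

import numpy as np
import pytest

from punctakit import (
    ConfigError,
    PlacementError,
    SimulationConfig,
    kinetics_factor,
    matched_blocked_config,
    simulate_blocking_endpoint,
    simulate_dissolution_movie,
    simulate_frap_movie,
)

NOISELESS = dict(noise_gain=0, read_noise_sd=0)


def test_config_rejects_bad_values():
    with pytest.raises(ConfigError):
        SimulationConfig(tau_s=-1.0)
    with pytest.raises(ConfigError):
        SimulationConfig(onset_s=-5.0)
    with pytest.raises(ConfigError):
        SimulationConfig(partition_coefficient=0.8, n_droplets=3)
    with pytest.raises(ConfigError):
        SimulationConfig(kinetics_model="bogus")
    with pytest.raises(ConfigError):
        SimulationConfig.from_dict({"tau_s": 30.0, "bogus_key": 1})


def test_placement_failure_is_explicit():
    cfg = SimulationConfig(image_shape=(48, 48), n_droplets=40,
                           droplet_radius_px=(8.0, 9.0), seed=1, **NOISELESS)
    with pytest.raises(PlacementError):
        simulate_dissolution_movie(cfg)


def test_droplets_inside_cell_footprint():
    cfg = SimulationConfig(seed=9, n_frames=2, **NOISELESS)
    _, truth = simulate_dissolution_movie(cfg)
    assert truth.droplet_coverage is not None
    assert not ((truth.droplet_coverage > 0) & ~truth.true_cell_mask).any()


def test_noiseless_conservation():
    """Dissolution redistributes dense-phase signal: totals constant to 1e-9."""
    for model in ("sigmoid_decay", "exponential_decay"):
        cfg = SimulationConfig(seed=3, kinetics_model=model, n_frames=50,
                               tau_s=25.0, onset_s=20.0, **NOISELESS)
        stack, _ = simulate_dissolution_movie(cfg)
        sums = stack.pixels.reshape(cfg.n_frames, -1).sum(axis=1)
        assert np.max(np.abs(sums - sums[0])) / sums[0] < 1e-9


def test_constant_model_frames_identical():
    cfg = SimulationConfig(seed=3, kinetics_model="constant", n_frames=6,
                           **NOISELESS)
    stack, _ = simulate_dissolution_movie(cfg)
    for i in range(1, 6):
        np.testing.assert_array_equal(stack.pixels[i], stack.pixels[0])


def test_sigmoid_true_fraction_matches_scalar_closed_form():
    """Renderer-derived fractions equal an independently coded logistic."""
    cfg = SimulationConfig(seed=3, kinetics_model="sigmoid_decay", tau_s=30.0,
                           onset_s=60.0, n_frames=90, frame_interval_s=2.0,
                           **NOISELESS)
    stack, truth = simulate_dissolution_movie(cfg)
    # independent scalar oracle, written from the model definition:
    # excess(t) = E0 / (1 + exp((t - (onset + 3 tau)) / tau)), lost excess
    # moves to the dilute pool, fraction = dense excess / constant total.
    e0 = cfg.dilute_level * (cfg.partition_coefficient - 1.0)
    a_drop = truth.droplet_coverage.sum()
    a_cell = truth.true_cell_mask.sum()
    total = cfg.dilute_level * a_cell + e0 * a_drop
    for i, t in enumerate(stack.times_s):
        f = 1.0 / (1.0 + np.exp((t - (60.0 + 3 * 30.0)) / 30.0))
        assert truth.true_fraction[i] == pytest.approx(e0 * f * a_drop / total,
                                                       rel=1e-9)


def test_determinism_bit_identical():
    cfg = SimulationConfig(seed=12, n_frames=10)
    s1, t1 = simulate_dissolution_movie(cfg)
    s2, t2 = simulate_dissolution_movie(cfg)
    np.testing.assert_array_equal(s1.pixels, s2.pixels)
    np.testing.assert_array_equal(t1.true_condensate_mask, t2.true_condensate_mask)
    s3, _ = simulate_dissolution_movie(SimulationConfig(seed=13, n_frames=10))
    assert not np.array_equal(s1.pixels, s3.pixels)


def test_frame_streams_independent_of_frame_count():
    """Shortening the movie must not reshuffle the noise of earlier frames."""
    long = simulate_dissolution_movie(SimulationConfig(seed=5, n_frames=20))[0]
    short = simulate_dissolution_movie(SimulationConfig(seed=5, n_frames=8))[0]
    np.testing.assert_array_equal(long.pixels[:8], short.pixels)


@pytest.mark.parametrize("model,sign", [("sigmoid_decay", -1),
                                        ("exponential_decay", -1),
                                        ("sigmoid_growth", +1)])
def test_true_fraction_monotone(model, sign):
    cfg = SimulationConfig(seed=4, kinetics_model=model, n_frames=40,
                           tau_s=20.0, onset_s=15.0, **NOISELESS)
    _, truth = simulate_dissolution_movie(cfg)
    diffs = np.diff(truth.true_fraction) * sign
    assert np.all(diffs >= -1e-12)
    assert np.all((truth.true_fraction >= 0) & (truth.true_fraction <= 1))


def test_kinetics_factor_limits():
    assert kinetics_factor(0.0, "constant", 10.0, 0.0) == 1.0
    assert kinetics_factor(50.0, "exponential_decay", 10.0, 50.0) == 1.0
    assert kinetics_factor(60.0, "exponential_decay", 10.0, 50.0) == pytest.approx(
        np.exp(-1.0))
    # sigmoid midpoint sits 3 tau after onset
    assert kinetics_factor(50.0 + 30.0, "sigmoid_decay", 10.0, 50.0) == pytest.approx(0.5)


def test_noise_statistics_background():
    """Background pixels: Poisson shot noise + Gaussian read noise."""
    cfg = SimulationConfig(image_shape=(192, 192), seed=21, n_frames=1,
                           kinetics_model="constant", background_level=10.0,
                           noise_gain=1.0, read_noise_sd=2.0)
    stack, truth = simulate_dissolution_movie(cfg)
    outside = ~truth.true_cell_mask
    vals = stack.pixels[0][outside]
    n = vals.size
    assert n >= 10_000
    se_mean = np.sqrt((10.0 + 4.0) / n)
    assert abs(vals.mean() - 10.0) < 3 * se_mean
    expected_var = 10.0 * 1.0 + 2.0 ** 2  # gain * level + read^2
    # chi-square interval for the sample variance at 3.5 sigma
    sd_var = expected_var * np.sqrt(2.0 / (n - 1))
    assert abs(vals.var(ddof=1) - expected_var) < 3.5 * sd_var


def test_shrink_mode_also_conserves_and_decays():
    cfg = SimulationConfig(seed=7, kinetics_model="exponential_decay",
                           dissolution_mode="shrink", n_frames=40, tau_s=20.0,
                           onset_s=10.0, **NOISELESS)
    stack, truth = simulate_dissolution_movie(cfg)
    sums = stack.pixels.reshape(cfg.n_frames, -1).sum(axis=1)
    assert np.max(np.abs(sums - sums[0])) / sums[0] < 1e-9
    assert truth.true_fraction[-1] < truth.true_fraction[0]
    # dense footprint really shrinks
    assert truth.true_condensate_mask[-1].sum() < truth.true_condensate_mask[0].sum()


# ------------------------------------------------------------------- FRAP

def test_frap_immobile_trace_flat_after_bleach():
    cfg = SimulationConfig(seed=5, kinetics_model="constant", n_frames=30,
                           frame_interval_s=5.0, **NOISELESS)
    stack, truth = simulate_frap_movie(cfg, bleach_frame=5, bleach_depth=0.7,
                                       mobile_fraction=0.0, exchange_tau_s=30.0)
    tr = truth.true_trace
    post = tr.raw_bleach_integrated[5:]
    np.testing.assert_allclose(post, post[0], rtol=1e-12)


def test_frap_full_recovery_returns_to_prebleach_ratio():
    cfg = SimulationConfig(seed=5, kinetics_model="constant", n_frames=60,
                           frame_interval_s=5.0, **NOISELESS)
    stack, truth = simulate_frap_movie(cfg, bleach_frame=5, bleach_depth=0.7,
                                       mobile_fraction=1.0, exchange_tau_s=2.0)
    tr = truth.true_trace
    r = tr.raw_bleach_integrated / tr.raw_total_integrated
    assert r[-1] == pytest.approx(r[:5].mean(), rel=1e-9)


def test_frap_normalized_plateau_equals_mobile_fraction():
    """Noiseless simulation + normalization: plateau = mobile fraction to 1e-6."""
    from punctakit import measure_frap_trace, normalize_frap

    cfg = SimulationConfig(seed=5, kinetics_model="constant", n_frames=100,
                           frame_interval_s=5.0, **NOISELESS)
    stack, truth = simulate_frap_movie(cfg, bleach_frame=5, bleach_depth=0.7,
                                       mobile_fraction=0.2, exchange_tau_s=20.0)
    trace = normalize_frap(measure_frap_trace(
        stack, truth.bleach_region, truth.true_cell_mask, 5,
        cfg.background_level))
    assert trace.normalized[-1] == pytest.approx(0.2, abs=1e-6)


def test_frap_region_outside_cell_errors():
    cfg = SimulationConfig(seed=5, kinetics_model="constant", n_frames=10,
                           **NOISELESS)
    bad_region = np.zeros(cfg.image_shape, dtype=bool)
    bad_region[0:3, 0:3] = True  # image corner, outside the cell ellipse
    with pytest.raises(ConfigError):
        simulate_frap_movie(cfg, bleach_frame=2, bleach_region=bad_region)


# ----------------------------------------------------------------- endpoint

def test_endpoint_blocked_scene_zero_ratio():
    cfg = SimulationConfig(seed=6, n_frames=1, kinetics_model="constant",
                           **NOISELESS)
    blocked = matched_blocked_config(cfg)
    a, b, truth = simulate_blocking_endpoint(cfg, blocked)
    assert truth.true_intensity_ratio_b == 0.0
    assert truth.true_intensity_ratio_a > 0.2
    # matched total expected cell intensity
    assert a.pixels.sum() == pytest.approx(b.pixels.sum(), rel=1e-9)


def test_endpoint_all_signal_in_droplets_gives_ratio_one():
    cfg = SimulationConfig(seed=6, n_frames=1, kinetics_model="constant",
                           dilute_level=0.0, dense_level=200.0,
                           background_level=0.0, **NOISELESS)
    cfg2 = SimulationConfig(seed=6, n_frames=1, kinetics_model="constant",
                            **NOISELESS)
    _, _, truth = simulate_blocking_endpoint(cfg, cfg2)
    assert truth.true_intensity_ratio_a == pytest.approx(1.0, abs=1e-12)


def test_endpoint_mismatched_geometry_errors():
    cfg_a = SimulationConfig(seed=6, n_frames=1, **NOISELESS)
    cfg_b = SimulationConfig(seed=6, n_frames=1,
                             cell_semi_axes_yx=(30.0, 30.0), **NOISELESS)
    with pytest.raises(ConfigError):
        simulate_blocking_endpoint(cfg_a, cfg_b)
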