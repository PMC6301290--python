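import numpy as np
import pytest

from capturestress.classify import ExerciseMetrics
from capturestress.io import read_accel_csv, read_deployment_table
from capturestress.synthetic import (BoutModelConfig, CovariateModel,
                                     EndpointModel, PhysioResponseConfig,
                                     bout_transition_matrix, draw_covariates,
                                     nurse_config, read_truth_json,
                                     reversible_transition_matrix,
                                     simulate_capture_event,
                                     simulate_physiology, simulate_study)


def _metrics(p_low=0.5, duration=60.0):
    p_med = (1.0 - p_low) / 2.0
    return ExerciseMetrics("e", p_low, p_med, 1.0 - p_low - p_med,
                           duration, 60.0)


# --- bout / trace generator ------------------------------------------------

def test_absorbing_low_state_gives_pure_low_event():
    # every state maps to low, so low is absorbing and the stationary law
    # puts all mass there; any seed must yield a pure resting event
    cfg = BoutModelConfig(transition_matrix=np.array(
        [[1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        front_loaded=False)
    for seed in (0, 1, 99):
        _, truth = simulate_capture_event(cfg, seed, duration_min=5.0)
        assert truth.p_low == 1.0


def test_seeded_determinism():
    cfg = BoutModelConfig()
    a, ta = simulate_capture_event(cfg, 123, duration_min=8.0)
    b, tb = simulate_capture_event(cfg, 123, duration_min=8.0)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(ta.levels, tb.levels)


def test_quantization_and_clipping(rng):
    cfg = BoutModelConfig()
    tr, _ = simulate_capture_event(cfg, rng, duration_min=15.0)
    for chan in (tr.x, tr.y, tr.z):
        steps = chan / cfg.quantization_g
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
        assert np.all(np.abs(chan) <= cfg.clip_g + 1e-12)


def test_true_proportions_sum_exactly_to_one(rng):
    for _ in range(5):
        _, truth = simulate_capture_event(BoutModelConfig(), rng,
                                          duration_min=6.0)
        assert truth.p_low + truth.p_med + truth.p_high == 1.0
        assert len(truth.levels) == int(round(truth.duration_min * 60))


def test_occupancy_converges_to_stationary_distribution():
    """Empirical occupancy over 10⁴ s matches the eigen-stationary law."""
    P = reversible_transition_matrix((0.5, 0.3, 0.2), switch_rate=0.1)
    cfg = BoutModelConfig(transition_matrix=P, front_loaded=False)
    _, truth = simulate_capture_event(cfg, 7, duration_min=10000 / 60.0)
    # independent oracle: left eigenvector of P for eigenvalue 1
    w, v = np.linalg.eig(P.T)
    pi = np.abs(np.real(v[:, np.argmin(np.abs(w - 1.0))]))
    pi /= pi.sum()
    occ = np.array([np.mean(truth.levels == l) for l in ("low", "med",
                                                         "high")])
    np.testing.assert_allclose(occ, pi, atol=0.03)


def test_front_loading_concentrates_struggle_early():
    cfg = BoutModelConfig()  # front-loading on by default
    starts = []
    for seed in range(30):
        _, truth = simulate_capture_event(cfg, seed, duration_min=60.0)
        n = len(truth.levels)
        first_half = np.mean(truth.levels[:n // 2] == "high")
        second_half = np.mean(truth.levels[n // 2:] == "high")
        starts.append(first_half - second_half)
    assert np.mean(starts) > 0.05


def test_vs_of_trace_matches_target_regime(rng):
    # quantization error on the vectorial sum is below one component step
    cfg = BoutModelConfig()
    tr, truth = simulate_capture_event(cfg, rng, duration_min=10.0)
    vs = np.sqrt(tr.x ** 2 + tr.y ** 2 + tr.z ** 2)
    low = vs[truth.levels == "low"]
    if low.size:
        assert np.all(np.abs(low - 1.0) < 0.1)


@pytest.mark.parametrize("bad", [
    dict(transition_matrix=np.full((3, 3), 0.5)),
    dict(amplitude_dist={"low": (0.3, 0.01), "med": (0.2, 0.01),
                         "high": (0.5, 0.01)}),
    dict(cycle_dist={"low": (-1.0, 1.0), "med": (3.5, 0.8),
                     "high": (3.0, 0.5)}),
    dict(quantization_g=0.0),
    dict(duration_min_range=(10.0, 5.0)),
])
def test_invalid_bout_config_rejected(bad):
    with pytest.raises(ValueError):
        BoutModelConfig(**bad)


def test_bout_transition_matrix_sojourns():
    P = bout_transition_matrix((600.0, 300.0, 120.0))
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(np.diag(P), [1 - 1 / 600, 1 - 1 / 300,
                                            1 - 1 / 120])


# --- physiology generator --------------------------------------------------

def test_zero_noise_intercept_only_reproduces_mean():
    cfg = PhysioResponseConfig(endpoints={
        "ph37": EndpointModel(target_mean=7.41, residual_sd=0.0)})
    panel = simulate_physiology(_metrics(), (27.0, 200.0), cfg, 0)
    assert panel.ph37 == pytest.approx(7.41, abs=1e-12)


def test_zero_noise_linear_predictor_exact():
    from capturestress.models import logratio_transform
    m = EndpointModel(target_mean=10.0, beta_plow=2.0, beta_duration=0.1,
                      beta_sst=0.5, beta_tl=-0.02, residual_sd=0.0)
    cfg = PhysioResponseConfig(endpoints={"glucose_mmol_l": m})
    metrics = _metrics(p_low=0.75, duration=30.0)
    panel = simulate_physiology(metrics, (25.0, 180.0), cfg, 0)
    expected = (cfg.intercept("glucose_mmol_l")
                + 2.0 * logratio_transform(0.75) + 0.1 * 30.0
                + 0.5 * 25.0 - 0.02 * 180.0)
    assert panel.glucose_mmol_l == pytest.approx(expected, abs=1e-12)


def test_noise_model_sd_recovered(rng):
    cfg = PhysioResponseConfig(endpoints={
        "ph37": EndpointModel(target_mean=7.41, residual_sd=0.11)})
    draws = [simulate_physiology(_metrics(), (27.0, 200.0), cfg, rng).ph37
             for _ in range(1000)]
    assert np.std(draws) == pytest.approx(0.11, rel=0.15)


def test_missing_covariate_error_names_field():
    cfg = nurse_config()
    with pytest.raises(ValueError, match="sst_c"):
        simulate_physiology(_metrics(), (None, 200.0), cfg, 0)
    with pytest.raises(ValueError, match="tl_cm"):
        simulate_physiology(_metrics(), (27.0, float("nan")), cfg, 0)


def test_negative_residual_sd_rejected():
    with pytest.raises(ValueError):
        EndpointModel(target_mean=1.0, residual_sd=-0.1)


def test_endpoint_means_calibrated_to_descriptive_statistics(rng):
    """Sample means of an n=36 nurse-shark study sit within 3 SE of the
    configured endpoint means (family-wise Monte-Carlo check)."""
    cfg = nurse_config()
    covs = draw_covariates(36, cfg.covariates, rng)
    from capturestress.synthetic import simulate_endpoint_table
    table = simulate_endpoint_table(covs, cfg, rng)
    # total sd per endpoint ≈ the descriptive sd the defaults target
    expected_sd = {"calcium_mmol_l": 0.98, "chloride_mmol_l": 16.43,
                   "sodium_mmol_l": 35.13, "potassium_mmol_l": 1.42,
                   "glucose_mmol_l": 5.41, "ph37": 0.11,
                   "lactate_mmol_l": 0.82, "haematocrit_pct": 4.41}
    for name, m in cfg.endpoints.items():
        z = (table[name].mean() - m.target_mean) / (expected_sd[name] /
                                                    np.sqrt(36))
        assert abs(z) <= 3.0, f"{name}: z={z:.2f}"


# --- whole-study simulation ------------------------------------------------

def test_simulate_study_outputs_and_roundtrip(small_study):
    out, paths, truths = small_study
    assert len(paths.accel_paths) == 8
    records = read_deployment_table(paths.deployment_path)
    assert len(records) == 8
    # traces round-trip through the readers with identical values
    tr = read_accel_csv(paths.accel_paths[0])
    assert len(tr) == int(round(truths[0].duration_min * 60))
    # truth sidecar round-trips exactly
    back = read_truth_json(paths.truth_path)
    np.testing.assert_array_equal(back[0].levels, truths[0].levels)
    assert back[0].p_low == truths[0].p_low


def test_simulate_study_rejects_empty():
    with pytest.raises(ValueError):
        simulate_study(0, BoutModelConfig(), nurse_config(), 0, "/tmp/x")
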