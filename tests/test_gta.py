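"""Windowing, the graph-transformer forecaster and its reductions."""

import numpy as np
import pytest

from mortgraph import (GTA, AdaptiveParams, GTAConfig, SynthConfig,
                       WindowConfig, adaptive_matrix, build_windows,
                       compose_adjacency, dtw_matrix, first_pc,
                       gcn_forward, geo_distance_matrix, kmeans_shapes,
                       simulate_panel, split_train_test, standardize_ages,
                       train_baseline)

TINY = GTAConfig(gcn_sizes=(16,), d_model=16, heads=2, encoder_layers=1,
                 ff_width=32, epochs=30, batch_size=8, seed=0)
TINY_WINDOW = WindowConfig(t=6, s=1, horizon=4)


@pytest.fixture(scope="module")
def tiny_setup():
    """Noiseless 4-country panel plus its adjacency bundle."""
    cfg = SynthConfig(m=4, n_clusters=2, n_years=30, n_ages=10,
                      cluster_drifts=(-1.5, 1.0),
                      geo_centers=((60, 20), (47, 6)),
                      noise_sd=0.0, walk_sd=0.1)
    panel, truth = simulate_panel(cfg, 13)
    train, test = split_train_test(panel, int(panel.years[23]))
    series = [first_pc(standardize_ages(train.log_rates[i])).pc1
              for i in range(panel.m)]
    cm = kmeans_shapes(series, 2, n_init=2, seed=0)
    params = AdaptiveParams.init(cm.k)
    bundle = compose_adjacency(
        dtw_matrix(series), geo_distance_matrix(truth.registry, train.countries),
        adaptive_matrix(cm.labels, params), countries=train.countries,
        params=params, labels=cm.labels)
    return train, test, bundle


def identity_bundle(m, bundle):
    """Bundle with zero similarity everywhere: P is exactly the identity."""
    from mortgraph import AdjacencyBundle
    zeros = np.zeros((m, m))
    return AdjacencyBundle(
        countries=bundle.countries, dtw_distance=zeros, geo_distance=zeros,
        a_ada=np.ones((m, m)), composite_distance=zeros,
        similarity=zeros, propagation=np.eye(m), tau=1.0)


class TestBuildWindows:
    def test_window_count_matches_formula(self):
        arr = np.arange(3 * 51 * 4, dtype=float).reshape(3, 51, 4)
        X, y = build_windows(arr, WindowConfig(t=10, s=1))
        assert X.shape == (41, 10, 3, 4)
        assert y.shape == (41, 3, 4)

    def test_step_equal_to_train_length_gives_one_sample(self):
        arr = np.zeros((2, 51, 3))
        X, y = build_windows(arr, WindowConfig(t=10, s=51))
        assert len(X) == 1

    def test_windows_are_exact_slices(self, rng):
        arr = rng.normal(size=(2, 20, 3))
        X, y = build_windows(arr, WindowConfig(t=5, s=2))
        for n, start in enumerate(range(0, 15, 2)):
            assert np.array_equal(X[n], arr[:, start:start + 5].transpose(1, 0, 2))
            assert np.array_equal(y[n], arr[:, start + 5])

    def test_window_longer_than_train_rejected(self):
        with pytest.raises(ValueError):
            build_windows(np.zeros((2, 8, 3)), WindowConfig(t=8))


class TestGCNForward:
    def test_identity_propagation_is_plain_linear_map(self, rng):
        X = rng.normal(size=(4, 6))
        W = rng.normal(size=(6, 3))
        out = gcn_forward(np.eye(4), X, W, np.zeros(3), activation="identity")
        assert np.array_equal(out, X @ W)

    def test_zero_weights_give_activated_bias(self, rng):
        X = rng.normal(size=(4, 6))
        b = np.array([-1.0, 2.0])
        out = gcn_forward(np.eye(4), X, np.zeros((6, 2)), b)
        assert np.allclose(out, np.maximum(b, 0.0))

    def test_two_node_hand_example(self):
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        X = np.array([[1.0, 0.0], [3.0, 2.0]])
        W = np.array([[1.0], [-1.0]])
        out = gcn_forward(P, X, W, np.zeros(1), activation="identity")
        # P X = [[2,1],[2,1]]; (P X) W = [[1],[1]]
        assert np.allclose(out, [[1.0], [1.0]])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gcn_forward(np.eye(3), rng.normal(size=(4, 6)),
                        rng.normal(size=(6, 2)), np.zeros(2))


class TestTraining:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_drops_tenfold_on_noiseless_panel(self, tiny_setup, seed):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 60, "seed": seed})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        assert res.loss_history[-1] < res.loss_history[0] / 10

    def test_fixed_seed_reproducible(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 5})
        r1 = GTA(train, bundle, TINY_WINDOW, cfg, kind="gta").fit()
        r2 = GTA(train, bundle, TINY_WINDOW, cfg, kind="gta").fit()
        assert r1.loss_history == r2.loss_history
        assert np.array_equal(r1.forecast(3).log_rates, r2.forecast(3).log_rates)

    def test_zero_epochs_returns_initialised_model(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 0})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        assert res.loss_history == []
        assert np.all(np.isfinite(res.forecast(2).log_rates))

    def test_adaptive_parameters_receive_gradient(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 5})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gta").fit()
        alpha, beta = res.adaptive_values()
        init_alpha = bundle.params.alpha()
        assert not np.allclose(alpha, init_alpha, atol=1e-12)
        assert beta != pytest.approx(bundle.params.beta(), abs=1e-12)

    def test_unknown_kind_rejected(self, tiny_setup):
        train, _, bundle = tiny_setup
        with pytest.raises(ValueError, match="kind"):
            GTA(train, bundle, kind="gcn")

    def test_gta_without_bundle_rejected(self, tiny_setup):
        train, _, _ = tiny_setup
        with pytest.raises(ValueError, match="bundle"):
            GTA(train, None, kind="gta")

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            GTAConfig(d_model=10, heads=3).validate()
        with pytest.raises(ValueError, match="dropout"):
            GTAConfig(dropout=1.0).validate()

    def test_dropout_training_runs_and_inference_is_deterministic(
            self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 4, "dropout": 0.2})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        assert np.all(np.isfinite(res.loss_history))
        # dropout is training-only: repeated forecasts agree exactly
        assert np.array_equal(res.forecast(3).log_rates,
                              res.forecast(3).log_rates)


class TestReductionIdentity:
    def test_identity_propagation_matches_tf_bit_for_bit(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 5})
        frozen = GTA(train, identity_bundle(train.m, bundle), TINY_WINDOW,
                     cfg, kind="gt").fit()
        tf = train_baseline("tf", train, TINY_WINDOW, cfg)
        assert frozen.loss_history == tf.loss_history
        assert np.array_equal(frozen.forecast(4).log_rates,
                              tf.forecast(4).log_rates)


class TestForecast:
    def test_horizon_one_equals_direct_prediction(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 3})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        fc = res.forecast(1)
        direct = res.predict_next(train.log_rates)
        assert np.array_equal(fc.log_rates[:, 0, :], direct)

    def test_longer_horizon_extends_not_rewrites(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 3})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        short = res.forecast(2).log_rates
        long = res.forecast(5).log_rates
        assert np.array_equal(long[:, :2, :], short)

    def test_forecasts_finite_across_seeds(self, tiny_setup):
        train, _, bundle = tiny_setup
        for seed in range(3):
            cfg = GTAConfig(**{**TINY.__dict__, "epochs": 5, "seed": seed})
            res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
            assert np.all(np.isfinite(res.forecast(6).log_rates))

    def test_bad_horizon_rejected(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 0})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        with pytest.raises(ValueError):
            res.forecast(0)

    def test_forecast_years_continue_train_years(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 0})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit()
        fc = res.forecast(3)
        assert fc.years[0] == train.years[-1] + 1
        assert len(fc.years) == 3

    def test_summary_mentions_dimensions(self, tiny_setup):
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 2})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gta").fit()
        text = res.summary()
        assert "countries (m)" in text and "adaptive beta" in text

    def test_checkpoint_round_trip(self, tiny_setup, tmp_path):
        from mortgraph import GTAResults
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 3})
        res = GTA(train, bundle, TINY_WINDOW, cfg, kind="gta").fit()
        res.save(tmp_path / "ckpt")
        back = GTAResults.load(tmp_path / "ckpt", train, bundle)
        assert back.loss_history == res.loss_history
        assert np.array_equal(back.forecast(3).log_rates,
                              res.forecast(3).log_rates)
        a1, b1 = res.adaptive_values()
        a2, b2 = back.adaptive_values()
        assert np.array_equal(a1, a2) and b1 == b2

    def test_result_csv_round_trip(self, tiny_setup, tmp_path):
        import pandas as pd
        train, _, bundle = tiny_setup
        cfg = GTAConfig(**{**TINY.__dict__, "epochs": 0})
        fc = GTA(train, bundle, TINY_WINDOW, cfg, kind="gt").fit().forecast(2)
        fc.to_csv(tmp_path / "fc.csv")
        df = pd.read_csv(tmp_path / "fc.csv")
        assert len(df) == train.m * 2 * train.d
        assert set(df.columns) == {"country", "year", "age", "log_rate"}
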