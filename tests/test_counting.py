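"""Counter networks, augmentation, metrics, and the experiment drivers."""

import numpy as np
import pytest

from rosettasim.counting import (CounterConfig, ExperimentConfig, augment_image,
                                 best_constant_agreement, build_counter, compute_metrics,
                                 evaluate, round_half_away, run_experiment, train)
from rosettasim.counting.experiments import synthetic_arrays
from rosettasim.counting.nn import Dense


class _ScriptedRng:
    """Deterministic stand-in for a Generator, fed from fixed sequences."""

    def __init__(self, randoms=(), integers=(), uniforms=()):
        self._r = list(randoms)
        self._i = list(integers)
        self._u = list(uniforms)

    def random(self):
        return self._r.pop(0)

    def integers(self, lo, hi):
        return self._i.pop(0)

    def uniform(self, lo, hi):
        return self._u.pop(0)


class TestBuildCounter:
    def test_small_outputs_scalar_per_image(self):
        cfg = CounterConfig(architecture="small", input_size=32, filters=(4, 8, 8))
        model = build_counter(cfg)
        x = np.zeros((3, 32, 32, 3), dtype=np.float32)
        out = model.predict(x)
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_large_fc_parameter_count(self):
        # after four 'same' convolutions each followed by 3x3/2 pooling,
        # a 32px input shrinks 32 -> 15 -> 7 -> 3 -> 1, so the flattened
        # feature size is 1*1*128 and the fc layer has 128*1024+1024 params
        cfg = CounterConfig(architecture="large", input_size=32)
        model = build_counter(cfg)
        dense_layers = [l for l in model.net.layers if isinstance(l, Dense)]
        fc = dense_layers[0]
        assert fc.w.size + fc.b.size == 128 * 1024 + 1024
        assert dense_layers[1].w.shape == (1024, 1)

    def test_unknown_architecture(self):
        with pytest.raises(ValueError):
            CounterConfig(architecture="huge")

    def test_weights_seeded(self):
        cfg = CounterConfig(input_size=16, filters=(3, 4, 4), seed=5)
        a, b = build_counter(cfg), build_counter(cfg)
        for (pa, _, _), (pb, _, _) in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa, pb)


class TestAugment:
    def test_disabled_is_identity(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = augment_image(img, rng, flips=False, crop_fraction=0.0,
                            brightness=False, contrast=False)
        np.testing.assert_array_equal(out, img)

    def test_forced_double_horizontal_flip_is_involution(self, rng):
        img = rng.random((12, 12, 3)).astype(np.float32)
        # scripted draws: skip vflip (0.9), take hflip (0.1), twice
        once = augment_image(img, _ScriptedRng(randoms=[0.9, 0.1]), crop_fraction=0.0,
                             brightness=False, contrast=False)
        twice = augment_image(once, _ScriptedRng(randoms=[0.9, 0.1]), crop_fraction=0.0,
                              brightness=False, contrast=False)
        np.testing.assert_array_equal(twice, img)
        assert not np.array_equal(once, img)

    def test_crop_window_always_inside_image(self, rng):
        # the crop offsets are drawn from integers(0, h - ch + 1); enumerate
        # every reachable offset and check the window bounds directly
        h = 64
        ch = int(round(h * 0.9))
        for top in range(0, h - ch + 1):
            assert 0 <= top and top + ch <= h
        # and exercise the full path a few hundred times
        img = rng.random((32, 32, 3)).astype(np.float32)
        for _ in range(300):
            out = augment_image(img, rng)
            assert out.shape == img.shape
            assert np.all((out >= 0) & (out <= 1))

    def test_brightness_contrast_bounded(self, rng):
        img = np.full((8, 8, 3), 0.5, dtype=np.float32)
        for _ in range(50):
            out = augment_image(img, rng, flips=False, crop_fraction=0.0)
            assert np.all((out >= 0.3) & (out <= 0.7))


class TestMetrics:
    def test_perfect_predictor(self):
        t = np.array([3, 7, 12, 20])
        m = compute_metrics(t, t.astype(float))
        assert (m.abs_count_diff_mean, m.count_diff_mean, m.mse) == (0, 0, 0)
        assert m.r_squared == 1.0
        assert m.agreement_pct == 100.0

    def test_hand_computed_example(self):
        # truths (3,4,5), rounded preds (4,4,4): |d| = (1,0,1), d sums to 0,
        # SS_res = 2, SS_tot = 2 -> R^2 = 0
        m = compute_metrics(np.array([3, 4, 5]), np.array([4.2, 3.6, 4.4]))
        assert m.abs_count_diff_mean == pytest.approx(2 / 3)
        assert m.count_diff_mean == pytest.approx(0.0)
        assert m.mse == pytest.approx(2 / 3)
        assert m.r_squared == pytest.approx(0.0)
        assert m.agreement_pct == pytest.approx(100 / 3)

    def test_constant_predictor_worse_than_mean_gives_negative_r2(self):
        # truths (1,2,9): mean 4, SS_tot = 38; preds (9,9,9): SS_res = 113
        m = compute_metrics(np.array([1, 2, 9]), np.array([9.0, 9.0, 9.0]))
        assert m.r_squared == pytest.approx(1 - 113 / 38)
        assert m.r_squared < 0

    def test_round_half_away_from_zero(self):
        np.testing.assert_array_equal(round_half_away(np.array([2.5, -2.5, 1.4, -1.6])),
                                      [3, -3, 1, -2])

    def test_identities_on_fuzzed_vectors(self, rng):
        for _ in range(10_000):
            n = int(rng.integers(2, 20))
            t = rng.integers(1, 25, size=n).astype(float)
            p = t + rng.normal(0, 3, size=n)
            m = compute_metrics(t, p)
            assert m.abs_count_diff_mean >= abs(m.count_diff_mean) - 1e-12
            assert m.mse >= m.count_diff_mean ** 2 - 1e-12
            assert 0.0 <= m.agreement_pct <= 100.0
            if np.ptp(t) > 0:
                assert m.r_squared <= 1.0 + 1e-12

    def test_order_invariance(self, rng):
        t = rng.integers(5, 21, size=40).astype(float)
        p = t + rng.normal(0, 1, size=40)
        m1 = compute_metrics(t, p)
        perm = rng.permutation(40)
        m2 = compute_metrics(t[perm], p[perm])
        assert m1 == m2

    def test_empty_and_mismatched_inputs(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            compute_metrics(np.array([1.0, 2.0]), np.array([1.0]))

    def test_best_constant_agreement(self):
        assert best_constant_agreement(np.array([5, 5, 5, 9])) == 75.0


_FAST = dict(input_size=16, filters=(3, 4, 4), epochs=2, batch_size=8,
             patience=0, augment=False)


class TestTraining:
    def _toy_data(self, rng, n=10, size=16):
        x = rng.random((n, size, size, 3)).astype(np.float32)
        y = rng.integers(5, 21, size=n).astype(np.float32)
        return x, y

    def test_smoke_one_epoch(self, rng):
        cfg = CounterConfig(**{**_FAST, "epochs": 1})
        model = build_counter(cfg)
        h = train(model, self._toy_data(rng), cfg)
        assert len(h["train_loss"]) == 1
        assert np.isfinite(h["train_loss"][0])

    def test_loss_decreases_on_rendered_subset(self):
        cfg = CounterConfig(input_size=32, filters=(6, 12, 12), epochs=30,
                            batch_size=16, patience=0, augment=False, seed=0)
        x, y = synthetic_arrays("S2", ExperimentConfig(counter=cfg, n_images=50, master_seed=8))
        model = build_counter(cfg)
        h = train(model, (x, y), cfg)
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_identical_runs_identical_histories(self, rng):
        data = self._toy_data(rng)
        cfg = CounterConfig(**_FAST, seed=3)
        h1 = train(build_counter(cfg), data, cfg)
        h2 = train(build_counter(cfg), data, cfg)
        assert h1 == h2

    def test_empty_training_data_errors(self):
        cfg = CounterConfig(**_FAST)
        with pytest.raises(ValueError):
            train(build_counter(cfg), (np.zeros((0, 16, 16, 3)), np.zeros(0)), cfg)

    def test_evaluate_order_invariance(self, rng):
        cfg = CounterConfig(**_FAST)
        model = build_counter(cfg)
        x, y = self._toy_data(rng, n=12)
        m1 = evaluate(model, (x, y))
        perm = rng.permutation(12)
        m2 = evaluate(model, (x[perm], y[perm]))
        for f in ("abs_count_diff_mean", "count_diff_mean", "mse", "r_squared", "agreement_pct"):
            assert getattr(m1, f) == pytest.approx(getattr(m2, f), abs=1e-9)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ExperimentConfig(
        counter=CounterConfig(architecture="small", input_size=16, filters=(3, 4, 4),
                              epochs=2, batch_size=8, patience=0, augment=False, seed=0),
        n_images=16, master_seed=4)


class TestExperiments:

    def test_interoperability_rows_complete(self, tiny_cfg, tmp_path):
        from dataclasses import replace
        report = run_experiment("interoperability", replace(tiny_cfg, out_dir=str(tmp_path)))
        with_metrics = [r for r in report.rows if r.get("metrics")]
        assert len(with_metrics) == 3  # S2->S1, S1->S2, S12 baseline
        for r in with_metrics:
            assert set(r["metrics"].row()) == {"AbsCountDiff", "CountDiff", "MSE",
                                               "R2", "Agreement (%)"}
        assert any(r.get("note") == "external data required" for r in report.rows)
        assert (tmp_path / "interoperability_metrics.csv").exists()
        assert report.histograms

    def test_generalization_standin_rows(self, tiny_cfg):
        report = run_experiment("generalization", tiny_cfg)
        tested = [r["test"] for r in report.rows if r.get("metrics")]
        assert any("S1" in t for t in tested) and any("S2" in t for t in tested)

    def test_unknown_experiment(self, tiny_cfg):
        with pytest.raises(ValueError):
            run_experiment("teleportation", tiny_cfg)
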