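"""Network assembly, Adam, training loop, metrics, complexity accounting."""

import warnings

import numpy as np
import pytest
import yaml

from mscmamba.model import (
    Adam,
    ClassifierHead,
    ModelConfig,
    MSCMambaModel,
    OptimizerState,
    VARIANTS,
    adam_step,
    build_model,
    classify,
    confusion_report,
    evaluate,
    forward_flops,
    train,
)


class DS:
    def __init__(self, X, y, sites):
        self.X, self.y, self.sites = X, y, sites


def tiny_dataset(rng, n=16, T=24, C=6, n_sites=2, mean_shift=1.0):
    X = rng.normal(size=(n, T, C))
    y = np.tile([0, 1], n // 2)
    X[y == 1] += mean_shift
    sites = np.array([f"s{i % n_sites}" for i in range(n)])
    return DS(X, y, sites)


TINY = dict(d_model=8, state_dim=4, kernel_widths=(3, 5), batch_size=8,
            epochs=3, patience=50)


class TestModelConfig:
    def test_yaml_round_trip_identity(self, tmp_path):
        cfg = ModelConfig(variant="mamba_ss", d_model=24, alpha=0.05,
                          kernel_widths=(3, 9), seed=7)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert ModelConfig.from_yaml(p) == cfg

    def test_from_yaml_string(self):
        cfg = ModelConfig()
        assert ModelConfig.from_yaml(cfg.to_yaml()) == cfg

    def test_invalid_variant(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="transformer")


class TestBuildModel:
    def test_parameter_count_deterministic(self):
        cfg = ModelConfig(seed=3, **TINY)
        assert build_model(cfg, 6).parameter_count() == \
            build_model(cfg, 6).parameter_count()

    def test_variant_parameter_ordering(self):
        counts = {v: build_model(ModelConfig(variant=v, **TINY), 6).parameter_count()
                  for v in VARIANTS}
        assert counts["mamba_rs"] < counts["msc_mamba"]
        assert counts["mamba_ss"] < counts["msc_mamba"]
        assert counts["mamba_original"] < counts["msc_mamba"]
        assert len(set(counts.values())) == 4  # all distinct

    def test_forward_probabilities_normalized(self, rng):
        model = build_model(ModelConfig(**TINY), 116)
        probs, feats = model.forward(rng.normal(size=(100, 116)))
        assert probs.data.shape == (1, 2)
        assert abs(probs.data.sum() - 1.0) < 1e-6
        assert feats.data.shape == (1, 8)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_forward(self, rng, variant):
        model = build_model(ModelConfig(variant=variant, **TINY), 5)
        probs, _ = model.forward(rng.normal(size=(3, 20, 5)))
        np.testing.assert_allclose(probs.data.sum(-1), 1.0, atol=1e-9)

    def test_time_invariant_variant_forward(self, rng):
        model = build_model(ModelConfig(time_invariant=True, **TINY), 5)
        probs, _ = model.forward(rng.normal(size=(2, 15, 5)))
        np.testing.assert_allclose(probs.data.sum(-1), 1.0, atol=1e-9)


class TestClassify:
    def test_equal_logits(self):
        head = ClassifierHead(W=np.zeros((2, 3)), b=np.zeros(2))
        p = classify(np.zeros((1, 3)), head)
        np.testing.assert_allclose(p, [[0.5, 0.5]])

    def test_log3_logits(self):
        head = ClassifierHead(W=np.array([[1.0], [0.0]]), b=np.zeros(2))
        p = classify(np.array([[np.log(3.0)]]), head)
        np.testing.assert_allclose(p, [[0.75, 0.25]], atol=1e-12)

    def test_shift_invariance(self, rng):
        W = rng.normal(size=(2, 4))
        x = rng.normal(size=(3, 4))
        p1 = classify(x, ClassifierHead(W=W, b=np.zeros(2)))
        p2 = classify(x, ClassifierHead(W=W, b=np.full(2, 5.0)))
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestAdam:
    def test_zero_gradient_no_move(self):
        st = OptimizerState.fresh([np.array([1.0, -2.0])], eta=0.01)
        st2 = adam_step(st, [np.zeros(2)])
        np.testing.assert_array_equal(st2.theta[0], [1.0, -2.0])
        assert st2.t == 1

    def test_first_step_magnitude(self):
        st = OptimizerState.fresh([np.array([0.0])], eta=0.001)
        st2 = adam_step(st, [np.array([1.0])])
        assert st2.theta[0][0] == pytest.approx(-0.001, rel=1e-6)

    def test_trace_matches_independent_scalar_adam(self):
        """Step-by-step agreement with a self-contained scalar Adam."""
        eta, b1, b2, eps, wd = 0.01, 0.9, 0.999, 1e-8, 5e-4
        st = OptimizerState.fresh([np.array([0.5])], eta=eta, weight_decay=wd)
        theta, m, v = 0.5, 0.0, 0.0
        g = 0.3
        for t in range(1, 3):
            st = adam_step(st, [np.array([g])])
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mh, vh = m / (1 - b1**t), v / (1 - b2**t)
            theta = theta - eta * mh / (np.sqrt(vh) + eps)
            theta = theta - eta * wd * theta
            assert st.theta[0][0] == pytest.approx(theta, abs=1e-12)

    def test_nonfinite_gradient_aborts(self):
        st = OptimizerState.fresh([np.zeros(2)])
        with pytest.raises(FloatingPointError):
            adam_step(st, [np.array([np.nan, 0.0])])


class TestConfusionReport:
    def test_worked_example(self):
        y = [1] * 3 + [0] * 1 + [1] * 2 + [0] * 4
        p = [1] * 3 + [1] * 1 + [0] * 2 + [0] * 4
        rep = confusion_report(y, p)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.n == 10

    def test_all_correct(self, rng):
        y = rng.integers(0, 2, 20)
        rep = confusion_report(y, y)
        assert rep.accuracy == rep.precision == rep.recall == 1.0

    def test_against_sklearn_oracle(self, rng):
        from sklearn.metrics import accuracy_score, precision_score, recall_score
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            if p.sum() == 0 or y.sum() == 0:
                continue
            rep = confusion_report(y, p)
            assert rep.accuracy == pytest.approx(accuracy_score(y, p))
            assert rep.precision == pytest.approx(precision_score(y, p))
            assert rep.recall == pytest.approx(recall_score(y, p))


class TestTraining:
    def test_deterministic_split_and_history(self, rng):
        ds = tiny_dataset(rng)
        cfg = ModelConfig(seed=11, **TINY)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, h1 = train(ds, cfg)
            m2, h2 = train(ds, cfg)
        np.testing.assert_array_equal(h1["train_idx"], h2["train_idx"])
        for e1, e2 in zip(h1["epochs"], h2["epochs"]):
            assert e1 == e2

    def test_zero_weights_skip_alignment_terms(self, rng):
        ds = tiny_dataset(rng)
        cfg = ModelConfig(seed=1, alpha=0.0, beta=0.0, **TINY)
        _, h = train(ds, cfg)
        assert all(e["align"] == 0.0 and e["adapt"] == 0.0 for e in h["epochs"])

    def test_single_class_rejected(self, rng):
        ds = tiny_dataset(rng)
        ds.y = np.zeros(len(ds.y), dtype=int)
        with pytest.raises(ValueError):
            train(ds, ModelConfig(**TINY))

    def test_single_site_warns(self, rng):
        ds = tiny_dataset(rng, n_sites=1)
        with pytest.warns(UserWarning, match="single-site"):
            _, h = train(ds, ModelConfig(seed=0, **TINY))
        assert all(e["align"] == 0.0 for e in h["epochs"])

    def test_overfits_16_subjects(self, rng):
        """Capacity check: training CE drops below 0.05 on 16 subjects
        within 500 optimization steps."""
        ds = tiny_dataset(rng, n=16, T=24, C=6)
        cfg = ModelConfig(seed=0, d_model=8, state_dim=4, kernel_widths=(3, 5),
                          batch_size=16, epochs=500, patience=10_000,
                          alpha=0.0, beta=0.0, dropout=0.0, val_fraction=0.0)
        model, h = train(ds, cfg)
        ces = [e["ce"] for e in h["epochs"]]
        assert min(ces) < 0.05

    def test_evaluate_report(self, rng):
        ds = tiny_dataset(rng, mean_shift=3.0)
        cfg = ModelConfig(seed=2, alpha=0.0, beta=0.0, epochs=30, **{
            k: v for k, v in TINY.items() if k != "epochs"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, _ = train(ds, cfg)
        rep = evaluate(model, ds)
        assert rep.n == 16
        assert 0.0 <= rep.accuracy <= 1.0

    def test_evaluate_empty_rejected(self, rng):
        model = build_model(ModelConfig(**TINY), 6)
        with pytest.raises(ValueError):
            evaluate(model, DS(np.zeros((0, 10, 6)), np.zeros(0), np.zeros(0)))


class TestPersistence:
    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = build_model(ModelConfig(seed=4, **TINY), 6)
        X = rng.normal(size=(3, 20, 6))
        before = model.predict_proba(X)
        path = model.save(tmp_path / "model.zip")
        back = MSCMambaModel.load(path)
        np.testing.assert_array_equal(back.predict_proba(X), before)
        assert back.cfg == model.cfg


class TestComplexity:
    def test_flops_affine_in_T(self):
        cfg = ModelConfig()
        f = [forward_flops(cfg, T, 32) for T in (128, 256, 512, 1024)]
        # affine in T: second differences of a doubling sequence vanish
        ratios = [f[i + 1] / f[i] for i in range(3)]
        for r in ratios:
            assert abs(r - 2.0) < 0.05

    def test_flops_variant_ordering(self):
        assert forward_flops(ModelConfig(variant="mamba_original"), 256, 32) < \
            forward_flops(ModelConfig(variant="msc_mamba"), 256, 32)

    def test_runtime_scaling_subquadratic(self, rng):
        """Empirical log-log slope of forward time over T in {128,...,1024}
        stays below 1.3 (linear-time scan)."""
        import time
        model = build_model(ModelConfig(d_model=8, state_dim=4), 8)
        times = []
        Ts = [128, 256, 512, 1024]
        X = {T: rng.normal(size=(1, T, 8)) for T in Ts}
        model.forward(X[128])  # warm up
        for T in Ts:
            reps = 3
            t0 = time.perf_counter()
            for _ in range(reps):
                model.forward(X[T])
            times.append((time.perf_counter() - t0) / reps)
        slope = np.polyfit(np.log(Ts), np.log(times), 1)[0]
        assert slope < 1.3
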