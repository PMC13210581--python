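import itertools

import numpy as np
import pytest

from ensdm import ensemble_eval, synthgen
from ensdm.ensemble_eval import (
    EnsembleModel, EvalRecord, SuitabilityMap, build_ensemble,
    confusion_at_threshold, ensemble_predict, gcm_mean, max_tss, project_all,
    roc_auc, summarize_performance, to_scores,
)
from ensdm.grid_io import GridError, GridSpec, PredictorStack, RasterLayer


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def tss_scan_oracle(scores, labels):
    """Independent exhaustive threshold scan."""
    best_t, best = None, -2.0
    for t in range(1001):
        sens, spec = confusion_at_threshold(scores, labels, t)
        tss = sens + spec - 1
        if tss > best:
            best, best_t = tss, t
    return best_t, best


SCORES6 = [900, 800, 700, 400, 300, 200]
LABELS6 = [1, 1, 1, 0, 0, 0]


class TestConfusion:
    def test_perfect_separation(self):
        assert confusion_at_threshold(SCORES6, LABELS6, 500) == (1.0, 1.0)

    def test_all_zero_scores(self):
        assert confusion_at_threshold([0, 0, 0, 0], [1, 1, 0, 0], 0) == (0.0, 1.0)

    def test_hand_counts(self):
        assert confusion_at_threshold(SCORES6, LABELS6, 750) == (pytest.approx(2 / 3), 1.0)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([1, 2], [1, 1], 0)


class TestRocAuc:
    def test_perfect(self):
        assert roc_auc(SCORES6, LABELS6) == 1.0

    def test_null_large_n(self, rng):
        scores = rng.integers(0, 1001, 20000)
        labels = rng.integers(0, 2, 20000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_oracle_30_points(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.integers(0, 50, 30)  # narrow range forces ties
            labels = np.array([1] * 12 + [0] * 18)
            assert roc_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12)


class TestMaxTss:
    def test_six_point_smallest_argmax(self):
        t, tss, sens, spec = max_tss(SCORES6, LABELS6)
        assert t == 400 and tss == 1.0

    def test_degenerate_equal_scores(self):
        t, tss, sens, spec = max_tss([500] * 6, LABELS6)
        assert tss == 0.0

    def test_tss_identity_three_decimals(self):
        # sensitivity 0.97531 and specificity 0.93900 give TSS 0.914 (3 dp)
        rec = EvalRecord("x", "ens", 0.99, 0.97531 + 0.93900 - 1.0, 532, 0.97531, 0.93900)
        assert round(rec.tss, 3) == 0.914

    def test_identity_enforced(self):
        with pytest.raises(ValueError, match="tss"):
            EvalRecord("x", "m", 0.9, 0.5, 100, 0.9, 0.9)

    def test_oracle_random_vectors(self):
        for seed in range(8):
            r = np.random.default_rng(seed)
            scores = r.integers(0, 1001, 60)
            labels = np.array([1] * 20 + [0] * 40)
            t, tss, _, _ = max_tss(scores, labels)
            t_o, tss_o = tss_scan_oracle(scores, labels)
            assert t == t_o
            assert tss == pytest.approx(tss_o, abs=1e-12)


class TestSummarize:
    def _rec(self, learner, tss, auc=0.9):
        return EvalRecord("r", learner, auc, tss, 500, (tss + 1) / 2, (tss + 1) / 2)

    def test_identical_replicates_sd_zero(self):
        table = summarize_performance([self._rec("a", 0.8), self._rec("a", 0.8)])
        assert table["tss_sd"].iloc[0] == 0.0

    def test_hand_mean_sd(self):
        table = summarize_performance([self._rec("a", 0.8), self._rec("a", 0.9)])
        assert table["tss_mean"].iloc[0] == pytest.approx(0.85)
        assert table["tss_sd"].iloc[0] == pytest.approx(0.070710678, abs=1e-6)

    def test_counts_and_sort(self):
        recs = [self._rec("lo", 0.5)] * 15 + [self._rec("hi", 0.9)] * 15
        table = summarize_performance(recs)
        assert list(table["learner"]) == ["hi", "lo"]
        assert (table["n"] == 15).all()


class _FakeFitted:
    def __init__(self, p):
        self.p = p

    def predict(self, X):
        return np.full(len(X), self.p)


def fake_replicate(p, rid="r", tss=0.8):
    from ensdm.fitcore import ReplicateModel, SplitPlan

    split = SplitPlan(rid, 1, 1, np.arange(1), np.arange(1), 0)
    rep = ReplicateModel(
        learner_name="fake", replicate_id=rid, set_id=1, repeat_index=1,
        fitted=_FakeFitted(p), means=np.zeros(1), sds=np.ones(1),
        layer_names=["x"], split=split)
    rep.eval_record = EvalRecord(rid, "fake", 0.9, tss, 500, (tss + 1) / 2, (tss + 1) / 2)
    return rep


class TestBuildEnsemble:
    def test_symmetric_weights(self):
        model = build_ensemble([fake_replicate(0.5, "a", 0.8), fake_replicate(0.5, "b", 0.8)])
        np.testing.assert_allclose(model.weights, [0.5, 0.5])

    def test_gate_drops_low_tss(self):
        model = build_ensemble([fake_replicate(0.5, "a", 0.9), fake_replicate(0.5, "b", 0.6)])
        assert len(model.replicates) == 1
        assert model.weights[0] == 1.0

    def test_hand_normalized_weights(self):
        model = build_ensemble([
            fake_replicate(0.5, "a", 0.9), fake_replicate(0.5, "b", 0.75),
            fake_replicate(0.5, "c", 0.72)])
        np.testing.assert_allclose(model.weights, [0.3797, 0.3165, 0.3038], atol=1e-4)

    def test_no_pass_raises(self):
        with pytest.raises(ValueError, match="gate"):
            build_ensemble([fake_replicate(0.5, "a", 0.5)])

    def test_weights_sum_to_one(self, small_pipeline):
        model = small_pipeline["model"]
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        for rep in model.replicates:
            assert rep.eval_record.tss >= model.gate


def one_layer_stack(vals, scenario="current"):
    spec = GridSpec(vals.shape[0], vals.shape[1], 0.0, 10.0, 0.5)
    return PredictorStack([RasterLayer(spec, vals, np.zeros(vals.shape, bool), "x")], scenario)


class TestEnsemblePredict:
    def test_constant_half_gives_500(self):
        model = EnsembleModel([fake_replicate(0.5)], [1.0], 0.7, layer_names=["x"])
        smap = ensemble_predict(model, one_layer_stack(np.zeros((3, 3))))
        assert np.all(smap.layer.values == 500)

    def test_hand_weighted_mean(self):
        model = EnsembleModel([fake_replicate(0.2, "a"), fake_replicate(0.6, "b")],
                              [0.5, 0.5], 0.7, layer_names=["x"])
        smap = ensemble_predict(model, one_layer_stack(np.zeros((2, 2))))
        assert np.all(smap.layer.values == 400)

    def test_never_exceeds_1000(self):
        model = EnsembleModel([fake_replicate(1.0, "a"), fake_replicate(1.0, "b")],
                              [0.5, 0.5], 0.7, layer_names=["x"])
        smap = ensemble_predict(model, one_layer_stack(np.zeros((2, 2))))
        assert np.all(smap.layer.values == 1000)

    def test_bounded_by_replicate_range(self, rng):
        reps = [fake_replicate(p, f"r{i}") for i, p in enumerate(rng.uniform(0, 1, 5))]
        w = rng.uniform(0.1, 1, 5)
        model = EnsembleModel(reps, w / w.sum(), 0.7, layer_names=["x"])
        smap = ensemble_predict(model, one_layer_stack(np.zeros((4, 4))))
        preds = [r.fitted.p * 1000 for r in reps]
        assert smap.layer.values.max() <= np.ceil(max(preds))
        assert smap.layer.values.min() >= np.floor(min(preds))

    def test_missing_layer_rejected(self):
        model = EnsembleModel([fake_replicate(0.5)], [1.0], 0.7, layer_names=["zzz"])
        with pytest.raises(GridError, match="zzz"):
            ensemble_predict(model, one_layer_stack(np.zeros((2, 2))))


class TestRounding:
    def test_half_away_from_zero(self):
        assert to_scores(np.array([0.0005]))[0] == 1
        assert to_scores(np.array([0.4995]))[0] == 500
        assert to_scores(np.array([1.0]))[0] == 1000


class TestGcmMean:
    def test_identical_stacks(self):
        stack = one_layer_stack(np.ones((3, 3)))
        out = gcm_mean([stack, stack, stack])
        np.testing.assert_array_equal(out.get("x").values, stack.get("x").values)

    def test_two_values_average(self):
        out = gcm_mean([one_layer_stack(np.full((2, 2), 1.0)), one_layer_stack(np.full((2, 2), 3.0))])
        assert np.all(out.get("x").values == 2.0)

    def test_brute_force_oracle(self):
        stacks = [synthgen.default_stack(s, synthgen.default_spec(20, 20)) for s in (1, 2, 3)]
        out = gcm_mean(stacks)
        for name in out.names:
            manual = np.zeros((20, 20))
            for st in stacks:
                manual += st.get(name).values
            manual /= 3
            valid = ~out.union_mask()
            np.testing.assert_allclose(out.get(name).values[valid], manual[valid], atol=1e-12)

    def test_union_mask(self):
        a = one_layer_stack(np.ones((2, 2)))
        vals = np.ones((2, 2))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        b = PredictorStack([RasterLayer(a.spec, vals, mask, "x")])
        out = gcm_mean([a, b])
        assert out.union_mask()[0, 0]


class TestProjectAll:
    def test_identical_scenario_identical_map(self, small_pipeline):
        model = small_pipeline["model"]
        stack = small_pipeline["stack"]
        m1, m2 = project_all(model, [stack, stack])
        np.testing.assert_array_equal(m1.layer.values, m2.layer.values)

    def test_seven_in_seven_out(self):
        model = EnsembleModel([fake_replicate(0.5)], [1.0], 0.7, layer_names=["x"])
        stacks = [one_layer_stack(np.zeros((2, 2)), f"s{i}") for i in range(7)]
        maps = project_all(model, stacks)
        assert len(maps) == 7
        assert [m.scenario_id for m in maps] == [f"s{i}" for i in range(7)]

    def test_shift_moves_suitability_with_truth(self, small_pipeline):
        from scipy.stats import spearmanr

        model = small_pipeline["model"]
        stack = small_pipeline["stack"]
        truth_model = synthgen.default_true_model()
        delta = synthgen.ScenarioDelta("warm", shift={"bio7": 1.0})
        shifted = synthgen.apply_scenario(stack, delta)
        base_map = small_pipeline["smap"]
        new_map = ensemble_predict(model, shifted)
        d_truth = (synthgen.true_suitability(truth_model, shifted, reference=stack).values
                   - small_pipeline["truth"].values)
        d_suit = new_map.layer.values.astype(float) - base_map.layer.values.astype(float)
        valid = ~stack.union_mask()
        rho = spearmanr(d_suit[valid], d_truth[valid]).statistic
        assert rho > 0
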