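import numpy as np
import pytest

from coherentgen import (
    ConditionSet,
    EnsembleSpec,
    coherence_distance,
    coherent_sample,
    compute_weights,
    consensus_noise,
    gaussian_oracle_predictor,
    make_schedule,
    multi_condition_sample,
    sample,
    unconditional_probe,
)
from coherentgen.models import PredictorCheckpoint, PredictorConfig
from coherentgen.nn import NoisePredictorMLP


def _stub_checkpoint(fn, D=2, cond_name="c", cond_dim=2, target="t", schedule=None):
    """Checkpoint whose network computes ``fn(xt, t)``; used to force
    specific prediction geometries."""

    class StubNet:
        def __init__(self):
            self.D = D
            self.cond_dims = {cond_name: cond_dim}

        def forward(self, xt, t, conditions=None):
            return fn(np.atleast_2d(xt), t)

    return PredictorCheckpoint(
        network=StubNet(),
        config=PredictorConfig(max_epochs=1),
        target_modality=target,
        condition_modalities=[cond_name],
        best_val_mse=1.0,
        schedule=schedule or make_schedule(100, 1e-3, 0.05),
    )


class TestComputeWeights:
    def test_equal_mses_give_equal_weights(self):
        np.testing.assert_allclose(compute_weights([1.0, 1.0]), [0.5, 0.5])

    def test_single_member_normalizes_to_one(self):
        np.testing.assert_allclose(compute_weights([0.37]), [1.0])

    def test_inverse_proportionality(self):
        np.testing.assert_allclose(compute_weights([0.5, 1.0]), [2 / 3, 1 / 3])

    @pytest.mark.parametrize("bad", [[0.0, 1.0], [-1.0, 2.0], []])
    def test_invalid_mses_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_weights(bad)


class TestConsensusNoise:
    def test_single_member_is_bit_exact_identity(self):
        p = np.random.default_rng(0).standard_normal((3, 4))
        out = consensus_noise([p], [1.0])
        np.testing.assert_array_equal(out, p)

    def test_identical_predictions_any_weights(self):
        p = np.random.default_rng(1).standard_normal((2, 3))
        out = consensus_noise([p, p.copy(), p.copy()], [0.2, 0.5, 0.3])
        np.testing.assert_array_equal(out, p)

    def test_weighted_average(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        np.testing.assert_allclose(consensus_noise([a, b], [0.25, 0.75]), [[0.25, 0.75]])

    def test_convexity_bounds(self):
        rng = np.random.default_rng(2)
        preds = [rng.standard_normal((4, 3)) for _ in range(3)]
        w = compute_weights([0.3, 0.5, 0.9])
        out = consensus_noise(preds, w)
        lo = np.min(preds, axis=0)
        hi = np.max(preds, axis=0)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus_noise([np.zeros((2, 2)), np.zeros((3, 2))], [0.5, 0.5])


class TestCoherenceDistance:
    def test_identical_predictions_zero(self):
        p = np.random.default_rng(0).standard_normal((3, 4))
        assert coherence_distance([p, p], [0.5, 0.5]) == pytest.approx(0.0)

    def test_orthogonal_predictions_one(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        assert coherence_distance([a, b], [0.5, 0.5]) == pytest.approx(1.0)

    def test_antipodal_predictions_two(self):
        v = np.array([[0.3, -0.7]])
        assert coherence_distance([v, -v], [0.5, 0.5]) == pytest.approx(2.0)

    def test_single_member_zero(self):
        assert coherence_distance([np.ones((2, 2))], [1.0]) == 0.0

    def test_zero_norm_prediction_counts_as_agreement(self):
        v = np.array([[1.0, 1.0]])
        z = np.zeros((1, 2))
        assert coherence_distance([v, z], [0.5, 0.5]) == pytest.approx(0.0)

    def test_pair_weighting(self):
        # members 0,1 agree; member 2 antipodal to both. pair weights w_i w_j
        v = np.array([[1.0, 0.0]])
        w = np.array([0.4, 0.4, 0.2])
        pw = {(0, 1): 0.16, (0, 2): 0.08, (1, 2): 0.08}
        total = sum(pw.values())
        expected = (pw[(0, 1)] * 0 + pw[(0, 2)] * 2 + pw[(1, 2)] * 2) / total
        assert coherence_distance([v, v, -v], w) == pytest.approx(expected)


class TestEnsembleSpec:
    def test_weight_validation(self):
        ck = _stub_checkpoint(lambda xt, t: xt)
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleSpec([(ck, "c")], np.array([0.7]))

    def test_distinct_condition_modalities_required(self):
        ck1 = _stub_checkpoint(lambda xt, t: xt)
        ck2 = _stub_checkpoint(lambda xt, t: xt)
        with pytest.raises(ValueError, match="distinct"):
            EnsembleSpec([(ck1, "c"), (ck2, "c")], np.array([0.5, 0.5]))

    def test_from_checkpoints_uses_inverse_mse_weights(self):
        ck1 = _stub_checkpoint(lambda xt, t: xt, cond_name="a")
        ck2 = _stub_checkpoint(lambda xt, t: xt, cond_name="b")
        ck1.best_val_mse, ck2.best_val_mse = 0.5, 1.0
        ck1.condition_modalities = ["a"]
        ck2.condition_modalities = ["b"]
        ens = EnsembleSpec.from_checkpoints([ck1, ck2])
        np.testing.assert_allclose(ens.weights, [2 / 3, 1 / 3])

    def test_manifest_lists_members(self):
        ck = _stub_checkpoint(lambda xt, t: xt)
        ck.condition_modalities = ["c"]
        text = EnsembleSpec.from_checkpoints([ck]).manifest()
        assert "target\tt" in text and "val_mse" in text


class TestCoherentSampleIdentities:
    def test_single_member_bit_identical_to_plain_sampling(self, privacy_setup):
        single = privacy_setup["single"]
        sched = privacy_setup["schedule"]
        val = privacy_setup["val"]
        n = 40
        cond = ConditionSet({"cna": val["cna"][:n]})
        ens = EnsembleSpec([(single, "cna")], np.array([1.0]))
        res = coherent_sample(ens, cond, sched, n=n, seed=99)
        plain = sample(single.predictor(), sched, n, single.network.D, cond, seed=99)
        np.testing.assert_array_equal(res.samples, plain)
        assert res.accepted
        np.testing.assert_array_equal(res.diagnostics.per_step_distance, 0.0)

    def test_duplicated_members_reproduce_single_model(self):
        sched = make_schedule(50, 1e-3, 0.05)
        fn = lambda xt, t: 0.1 * xt
        cks = [_stub_checkpoint(fn, cond_name=c, schedule=sched) for c in ("a", "b", "d")]
        cond = ConditionSet({c: np.zeros((5, 2)) for c in ("a", "b", "d")})
        ens = EnsembleSpec([(ck, c) for ck, c in zip(cks, "abd")],
                           np.array([0.2, 0.5, 0.3]))
        res = coherent_sample(ens, cond, sched, n=5, seed=7)
        solo = EnsembleSpec([(cks[0], "a")], np.array([1.0]))
        res_solo = coherent_sample(solo, ConditionSet({"a": np.zeros((5, 2))}),
                                   sched, n=5, seed=7)
        np.testing.assert_array_equal(res.samples, res_solo.samples)
        np.testing.assert_allclose(res.diagnostics.per_step_distance, 0.0, atol=1e-12)
        assert res.accepted

    def test_antipodal_members_rejected_after_retries(self):
        sched = make_schedule(50, 1e-3, 0.05)
        ck1 = _stub_checkpoint(lambda xt, t: np.ones_like(xt), cond_name="a", schedule=sched)
        ck2 = _stub_checkpoint(lambda xt, t: -np.ones_like(xt), cond_name="b", schedule=sched)
        ens = EnsembleSpec([(ck1, "a"), (ck2, "b")], np.array([0.5, 0.5]))
        cond = ConditionSet({"a": np.zeros((3, 2)), "b": np.zeros((3, 2))})
        res = coherent_sample(ens, cond, sched, n=3, seed=0, max_retries=2)
        assert not res.accepted
        assert res.retries_used == 2
        assert res.diagnostics.incoherent_fraction == pytest.approx(1.0)
        np.testing.assert_allclose(res.diagnostics.per_step_distance, 2.0)

    def test_missing_condition_modality_rejected_before_sampling(self):
        sched = make_schedule(10, 1e-3, 0.05)
        ck = _stub_checkpoint(lambda xt, t: xt, cond_name="a", schedule=sched)
        ens = EnsembleSpec([(ck, "a")], np.array([1.0]))
        with pytest.raises(KeyError, match="a"):
            coherent_sample(ens, ConditionSet({"b": np.zeros((2, 2))}), sched, n=2, seed=0)


class TestRejectionBoundary:
    @pytest.mark.parametrize("bad_steps,accepted", [(5, True), (6, False)])
    def test_exactly_at_threshold_is_accepted(self, bad_steps, accepted):
        """Strict comparison: 5 incoherent steps of 100 is accepted,
        6 of 100 is rejected."""
        sched = make_schedule(100, 1e-3, 0.05)
        # members disagree (antipodal) only on the first `bad_steps` reverse steps
        bad = set(range(100, 100 - bad_steps, -1))
        ck1 = _stub_checkpoint(lambda xt, t: np.ones_like(xt), cond_name="a", schedule=sched)
        ck2 = _stub_checkpoint(
            lambda xt, t: -np.ones_like(xt) if t in bad else np.ones_like(xt),
            cond_name="b", schedule=sched,
        )
        ens = EnsembleSpec([(ck1, "a"), (ck2, "b")], np.array([0.5, 0.5]))
        cond = ConditionSet({"a": np.zeros((2, 2)), "b": np.zeros((2, 2))})
        res = coherent_sample(ens, cond, sched, n=2, seed=1, max_retries=1)
        assert res.accepted is accepted
        assert res.diagnostics.incoherent_fraction == pytest.approx(bad_steps / 100)


class TestOracleConsensus:
    def test_two_gaussian_oracles_blend_by_weights(self):
        """With identity covariance, the weighted consensus of two oracles
        conditioned on different means is itself the exact oracle for the
        weighted mean — verified against that closed-form sampler."""
        sched = make_schedule(400, 1e-4, 0.03)
        mu1, mu2 = np.array([3.0, 0.0]), np.array([-1.0, 2.0])
        w = compute_weights([0.5, 1.0])  # [2/3, 1/3]
        p1 = gaussian_oracle_predictor(mu1, np.eye(2), sched)
        p2 = gaussian_oracle_predictor(mu2, np.eye(2), sched)
        ck1 = _stub_checkpoint(lambda xt, t: p1(xt, t), cond_name="a", schedule=sched)
        ck2 = _stub_checkpoint(lambda xt, t: p2(xt, t), cond_name="b", schedule=sched)
        ck1.best_val_mse, ck2.best_val_mse = 0.5, 1.0
        ens = EnsembleSpec([(ck1, "a"), (ck2, "b")], w)
        cond = ConditionSet({"a": np.zeros((1500, 2)), "b": np.zeros((1500, 2))})
        # threshold above the cosine-distance maximum: no trajectory is
        # rejected, so the comparison isolates the consensus dynamics
        res = coherent_sample(ens, cond, sched, n=1500, seed=3, threshold=2.1)
        blended = w[0] * mu1 + w[1] * mu2
        # independent closed-form route: single oracle at the blended mean
        direct = sample(
            gaussian_oracle_predictor(blended, np.eye(2), sched),
            sched, 1500, 2, seed=3,
        )
        np.testing.assert_allclose(res.samples, direct, atol=1e-8)
        assert np.all(np.abs(res.samples.mean(0) - blended) < 3 / np.sqrt(1500) * 1.5)


class TestMultiConditionSample:
    def test_full_mask_runs_unconditionally(self, privacy_setup):
        multi = privacy_setup["multi"]
        cond = ConditionSet.empty(multi.condition_modalities, n=10)
        out = multi_condition_sample(multi, cond, seed=4)
        assert out.shape == (10, multi.network.D)

    def test_deterministic(self, privacy_setup):
        multi = privacy_setup["multi"]
        val = privacy_setup["val"]
        cond = ConditionSet({"cna": val["cna"][:8]})
        a = multi_condition_sample(multi, cond, seed=11)
        b = multi_condition_sample(multi, cond, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_unknown_modality_rejected(self, privacy_setup):
        multi = privacy_setup["multi"]
        with pytest.raises(KeyError):
            multi_condition_sample(multi, ConditionSet({"bogus": np.zeros((2, 2))}), seed=0)


class TestUnconditionalProbe:
    def test_probe_deterministic(self, privacy_setup):
        ens = privacy_setup["ensemble"]
        sched = privacy_setup["schedule"]
        a = unconditional_probe(ens, sched, 16, seed=5)
        b = unconditional_probe(ens, sched, 16, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_ensemble_probe_concentrates_near_global_mean(self, privacy_setup):
        """Zero-conditioned single-condition members generate around the
        distribution mean, far from every cluster."""
        ens = privacy_setup["ensemble"]
        sched = privacy_setup["schedule"]
        tr = privacy_setup["train"]["rnaseq"]
        probe = unconditional_probe(ens, sched, 200, seed=5)
        # spread of the probe is far below the (standardized) data spread
        assert probe.std(axis=0).mean() < 0.8 * tr.std(axis=0).mean()
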