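import numpy as np
import pandas as pd
import pytest

from coherentgen.experiments import (
    CounterfactualScore,
    ExperimentConfig,
    OracleGenerator,
    TruthPosteriorGenerator,
    completion_experiment,
    counterfactual_variance_score,
    parity_experiment,
    prioritization_curves,
)


@pytest.fixture(scope="module")
def exp_cfg():
    return ExperimentConfig(n_runs=3, n_estimators=150, seed=0)


class TestGeneratorWrappers:
    def test_diffusion_generator_conditions_on_known_modalities(self, privacy_setup):
        import pandas as pd

        from coherentgen.experiments import DiffusionGenerator

        gen = DiffusionGenerator(privacy_setup["multi"])
        ids = [f"v{i}" for i in range(12)]
        cond = {"cna": pd.DataFrame(privacy_setup["val"]["cna"][:12], index=ids)}
        out = gen.generate("rnaseq", cond, seed=3)
        assert out.shape == (12, 8)
        assert list(out.index) == ids
        pd.testing.assert_frame_equal(out, gen.generate("rnaseq", cond, seed=3))
        with pytest.raises(ValueError, match="generates"):
            gen.generate("cna", cond, seed=0)

    def test_coherent_generator_records_diagnostics(self, privacy_setup):
        import pandas as pd

        from coherentgen.experiments import CoherentGenerator

        gen = CoherentGenerator(privacy_setup["ensemble"])
        ids = [f"v{i}" for i in range(10)]
        cond = {"cna": pd.DataFrame(privacy_setup["val"]["cna"][:10], index=ids)}
        out = gen.generate("rnaseq", cond, seed=5)
        assert out.shape == (10, 8)
        assert gen.last_result is not None
        # single-member ensemble: perfectly coherent, never rejected
        assert gen.last_result.accepted
        assert gen.last_result.retries_used == 0


class TestParityExperiment:
    def test_oracle_generator_scores_identical_to_real(self, small_cohort, small_split, exp_cfg):
        oracle = OracleGenerator(small_cohort.latents)
        table = parity_experiment(
            small_cohort, small_split, {"oracle": oracle}, exp_cfg,
            modalities=["rnaseq", "cna"], tasks=["type"],
        )
        for m in ("rnaseq", "cna"):
            sub = table[(table["modality"] == m) & (table["metric"] == "macro_f1")]
            real = sub[sub["method"] == "real"]["value"].iloc[0]
            synth = sub[sub["method"] == "oracle"]["value"].iloc[0]
            assert synth == pytest.approx(real)
            assert sub[sub["method"] == "oracle"]["sd"].iloc[0] == 0.0

    def test_truth_generator_parity_on_reconstructible_modality(
        self, small_cohort, small_split, exp_cfg
    ):
        """rnaseq is shared-dominated, so classifiers should score nearly
        the same on generated and real data."""
        gen = TruthPosteriorGenerator(small_cohort)
        table = parity_experiment(
            small_cohort, small_split, {"truth": gen}, exp_cfg,
            modalities=["rnaseq"], tasks=["type"],
        )
        sub = table[table["metric"] == "macro_f1"]
        real = sub[sub["method"] == "real"]["value"].iloc[0]
        synth = sub[sub["method"] == "truth"]["value"].iloc[0]
        assert abs(real - synth) < 0.1

    def test_dispersion_reported_for_repeated_runs(self, small_cohort, small_split, exp_cfg):
        gen = TruthPosteriorGenerator(small_cohort)
        table = parity_experiment(
            small_cohort, small_split, {"truth": gen}, exp_cfg,
            modalities=["cna"], tasks=["stage"],
        )
        synth = table[(table["method"] == "truth")]
        assert (synth["n_runs"] == exp_cfg.n_runs).all()
        assert synth["sd"].notna().all()


class TestCompletionExperiment:
    def test_oracle_gain_exactly_cancels_drop(self, small_cohort, small_split, exp_cfg):
        oracle = OracleGenerator(small_cohort.latents)
        table = completion_experiment(
            small_cohort, small_split, {"oracle": oracle},
            [["rnaseq", "wsi"]], exp_cfg,
        )
        for task in ("stage", "survival"):
            sub = table[table["task"] == task]
            drop = sub[sub["quantity"] == "drop_from_ablation"]["mean"].iloc[0]
            gain = sub[sub["quantity"] == "gain_oracle"]["mean"].iloc[0]
            assert gain == pytest.approx(-drop, abs=1e-12)
            assert sub[sub["quantity"] == "gain_oracle"]["sd"].iloc[0] == 0.0

    def test_empty_pattern_has_zero_drop_and_gain(self, small_cohort, small_split, exp_cfg):
        oracle = OracleGenerator(small_cohort.latents)
        table = completion_experiment(
            small_cohort, small_split, {"oracle": oracle}, [[]], exp_cfg,
            tasks=["stage"],
        )
        sub = table[table["task"] == "stage"]
        assert sub[sub["quantity"] == "drop_from_ablation"]["mean"].iloc[0] == 0.0
        assert sub[sub["quantity"] == "gain_oracle"]["mean"].iloc[0] == 0.0

    def test_truth_completion_recovers_performance(self, small_cohort, small_split, exp_cfg):
        """Removing the two most shared-informative modalities hurts, and
        truth-based completion recovers a gain within 2 sd of the drop."""
        gen = TruthPosteriorGenerator(small_cohort)
        table = completion_experiment(
            small_cohort, small_split, {"truth": gen},
            [["rnaseq", "wsi"]], exp_cfg, tasks=["stage"],
        )
        sub = table[table["task"] == "stage"]
        drop = sub[sub["quantity"] == "drop_from_ablation"]["mean"].iloc[0]
        gain_row = sub[sub["quantity"] == "gain_truth"]
        gain, sd = gain_row["mean"].iloc[0], gain_row["sd"].iloc[0]
        assert drop < 0
        assert gain > 0
        assert abs(gain - (-drop)) <= 2 * max(sd, 0.02)


class TestCounterfactualScore:
    def test_deterministic_generator_scores_zero(self, small_cohort, small_split):
        from sklearn.ensemble import RandomForestClassifier

        X_tr = pd.concat(
            [small_cohort.latents[m].loc[small_split.train_ids]
             for m in small_cohort.modalities], axis=1,
        )
        clf = RandomForestClassifier(n_estimators=50, random_state=0)
        clf.fit(X_tr.to_numpy(float), small_cohort.stage_label.loc[small_split.train_ids])
        oracle = OracleGenerator(small_cohort.latents)  # seed-independent output
        sid = small_split.test_ids[0]
        profile = {m: small_cohort.latents[m].loc[[sid]] for m in small_cohort.modalities}
        score = counterfactual_variance_score(
            clf, profile, oracle, "rnaseq", X_tr.columns, n_versions=4,
            seeds=[1, 2, 3, 4],
        )
        assert score.score == 0.0
        assert score.sample_id == str(sid)

    def test_classifier_ignoring_modality_scores_zero(self, small_cohort, small_split):
        class ConstantClassifier:
            def predict_proba(self, X):
                return np.tile([0.25, 0.25, 0.25, 0.25], (len(X), 1))

        gen = TruthPosteriorGenerator(small_cohort)
        sid = small_split.test_ids[0]
        profile = {m: small_cohort.latents[m].loc[[sid]] for m in small_cohort.modalities}
        cols = pd.concat(
            [small_cohort.latents[m] for m in small_cohort.modalities], axis=1
        ).columns
        score = counterfactual_variance_score(
            ConstantClassifier(), profile, gen, "rnaseq", cols, n_versions=4,
            seeds=[1, 2, 3, 4],
        )
        assert score.score == 0.0

    def test_matches_brute_force_recomputation(self, small_cohort, small_split):
        """The score equals the variance of the stored probability vectors
        recomputed exhaustively."""
        from sklearn.ensemble import RandomForestClassifier

        X_tr = pd.concat(
            [small_cohort.latents[m].loc[small_split.train_ids]
             for m in small_cohort.modalities], axis=1,
        )
        clf = RandomForestClassifier(n_estimators=50, random_state=0)
        clf.fit(X_tr.to_numpy(float), small_cohort.stage_label.loc[small_split.train_ids])
        gen = TruthPosteriorGenerator(small_cohort)
        sid = small_split.test_ids[3]
        profile = {m: small_cohort.latents[m].loc[[sid]] for m in small_cohort.modalities}
        seeds = [10, 20, 30, 40, 50]
        score = counterfactual_variance_score(
            clf, profile, gen, "rnaseq", X_tr.columns, n_versions=5, seeds=seeds
        )
        probas = []
        for s in seeds:
            block = gen.generate("rnaseq", {m: profile[m] for m in profile if m != "rnaseq"}, seed=s)
            completed = {m: (block if m == "rnaseq" else profile[m])
                         for m in small_cohort.modalities}
            X = pd.concat(completed.values(), axis=1)[X_tr.columns]
            probas.append(clf.predict_proba(X.to_numpy(float))[0])
        expected = np.stack(probas).var(axis=0).mean()
        assert score.score == pytest.approx(expected, abs=1e-15)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            CounterfactualScore("s", "rnaseq", -0.1)


class TestPrioritizationCurves:
    def test_endpoint_fractions_equalize_strategies(self, prioritization_setup):
        setup = prioritization_setup
        cfg = ExperimentConfig(
            n_runs=2, n_estimators=300, seed=0, acquisition_fractions=(0.0, 1.0)
        )
        curves = prioritization_curves(
            setup["cohort"], setup["split"], setup["classifier"], setup["generator"],
            "rnaseq", setup["scores"], cfg,
        )
        # at 0% and 100% acquisition both strategies see identical data
        np.testing.assert_allclose(curves["informed_mean"], curves["random_mean"])
        assert curves["informed_sd"].iloc[1] == 0.0  # full acquisition: no generation

    def test_informed_beats_random_on_private_signal_scenario(self, prioritization_setup):
        setup = prioritization_setup
        cfg = ExperimentConfig(n_runs=10, n_estimators=300, seed=0)
        curves = prioritization_curves(
            setup["cohort"], setup["split"], setup["classifier"], setup["generator"],
            "rnaseq", setup["scores"], cfg,
        )
        wins = sum(
            a >= b for a, b in zip(curves.attrs["areas_informed"],
                                   curves.attrs["areas_random"])
        )
        assert wins >= 9
        assert curves.attrs["area_informed"] > curves.attrs["area_random"]

    def test_minority_samples_receive_higher_scores(self, prioritization_setup):
        setup = prioritization_setup
        cohort = setup["cohort"]
        mask = cohort.truth["private_stage_mask"]
        pos = {sid: i for i, sid in enumerate(cohort.sample_ids)}
        minority = [s.score for s in setup["scores"] if mask[pos[s.sample_id]]]
        majority = [s.score for s in setup["scores"] if not mask[pos[s.sample_id]]]
        assert np.mean(minority) > 2 * np.mean(majority)

    def test_incomplete_scores_rejected(self, prioritization_setup):
        setup = prioritization_setup
        with pytest.raises(ValueError, match="cover"):
            prioritization_curves(
                setup["cohort"], setup["split"], setup["classifier"],
                setup["generator"], "rnaseq", setup["scores"][:-1],
                ExperimentConfig(n_runs=1, seed=0),
            )
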