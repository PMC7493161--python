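"""Training-procedure contracts: determinism, reductions, loss descent,
checkpoint selection, cross-validated reporting."""

import numpy as np
import pandas as pd
import pytest

from omicsfuse.containers import OmicsMatrix, SurvivalTable
from omicsfuse.datagen import SyntheticOmicsConfig, simulate_omics_survival
from omicsfuse.evaluation import paired_hidden_distance
from omicsfuse.losses import mse_recon
from omicsfuse.models import NetworkSpec, build_bundle, decode, encode
from omicsfuse.training import (TaskData, TrainConfig, run_cross_validation,
                                train_concat, train_cross, train_single)


def separable_data(rng, n=50, d=10):
    """Two linearly separable classes."""
    y = np.repeat([0, 1], n // 2)
    x = rng.uniform(0, 0.3, size=(n, d))
    x[y == 1, :3] += 0.6
    return TaskData([x], labels=y)


def states_equal(s1, s2):
    return all(np.array_equal(a, b)
               for m1, m2 in zip(s1, s2) for a, b in zip(m1, m2))


@pytest.fixture
def clf_spec():
    return NetworkSpec(input_dim=10, latent_dim=4, head="classifier",
                       n_classes=2)


class TestTrainSingle:
    def test_zero_epochs_leaves_parameters_unchanged(self, rng, clf_spec):
        bundle = build_bundle([clf_spec], "single", seed=0)
        before = bundle.get_state()
        cfg = TrainConfig(endpoint="classification", epochs=0, seed=0)
        train_single(bundle, separable_data(rng), cfg)
        assert states_equal(before, bundle.get_state())

    def test_separable_data_reaches_full_training_accuracy(self, rng, clf_spec):
        data = separable_data(rng)
        bundle = build_bundle([clf_spec], "single", seed=1)
        cfg = TrainConfig(endpoint="classification", epochs=200, seed=1)
        res = train_single(bundle, data, cfg)
        pred = res.bundle.predict(data.xs).argmax(axis=1)
        assert np.mean(pred == data.labels) == 1.0

    def test_reconstruction_improves_over_training(self, rng, clf_spec):
        data = separable_data(rng)
        bundle = build_bundle([clf_spec], "single", seed=2)
        x = data.xs[0]
        init_recon = mse_recon(x, decode(bundle.decoders[0],
                                         encode(bundle.encoders[0], x, clf_spec),
                                         clf_spec))
        cfg = TrainConfig(endpoint="classification", epochs=50, seed=2)
        res = train_single(bundle, data, cfg)
        final_recon = mse_recon(x, decode(res.bundle.decoders[0],
                                          encode(res.bundle.encoders[0], x, clf_spec),
                                          clf_spec))
        assert final_recon < init_recon
        assert res.trace["recon_loss"].iloc[-1] < res.trace["recon_loss"].iloc[0]

    def test_deterministic_given_seed(self, rng, clf_spec):
        data = separable_data(rng)
        cfg = TrainConfig(endpoint="classification", epochs=10, seed=3)
        traces = []
        for _ in range(2):
            bundle = build_bundle([clf_spec], "single", seed=3)
            traces.append(train_single(bundle, data, cfg).trace)
        pd.testing.assert_frame_equal(traces[0], traces[1])

    def test_survival_without_events_raises(self, rng, clf_spec):
        spec = NetworkSpec(input_dim=10, latent_dim=4, head="survival")
        bundle = build_bundle([spec], "single", seed=0)
        data = TaskData([rng.uniform(size=(20, 10))],
                        time=rng.exponential(5, 20) + 0.1,
                        event=np.zeros(20, int))
        with pytest.raises(ValueError, match="no events"):
            train_single(bundle, data, TrainConfig(endpoint="survival"))


class TestTrainConcat:
    def test_single_modality_reduces_to_train_single(self, rng, clf_spec):
        data = separable_data(rng)
        cfg = TrainConfig(endpoint="classification", epochs=8, seed=4)
        b_single = build_bundle([clf_spec], "single", seed=4)
        b_concat = build_bundle([clf_spec], "concat", seed=4)
        t_single = train_single(b_single, data, cfg).trace
        t_concat = train_concat(b_concat, data, cfg).trace
        pd.testing.assert_frame_equal(t_single, t_concat)
        assert states_equal(b_single.get_state(), b_concat.get_state())

    def test_both_modalities_reconstruction_improves(self, rng, clf_spec):
        x1 = separable_data(rng)
        x2 = rng.uniform(size=(50, 10))
        data = TaskData([x1.xs[0], x2], labels=x1.labels)
        bundle = build_bundle([clf_spec, clf_spec], "concat", seed=5)

        def recon(b, m):
            return mse_recon(data.xs[m],
                             decode(b.decoders[m],
                                    encode(b.encoders[m], data.xs[m], clf_spec),
                                    clf_spec))

        init = [recon(bundle, 0), recon(bundle, 1)]
        cfg = TrainConfig(endpoint="classification", epochs=50, seed=5)
        res = train_concat(bundle, data, cfg)
        assert recon(res.bundle, 0) < init[0]
        assert recon(res.bundle, 1) < init[1]

    def test_head_consumes_sum_of_latent_dims(self, clf_spec):
        bundle = build_bundle([clf_spec, clf_spec], "concat", seed=0)
        assert bundle.head_input_dim == 8


class TestTrainCross:
    def test_zero_budgets_leave_parameters_unchanged(self, rng, clf_spec):
        bundle = build_bundle([clf_spec, clf_spec], "cross", seed=6)
        before = bundle.get_state()
        data = TaskData([rng.uniform(size=(30, 10))] * 2,
                        labels=rng.integers(0, 2, 30))
        cfg = TrainConfig(endpoint="classification", epochs=0, seed=6,
                          epochs_per_cross_step=(0, 0, 0))
        train_cross(bundle, data, cfg)
        assert states_equal(before, bundle.get_state())

    def test_identical_modalities_cross_recon_matches_within_recon(self, rng,
                                                                   clf_spec):
        # with x1 = x2, reconstructing across modalities is the same task
        # as reconstructing within; losses should land close together
        x = separable_data(rng).xs[0]
        data = TaskData([x, x.copy()], labels=separable_data(rng).labels)
        bundle = build_bundle([clf_spec, clf_spec], "cross", seed=7)
        cfg = TrainConfig(endpoint="classification", seed=7,
                          epochs_per_cross_step=(40, 40, 5))
        res = train_cross(bundle, data, cfg)
        trace = res.trace
        within = trace[trace.phase == "recon"]["loss"].iloc[-1]
        across = trace[trace.phase == "cross"]["loss"].iloc[-1]
        assert across == pytest.approx(within, rel=0.5)

    def test_cross_step_aligns_paired_latents(self, clf_spec):
        # on shared-signal data, adding the cross-reconstruction phase must
        # shrink the mean paired-latent distance relative to step 1 alone
        cfg_gen = SyntheticOmicsConfig(n_samples=200,
                                       features_per_modality=(10, 10),
                                       effect_unique=0.0, noise_sd=0.3, seed=8)
        mats, table, _ = simulate_omics_survival(cfg_gen)
        spec = NetworkSpec(input_dim=10, latent_dim=4, head="survival")
        data = TaskData([m.values for m in mats], time=table.time,
                        event=table.event)

        def mean_dist(budgets):
            bundle = build_bundle([spec, spec], "cross", seed=8)
            cfg = TrainConfig(endpoint="survival", seed=8,
                              epochs_per_cross_step=budgets)
            res = train_cross(bundle, data, cfg)
            zs = [encode(e, x, spec) for e, x in zip(res.bundle.encoders, data.xs)]
            return paired_hidden_distance(zs[0], zs[1])[1]["mean"]

        assert mean_dist((30, 30, 0)) < mean_dist((30, 0, 0))

    def test_unequal_latent_dims_rejected(self):
        s1 = NetworkSpec(input_dim=10, latent_dim=4, head="survival")
        s2 = NetworkSpec(input_dim=10, latent_dim=6, head="survival")
        with pytest.raises(ValueError):
            build_bundle([s1, s2], "cross", seed=0)

    def test_interleaved_schedule_runs_all_phases(self, rng, clf_spec):
        bundle = build_bundle([clf_spec, clf_spec], "cross", seed=9)
        data = TaskData([rng.uniform(size=(40, 10))] * 2,
                        labels=rng.integers(0, 2, 40))
        cfg = TrainConfig(endpoint="classification", seed=9,
                          epochs_per_cross_step=(3, 3, 3),
                          interleave_cross_steps=True)
        res = train_cross(bundle, data, cfg)
        assert set(res.trace["phase"]) == {"recon", "cross", "task"}


@pytest.fixture(scope="module")
def omics():
    cfg = SyntheticOmicsConfig(n_samples=120, features_per_modality=(15, 15),
                               effect_shared=1.0, censoring_fraction=0.3,
                               seed=10)
    return simulate_omics_survival(cfg)


class TestRunCrossValidation:
    def test_survival_cv_reports_four_folds(self, omics):
        mats, table, _ = omics
        cfg = TrainConfig(endpoint="survival", epochs=3, seed=0)
        result = run_cross_validation(mats, integration="concat",
                                      survival=table, feature_mode="none",
                                      latent_dim=4, config=cfg, seed=0)
        rep = result.reports["c_index"]
        assert len(rep.fold_values) == 4
        assert 0.0 <= rep.mean <= 1.0
        assert rep.std >= 0
        # mean ± std formatting convention
        assert "±" in str(rep)
        assert result.distances is not None
        assert set(result.distances["fold"]) == {0, 1, 2, 3}

    def test_checkpoint_selected_on_validation_only(self, omics):
        mats, table, _ = omics
        cfg = TrainConfig(endpoint="survival", epochs=4, seed=1)
        result = run_cross_validation(mats[:1], integration="single",
                                      survival=table, feature_mode="none",
                                      latent_dim=4, config=cfg, seed=1)
        assert all(result.fold_details["best_epoch"] < 4)
        assert all(result.fold_details["best_val_metric"].notna())

    def test_mismatched_sample_ids_rejected(self, omics):
        mats, table, _ = omics
        other = OmicsMatrix(mats[1].values,
                            [f"X{i}" for i in range(mats[1].n_samples)],
                            mats[1].feature_ids, "m2")
        with pytest.raises(ValueError, match="do not match"):
            run_cross_validation([mats[0], other], integration="concat",
                                 survival=table, feature_mode="none")

    def test_fewer_than_two_folds_rejected(self, omics):
        mats, table, _ = omics
        with pytest.raises(ValueError):
            run_cross_validation(mats, integration="concat", survival=table,
                                 n_folds=1)

    def test_classification_cv_metric_names(self, rng):
        x = rng.uniform(size=(80, 12))
        y = (x[:, 0] > 0.5).astype(int)
        mat = OmicsMatrix(x, [f"s{i}" for i in range(80)],
                          [f"f{j}" for j in range(12)], "m1")
        cfg = TrainConfig(endpoint="classification", epochs=3, seed=2)
        result = run_cross_validation([mat], integration="single", labels=y,
                                      feature_mode="none", latent_dim=4,
                                      config=cfg, seed=2)
        assert set(result.reports) == {"accuracy", "weighted_precision",
                                       "weighted_recall"}
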