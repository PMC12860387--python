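"""Loss identities, K-fold partitioning, and training-loop contracts."""

import numpy as np
import pytest

from spotdecon.config import RunConfig
from spotdecon.data_io import PathologyLabels, ProportionMatrix, StDataset
from spotdecon.pipeline import simulate_run, train_run
from spotdecon.simulator import PseudoSpotConfig, simulate_pseudospots
from spotdecon.metrics import evaluate_folds
from spotdecon.pipeline import build_model
from spotdecon.training import (LossWeights, TrainConfig, cross_validate,
                                deconvolve, fit, kfold_split, loss_deconv,
                                loss_hist, loss_match, loss_recon, total_loss)


class TestCrossEntropies:
    def test_one_hot_perfect_prediction_is_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_deconv(y, y.copy()) == pytest.approx(0.0, abs=1e-10)
        assert loss_hist(y, y.copy()) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_equals_n_log_p(self, rng):
        s1, p1 = 17, 5
        y = rng.dirichlet(np.ones(p1), size=s1)
        yhat = np.full((s1, p1), 1.0 / p1)
        assert loss_deconv(y, yhat) == pytest.approx(s1 * np.log(p1), rel=1e-12)

    def test_hand_case_direct_evaluation(self):
        val = loss_deconv(np.array([[0.7, 0.3]]), np.array([[0.6, 0.4]]))
        assert val == pytest.approx(-(0.7 * np.log(0.6) + 0.3 * np.log(0.4)),
                                    rel=1e-12)
        assert val == pytest.approx(0.6325, abs=5e-5)

    def test_random_case_matches_brute_force(self, rng):
        y = rng.dirichlet(np.ones(4), size=6)
        yhat = rng.dirichlet(np.ones(4), size=6)
        brute = -sum(y[i, j] * np.log(yhat[i, j])
                     for i in range(6) for j in range(4))
        assert loss_hist(y, yhat) == pytest.approx(brute, rel=1e-9)

    def test_lower_bound_is_row_entropy_sum(self, rng):
        y = rng.dirichlet(np.ones(3), size=10)
        entropy = -(y * np.log(np.clip(y, 1e-300, None))).sum()
        assert loss_deconv(y, y.copy()) == pytest.approx(entropy, rel=1e-9)
        for _ in range(5):
            other = rng.dirichlet(np.ones(3), size=10)
            assert loss_deconv(y, other) >= entropy - 1e-9


class TestReconLoss:
    def test_perfect_reconstruction_zero(self, rng):
        x = rng.normal(size=(4, 6))
        assert loss_recon(x, x.copy()) == 0.0

    def test_constant_offset_closed_form(self, rng):
        r, g, delta = 7, 11, 0.3
        x = rng.normal(size=(r, g))
        assert loss_recon(x, x + delta, "sum") == pytest.approx(
            r * g * delta ** 2, rel=1e-9)
        assert loss_recon(x, x + delta, "mean") == pytest.approx(
            delta ** 2, rel=1e-9)

    def test_random_pair_matches_elementwise_brute_force(self, rng):
        a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        brute = sum((a[i, j] - b[i, j]) ** 2 for i in range(3) for j in range(4))
        assert loss_recon(a, b) == pytest.approx(brute, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            loss_recon(np.zeros((2, 2)), np.zeros((2, 3)))


class TestMatchLoss:
    def test_all_half_probabilities_give_log_two(self):
        p = np.full(6, 0.5)
        assert loss_match(p, p) == pytest.approx(np.log(2), abs=1e-9)

    def test_certain_correct_domains_drive_loss_to_zero(self):
        assert loss_match(np.full(4, 1 - 1e-9), np.full(4, 1e-9)) < 1e-6

    def test_two_sample_hand_case(self):
        pr, ps = np.array([0.8]), np.array([0.3])
        expected = -(np.log(0.8) + np.log(0.7)) / 2
        assert loss_match(pr, ps) == pytest.approx(expected, rel=1e-9)


class TestTotalLoss:
    def test_real_data_default_weights(self):
        w = LossWeights()
        assert (w.lambda1, w.lambda2, w.lambda3) == (0.1, 0.1, 0.01)

    def test_all_zero_weights_reduce_to_deconv(self):
        w = LossWeights(0.0, 0.0, 0.0)
        assert total_loss((3.7, 9, 9, 9), w) == 3.7

    def test_weighted_arithmetic(self):
        w = LossWeights(0.1, 0.1, 0.01)
        assert total_loss((1, 2, 3, 4), w) == pytest.approx(1.54)

    def test_linear_in_each_lambda(self, rng):
        comps = tuple(rng.random(4) * 5)
        base = LossWeights(0.2, 0.3, 0.4)
        eps = 1e-6
        for i, name in enumerate(("lambda1", "lambda2", "lambda3")):
            kw = dict(lambda1=0.2, lambda2=0.3, lambda3=0.4)
            kw[name] += eps
            slope = (total_loss(comps, LossWeights(**kw))
                     - total_loss(comps, base)) / eps
            assert slope == pytest.approx(comps[i + 1], rel=1e-5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0, 0)


class TestKfold:
    def test_singleton_folds(self):
        folds = kfold_split(10, 10, seed=1)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_25_into_10_gives_five_threes_and_five_twos(self):
        sizes = sorted(len(f) for f in kfold_split(25, 10, seed=2))
        assert sizes == [2] * 5 + [3] * 5

    def test_partition_property(self, rng):
        n, k = int(rng.integers(20, 100)), int(rng.integers(2, 11))
        folds = kfold_split(n, k, seed=3)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == n and len(set(all_idx.tolist())) == n

    def test_deterministic_in_seed(self):
        a = kfold_split(30, 4, seed=9)
        b = kfold_split(30, 4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10)


@pytest.fixture(scope="module")
def tiny_study():
    cfg = RunConfig({"seed": 3, "simulator": {
        "n_cells": 300, "n_genes": 60, "n_types": 3, "n_spots": 80,
        "slide_rows": 6, "slide_cols": 6, "n_regions": 3,
        "spacing_px": 30.0, "image_margin_px": 40}})
    return cfg, simulate_run(cfg)


class TestFit:
    def test_zero_epochs_leaves_parameters_untouched(self, tiny_study):
        cfg, study = tiny_study
        model, curves = train_run(cfg, study, epochs=0)
        fresh, _ = train_run(cfg, study, epochs=0)
        for k in model.params:
            np.testing.assert_array_equal(model.params[k].data,
                                          fresh.params[k].data)
        assert curves["deconv"] == []

    def test_losses_decrease_on_tiny_run(self, tiny_study):
        cfg, study = tiny_study
        _, curves = train_run(cfg, study, epochs=25, batch_size=40)
        assert curves["deconv"][-1] < curves["deconv"][0]
        assert curves["recon"][-1] < curves["recon"][0]

    def test_missing_pathology_with_lambda1_rejected(self, tiny_study):
        cfg, study = tiny_study
        real = StDataset(expression=study.real.expression,
                         coords=study.real.coords, image=study.real.image)
        with pytest.raises(ValueError, match="lambda1"):
            fit(study.simulated, real, None,  # model never reached
                TrainConfig(epochs=1), LossWeights(0.1, 0.1, 0.0))

    def test_unaligned_gene_spaces_rejected(self, tiny_study, small_reference):
        cfg, study = tiny_study
        expr, props = simulate_pseudospots(small_reference,
                                           PseudoSpotConfig(n_spots=5, seed=1))
        sim = StDataset(expression=expr, proportions=props)
        with pytest.raises(ValueError, match="align"):
            fit(sim, study.real, None, TrainConfig(epochs=1),
                LossWeights(0, 0.1, 0))

    def test_table_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.epochs == 300 and cfg.batch_size == 400
        assert cfg.k_folds == 10


@pytest.fixture(scope="module")
def trained(tiny_study):
    cfg, study = tiny_study
    model, _ = train_run(cfg, study, epochs=15, batch_size=40)
    return model


class TestCrossValidation:
    def test_folds_cover_every_spot_once_and_aggregate(self, tiny_study):
        cfg, study = tiny_study
        from spotdecon.data_io import align_genes
        sim_e, real_e = align_genes(study.simulated.expression,
                                    study.real.expression, n_top=None)
        sim = StDataset(expression=sim_e,
                        proportions=study.simulated.proportions)
        real = StDataset(expression=real_e, coords=study.real.coords,
                         image=study.real.image, pathology=study.real.pathology)
        tc = TrainConfig(epochs=2, batch_size=40, k_folds=3, seed=1)
        n_classes = len(real.pathology.class_names)

        def factory():
            return build_model(cfg, sim_e.n_genes, 3, n_classes)

        folds = cross_validate(sim, real, factory, tc,
                               LossWeights(0.1, 0.1, 0.01))
        covered = np.concatenate([idx for idx, _ in folds])
        assert sorted(covered.tolist()) == list(range(real_e.n_spots))
        report = evaluate_folds(folds, study.real_truth.values,
                                real.coords.xy)
        assert np.isfinite(report.pcc_mean) and report.rmse >= 0


class TestDeconvolve:
    def test_rows_on_simplex(self, tiny_study, trained):
        _, study = tiny_study
        props = deconvolve(trained, trained._trained_real)
        np.testing.assert_allclose(props.values.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(props.values >= 0)

    def test_deterministic(self, tiny_study, trained):
        a = deconvolve(trained, trained._trained_real)
        b = deconvolve(trained, trained._trained_real)
        np.testing.assert_array_equal(a.values, b.values)

    def test_gene_space_mismatch_reported(self, tiny_study, trained,
                                          small_reference):
        expr, _ = simulate_pseudospots(small_reference,
                                       PseudoSpotConfig(n_spots=8, seed=2))
        with pytest.raises(ValueError, match="gene-space"):
            deconvolve(trained, StDataset(expression=expr))
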