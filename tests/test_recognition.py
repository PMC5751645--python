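import math

import numpy as np
import pytest
from scipy import stats

from microexp.descriptors import DisplacementFeature
from microexp.errors import ShapeError, TrainingError
from microexp.geometry import CELL_NAMES
from microexp.recognition import (CLASSES, ExpressionModel,
                                  classify_expression, fit_expression_models,
                                  mvn_logpdf)


def _feature(pairs_by_cell=None, n_pairs=10, fill=(0.0, 0.0)):
    pairs = {}
    for name in CELL_NAMES:
        if pairs_by_cell and name in pairs_by_cell:
            pairs[name] = np.asarray(pairs_by_cell[name], dtype=float)
        else:
            pairs[name] = np.tile(np.asarray(fill, dtype=float), (n_pairs, 1))
    return DisplacementFeature(pairs=pairs)


def _features_from_gaussian(rng, mu, sigma, n_sequences, n_pairs=10):
    feats = []
    for _ in range(n_sequences):
        pairs = {n: rng.multivariate_normal(mu[n], sigma[n], size=n_pairs)
                 for n in CELL_NAMES}
        feats.append(DisplacementFeature(pairs=pairs))
    return feats


class TestMvnLogpdf:
    def test_at_mean_identity_covariance(self):
        assert mvn_logpdf([0, 0], [0, 0], np.eye(2)) == pytest.approx(
            -math.log(2 * math.pi), abs=1e-12)

    def test_unit_offset(self):
        assert mvn_logpdf([1, 0], [0, 0], np.eye(2)) == pytest.approx(
            -math.log(2 * math.pi) - 0.5, abs=1e-12)

    def test_matches_scipy_on_random_spd(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.normal(size=(2, 2))
            sigma = a @ a.T + 0.1 * np.eye(2)
            mu = rng.normal(size=2)
            x = rng.normal(size=2)
            expected = stats.multivariate_normal(mean=mu, cov=sigma).logpdf(x)
            assert mvn_logpdf(x, mu, sigma) == pytest.approx(expected, abs=1e-9)

    def test_non_spd_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            mvn_logpdf([0, 0], [0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestFitExpressionModels:
    def test_recovers_known_gaussian(self):
        rng = np.random.default_rng(10)
        mu = {n: np.array([3.0, -1.0]) for n in CELL_NAMES}
        sigma = {n: np.array([[2.0, 0.5], [0.5, 1.0]]) for n in CELL_NAMES}
        feats = {cls: _features_from_gaussian(rng, mu, sigma, n_sequences=50)
                 for cls in CLASSES}  # 50 x 10 = 500 pairs per cell
        model = fit_expression_models(feats)
        for cell in CELL_NAMES:
            est_mu = model.means["positive"][cell]
            est_cov = model.covs["positive"][cell]
            assert np.abs(est_mu - [3.0, -1.0]).max() < 0.2
            assert np.abs(est_cov - sigma[cell]).max() < 0.3

    def test_identical_displacements_floor_covariance(self):
        feats = {cls: [_feature(fill=(1.0, 2.0)), _feature(fill=(1.0, 2.0))]
                 for cls in CLASSES}
        model = fit_expression_models(feats, cov_floor=1e-6)
        for cell in CELL_NAMES:
            np.testing.assert_array_equal(model.covs["surprise"][cell],
                                          1e-6 * np.eye(2))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        mu = {n: np.zeros(2) for n in CELL_NAMES}
        sigma = {n: np.eye(2) for n in CELL_NAMES}
        feats = {cls: _features_from_gaussian(rng, mu, sigma, 5)
                 for cls in CLASSES}
        m1 = fit_expression_models(feats)
        m2 = fit_expression_models(
            {cls: list(reversed(fs)) for cls, fs in feats.items()})
        for cls in CLASSES:
            for cell in CELL_NAMES:
                np.testing.assert_allclose(m1.means[cls][cell],
                                           m2.means[cls][cell], atol=1e-12)
                np.testing.assert_allclose(m1.covs[cls][cell],
                                           m2.covs[cls][cell], atol=1e-12)

    def test_missing_class_is_named_in_error(self):
        feats = {"positive": [_feature(), _feature()]}
        with pytest.raises(TrainingError, match="negative"):
            fit_expression_models(feats)

    def test_mean_pooling_mode(self):
        rng = np.random.default_rng(4)
        mu = {n: np.array([1.0, 0.0]) for n in CELL_NAMES}
        sigma = {n: 0.01 * np.eye(2) for n in CELL_NAMES}
        feats = {cls: _features_from_gaussian(rng, mu, sigma, 10)
                 for cls in CLASSES}
        model = fit_expression_models(feats, pooling="mean")
        assert model.counts["positive"] == 10  # one observation per sequence


def _random_model(rng, separation=6.0, shared_cov=False):
    means, covs = {}, {}
    shared = {}
    for cell in CELL_NAMES:
        a = rng.normal(size=(2, 2)) * 0.3
        shared[cell] = a @ a.T + np.eye(2)
    for ci, cls in enumerate(CLASSES):
        means[cls] = {}
        covs[cls] = {}
        for cell in CELL_NAMES:
            angle = 2 * math.pi * (ci / 3.0) + rng.uniform(-0.2, 0.2)
            means[cls][cell] = separation * np.array(
                [math.cos(angle), math.sin(angle)])
            if shared_cov:
                covs[cls][cell] = shared[cell]
            else:
                a = rng.normal(size=(2, 2)) * 0.3
                covs[cls][cell] = a @ a.T + np.eye(2)
    return ExpressionModel(means=means, covs=covs,
                           counts={c: 100 for c in CLASSES})


class TestClassifyExpression:
    def test_feature_at_class_mean_is_recovered(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, separation=8.0)
        for cls in CLASSES:
            feature = _feature({n: np.tile(model.means[cls][n], (10, 1))
                                for n in CELL_NAMES})
            assert classify_expression(feature, model).predicted == cls

    def test_identical_class_models_tie_break_on_order(self):
        means = {c: {n: np.zeros(2) for n in CELL_NAMES} for c in CLASSES}
        covs = {c: {n: np.eye(2) for n in CELL_NAMES} for c in CLASSES}
        model = ExpressionModel(means=means, covs=covs,
                                counts={c: 10 for c in CLASSES})
        result = classify_expression(_feature(), model)
        scores = list(result.scores.values())
        assert scores[0] == scores[1] == scores[2]
        assert result.predicted == "positive"  # first maximal in fixed order

    def test_matches_extended_precision_oracle(self):
        # independent oracle: scipy per-pair log-densities accumulated in
        # extended precision, argmax by enumeration
        rng = np.random.default_rng(6)
        for _ in range(200):
            model = _random_model(rng, separation=rng.uniform(0.0, 4.0))
            feature = _feature(
                {n: rng.normal(scale=3.0, size=(10, 2)) for n in CELL_NAMES})
            totals = {}
            for cls in CLASSES:
                acc = np.longdouble(0.0)
                for cell in CELL_NAMES:
                    mvn = stats.multivariate_normal(
                        mean=model.means[cls][cell], cov=model.covs[cls][cell])
                    for x in feature.pairs[cell]:
                        acc += np.longdouble(mvn.logpdf(x))
                totals[cls] = acc
            oracle = max(CLASSES, key=lambda c: totals[c])
            assert classify_expression(feature, model).predicted == oracle

    def test_invariant_under_common_cell_permutation(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng)
        feature = _feature({n: rng.normal(size=(10, 2)) for n in CELL_NAMES})
        base = classify_expression(feature, model)
        perm = list(CELL_NAMES)[::-1]
        feature2 = DisplacementFeature(
            pairs={n: feature.pairs[n] for n in CELL_NAMES})
        model2 = ExpressionModel(
            means={c: {n: model.means[c][n] for n in perm} for c in CLASSES},
            covs={c: {n: model.covs[c][n] for n in perm} for c in CLASSES},
            counts=model.counts, cell_order=tuple(perm))
        feature_perm = DisplacementFeature.__new__(DisplacementFeature)
        feature_perm.pairs = {n: feature.pairs[n] for n in perm}
        scores2 = classify_expression(feature_perm, model2).scores
        for cls in CLASSES:
            assert scores2[cls] == pytest.approx(base.scores[cls], rel=1e-12)

    def test_cell_order_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng)
        feature_perm = DisplacementFeature.__new__(DisplacementFeature)
        feature_perm.pairs = {n: np.zeros((10, 2))
                              for n in reversed(CELL_NAMES)}
        with pytest.raises(ShapeError):
            classify_expression(feature_perm, model)


class TestEndToEndSeparation:
    def _sampled_dataset(self, rng, separation, n_train=20, n_test=50):
        # shared covariances: at zero mean separation the classes are then
        # genuinely indistinguishable and accuracy must fall to chance
        model = _random_model(rng, separation=separation, shared_cov=True)
        train = {cls: _features_from_gaussian(
            rng, model.means[cls], model.covs[cls], n_train)
            for cls in CLASSES}
        test = [(cls, f) for cls in CLASSES
                for f in _features_from_gaussian(
                    rng, model.means[cls], model.covs[cls], n_test)]
        return train, test

    def test_high_separation_accuracy(self):
        rng = np.random.default_rng(21)
        train, test = self._sampled_dataset(rng, separation=6.0)
        fitted = fit_expression_models(train)
        correct = sum(classify_expression(f, fitted).predicted == cls
                      for cls, f in test)
        assert correct / len(test) >= 0.95

    def test_zero_separation_is_chance(self):
        rng = np.random.default_rng(22)
        train, test = self._sampled_dataset(rng, separation=0.0)
        fitted = fit_expression_models(train)
        correct = sum(classify_expression(f, fitted).predicted == cls
                      for cls, f in test)
        acc = correct / len(test)
        # 3-class chance band (99.9% binomial) at n = 150
        assert 1 / 3 - 3.3 * math.sqrt(2 / 9 / 150) <= acc \
            <= 1 / 3 + 3.3 * math.sqrt(2 / 9 / 150)

    def test_training_set_scores_are_finite(self):
        rng = np.random.default_rng(23)
        train, _ = self._sampled_dataset(rng, separation=2.0, n_test=1)
        fitted = fit_expression_models(train)
        for cls, feats in train.items():
            for f in feats:
                scores = classify_expression(f, fitted).scores
                assert all(np.isfinite(v) for v in scores.values())


class TestModelSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(30)
        model = _random_model(rng)
        path = tmp_path / "expr.json"
        model.save(path)
        loaded = ExpressionModel.load(path)
        for cls in CLASSES:
            for cell in CELL_NAMES:
                np.testing.assert_array_equal(loaded.means[cls][cell],
                                              model.means[cls][cell])
                np.testing.assert_array_equal(loaded.covs[cls][cell],
                                              model.covs[cls][cell])
        assert loaded.counts == model.counts
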