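import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import norm

from conftest import make_dataset
from mcsd.classifier import (
    MCSDModel,
    accuracy,
    bayes_risk_two_class,
    classify,
    estimate_utility,
    expected_utilities,
    fit,
    format_percent,
    gaussian_bayes_risk,
    identity_utility,
    load_model,
    logdensity_compressed,
    logdensity_original,
    predict,
    save_model,
    stability_experiment,
)
from mcsd.compress import CompressMatrix, project
from mcsd.errors import AlignmentError, InputError
from mcsd.synthetic import SyntheticConfig, generate


def toy_model(means, sigma=1.0, priors=None, utility=None, phi=None, m=None):
    """Hand-built compressed model for decision-rule tests."""
    means = np.asarray(means, dtype=float)
    n, dim = means.shape
    phi = phi if phi is not None else CompressMatrix.identity(dim)
    priors = np.full(n, 1.0 / n) if priors is None else np.asarray(priors)
    utility = identity_utility(n) if utility is None else np.asarray(utility)
    return MCSDModel(
        phi=phi,
        class_means=means,
        class_means_compressed=np.vstack([project(phi, mk) for mk in means]),
        sigma=np.array([sigma]),
        priors=priors,
        utility=utility,
        class_names=[f"c{k}" for k in range(n)],
    )


def separable_dataset(seed=0, n_classes=3, n_feat=40, per_class=5):
    """Effectively noise-free planted data: classes are exactly separable."""
    cfg = SyntheticConfig(
        n_classes=n_classes,
        block_sizes=(n_feat,),
        per_class_train=per_class,
        per_class_test=per_class - 1,
        informative_per_class_per_block=4,
        effect_size=200.0,
        noise_sigma=1e-3,
        seed=seed,
    )
    data = generate(cfg)
    return data.train_blocks[0], data.test_blocks[0]


class TestDensities:
    def test_standard_normal_at_mode(self):
        logp = logdensity_original(np.array([0.3]), np.array([0.3]), 1.0)
        assert np.exp(logp) == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_two_dim_at_mode(self):
        logp = logdensity_original(np.zeros(2), np.zeros(2), 1.0)
        assert np.exp(logp) == pytest.approx(1 / (2 * np.pi), rel=1e-12)

    def test_one_sigma_displacement_factor(self):
        s = np.array([1.0, 2.0])
        base = logdensity_original(s, s, 0.7)
        moved = logdensity_original(s + np.array([0.7, 0.0]), s, 0.7)
        assert moved - base == pytest.approx(-0.5, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            logdensity_original(np.zeros(1), np.zeros(1), 0.0)
        with pytest.raises(ValueError):
            logdensity_compressed(np.zeros(1), np.eye(1), np.zeros(1), -1.0)

    def test_compressed_reduces_to_original_for_identity_phi(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 7))
            y = rng.normal(size=n)
            s = rng.normal(size=n)
            sigma = float(rng.uniform(0.5, 2.0))
            a = logdensity_original(y, s, sigma)
            b = logdensity_compressed(y, np.eye(n), s, sigma)
            assert abs(a - b) <= 1e-12

    def test_sum_row_closed_form(self):
        # phi = (1, 1): compressed variance is 2, density at the mean 1/sqrt(4 pi)
        logp = logdensity_compressed(
            np.array([0.0]), np.array([[1.0, 1.0]]), np.zeros(2), 1.0
        )
        assert np.exp(logp) == pytest.approx(1 / np.sqrt(4 * np.pi), rel=1e-12)

    def test_value_at_mean_is_normalizer(self, rng):
        phi = rng.normal(size=(2, 5))
        s = rng.normal(size=5)
        sigma = 1.3
        cov = sigma**2 * phi @ phi.T
        logp = logdensity_compressed(phi @ s, phi, s, sigma)
        expect = -0.5 * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(cov)))
        assert logp == pytest.approx(expect, abs=1e-10)

    def test_rank_deficient_gram_is_conditioned(self):
        # duplicated compress rows make phi phi^T singular; the ridge keeps
        # the density finite and well-defined
        phi = np.array([[1.0, 0.0], [1.0, 0.0]])
        logp = logdensity_compressed(np.zeros(2), phi, np.zeros(2), 1.0)
        assert np.isfinite(logp)


class TestBayesRisk:
    def test_identical_densities_give_half(self):
        p = lambda x: norm.pdf(x, 0.0, 1.0)
        assert bayes_risk_two_class(0.5, 0.5, p, p, 0.7) == pytest.approx(0.5, abs=1e-9)

    def test_gaussian_pair_matches_closed_form(self):
        br = bayes_risk_two_class(
            0.5, 0.5, lambda x: norm.pdf(x, 0, 1), lambda x: norm.pdf(x, 2, 1), 1.0
        )
        assert br == pytest.approx(norm.cdf(-1), abs=1e-6)
        assert gaussian_bayes_risk(0.5, 0.5, 0, 1, 2, 1, 1.0) == pytest.approx(
            norm.cdf(-1), abs=1e-12
        )

    def test_boundary_at_infinity_leaves_only_p2(self):
        br = bayes_risk_two_class(
            0.3, 0.7, lambda x: norm.pdf(x, 0, 1), lambda x: norm.pdf(x, 2, 1), 40.0
        )
        assert br == pytest.approx(0.7, abs=1e-9)

    def test_bad_priors_rejected(self):
        p = lambda x: norm.pdf(x)
        with pytest.raises(ValueError):
            bayes_risk_two_class(0.6, 0.6, p, p, 0.0)
        with pytest.raises(ValueError):
            gaussian_bayes_risk(0.2, 0.3, 0, 1, 1, 1, 0.0)


class TestUtility:
    def test_identity_is_kronecker(self):
        u = estimate_utility(np.zeros((3, 2)), np.eye(2), 1.0, np.full(3, 1 / 3),
                             method="identity")
        np.testing.assert_array_equal(u, np.eye(3))

    def test_pairwise_br_coincident_means(self):
        mu = np.zeros((2, 2))
        u = estimate_utility(mu, np.eye(2), 1.0, np.full(2, 0.5), method="pairwise_br")
        assert u[0, 1] == pytest.approx(0.5)
        assert u[1, 0] == pytest.approx(0.5)
        np.testing.assert_array_equal(np.diag(u), 1.0)

    def test_mc_far_separated_is_identity(self):
        mu = 10.0 * np.eye(3)[:, :2] * 3  # gaps of ~30 sigma
        u = estimate_utility(
            mu, np.eye(2), 1.0, np.full(3, 1 / 3),
            method="mc_multiclass", n_mc=10_000, seed=7,
        )
        assert np.abs(u - np.eye(3)).max() <= 0.01

    def test_mc_requires_seed_and_samples(self):
        mu = np.zeros((2, 2))
        with pytest.raises(ValueError):
            estimate_utility(mu, np.eye(2), 1.0, np.full(2, 0.5),
                             method="mc_multiclass", seed=None)
        with pytest.raises(ValueError):
            estimate_utility(mu, np.eye(2), 1.0, np.full(2, 0.5),
                             method="mc_multiclass", n_mc=10, seed=1)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_utility(np.zeros((2, 2)), np.eye(2), 1.0, np.full(2, 0.5),
                             method="nope")

    def test_column_diagonal_dominance_when_separated(self):
        mu = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        u = estimate_utility(mu, np.eye(2), 1.0, np.full(3, 1 / 3),
                             method="mc_multiclass", n_mc=5000, seed=3)
        for j in range(3):
            off = np.delete(u[:, j], j)
            assert u[j, j] >= off.max()


class TestClassify:
    def test_dominant_likelihood_wins(self):
        model = toy_model([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]], sigma=0.5)
        assert classify(np.array([5.0, 5.0]), model) == 1

    def test_tie_breaks_to_lowest_index(self):
        model = toy_model([[1.0, 1.0], [1.0, 1.0]])
        assert classify(np.array([3.0, -2.0]), model) == 0

    def test_identity_utility_equals_maximum_likelihood(self, rng):
        # with the Kronecker utility and equal priors the expected-utility
        # argmax collapses to the likelihood argmax
        for _ in range(100):
            n_classes = int(rng.integers(2, 5))
            m, n = int(rng.integers(1, 4)), int(rng.integers(4, 8))
            phi = rng.normal(size=(m, n))
            means = rng.normal(size=(n_classes, n))
            model = toy_model(
                means,
                sigma=float(rng.uniform(0.3, 2.0)),
                phi=CompressMatrix(sp.csr_matrix(phi)),
            )
            y = rng.normal(size=m)
            ml = int(np.argmax(model.log_likelihoods(y)))
            assert classify(y, model) == ml

    def test_prior_monotonicity_on_grid(self):
        # raising a class prior can only grow its decision region
        means = [[-1.0], [1.0]]
        grid = np.linspace(-4, 4, 161)
        region_sizes = []
        for p0 in (0.3, 0.5, 0.7):
            model = toy_model(means, priors=[p0, 1 - p0])
            decided0 = [classify(np.array([g]), model) == 0 for g in grid]
            region_sizes.append(sum(decided0))
        assert region_sizes[0] <= region_sizes[1] <= region_sizes[2]

    def test_expected_utilities_are_posterior_for_identity(self):
        model = toy_model([[0.0], [2.0]])
        eu = expected_utilities(np.array([0.5]), model)
        assert eu.sum() == pytest.approx(1.0)
        assert eu[0] > eu[1]


class TestFitPredict:
    def test_separable_training_data_classified_perfectly(self):
        train, _ = separable_dataset()
        model = fit(train, 12)
        pred = predict(model, train.matrix)
        assert accuracy(pred, train.y) == 1.0

    def test_separable_test_data_classified_perfectly(self):
        train, test = separable_dataset(seed=5)
        model = fit(train, 12)
        assert accuracy(predict(model, test.matrix), test.y) == 1.0

    def test_compressed_means_are_projected_means(self):
        train, _ = separable_dataset(seed=2)
        model = fit(train, 10)
        for k in range(model.n_classes):
            np.testing.assert_allclose(
                model.class_means_compressed[k],
                project(model.phi, model.class_means[k]),
                atol=1e-10,
            )

    def test_m_larger_than_samples_rejected(self):
        train, _ = separable_dataset()
        with pytest.raises(ValueError, match="m <= c"):
            fit(train, train.matrix.n_samples + 1)

    def test_class_with_single_sample_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(5, 5)),
                          [0, 0, 0, 0, 1])
        with pytest.raises(InputError):
            fit(ds, 2)

    def test_refit_same_seed_is_bit_identical(self, tmp_path):
        train, _ = separable_dataset(seed=3)
        for d in ("a", "b"):
            model = fit(train, 8, utility_method="mc_multiclass", n_mc=1000, seed=42)
            save_model(model, tmp_path / d)
        for name in ("model.json", "phi.tsv", "row_stats.tsv", "selected.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_model_round_trip_predicts_identically(self, tmp_path):
        train, test = separable_dataset(seed=4)
        model = fit(train, 8)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(
            predict(model, test.matrix), predict(back, test.matrix)
        )
        np.testing.assert_allclose(
            back.phi.toarray(), model.phi.toarray(), atol=0
        )

    def test_predict_single_sample(self):
        train, test = separable_dataset(seed=6)
        model = fit(train, 8)
        single = test.matrix.subset_samples([test.matrix.sample_ids[0]])
        assert predict(model, single).shape == (1,)

    def test_column_permutation_permutes_predictions(self, rng):
        train, test = separable_dataset(seed=7)
        model = fit(train, 8)
        base = predict(model, test.matrix)
        perm = rng.permutation(test.matrix.n_samples)
        shuffled = test.matrix.subset_samples(
            [test.matrix.sample_ids[i] for i in perm]
        )
        np.testing.assert_array_equal(predict(model, shuffled), base[perm])

    def test_probe_mismatch_rejected(self):
        train, test = separable_dataset(seed=8)
        model = fit(train, 8)
        wrong = make_dataset(test.matrix.values, test.y, probe_prefix="other")
        with pytest.raises(AlignmentError):
            predict(model, wrong.matrix)

    def test_noncompressed_detector_on_selected_features(self):
        train, test = separable_dataset(seed=9)
        model = fit(train, 12, detector="noncompressed")
        assert model.phi.solver == "selector"
        assert accuracy(predict(model, test.matrix), test.y) == 1.0

    def test_noncompressed_all_features(self):
        train, _ = separable_dataset(seed=10)
        model = fit(train, detector="noncompressed")
        assert model.m == train.matrix.n_probes


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_all_wrong(self):
        assert accuracy([1, 1], [2, 3]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            accuracy([], [])
        with pytest.raises(ValueError):
            accuracy([1], [1, 2])

    def test_percent_formatting(self):
        assert format_percent(50 / 55) == "90.9"


class TestStability:
    def test_separable_data_is_perfectly_stable(self):
        cfg = SyntheticConfig(
            n_classes=3, block_sizes=(50,), per_class_train=6, per_class_test=4,
            informative_per_class_per_block=4, effect_size=200.0,
            noise_sigma=1e-3, seed=22,
        )
        data = generate(cfg)
        full = LabeledDatasetUnion(data)
        res = stability_experiment(full, n_repeats=3, per_class_train=6,
                                   seed=5, m=9)
        assert res.mean_accuracy == 1.0
        assert res.std_accuracy == 0.0

    def test_single_repeat_and_determinism(self):
        cfg = SyntheticConfig(
            n_classes=2, block_sizes=(40,), per_class_train=6, per_class_test=4,
            informative_per_class_per_block=3, effect_size=4.0, seed=23,
        )
        data = generate(cfg)
        full = LabeledDatasetUnion(data)
        one = stability_experiment(full, n_repeats=1, per_class_train=6, seed=9, m=6)
        assert len(one.accuracies) == 1
        assert one.std_accuracy == 0.0
        again = stability_experiment(full, n_repeats=1, per_class_train=6, seed=9, m=6)
        assert one.accuracies == again.accuracies

    def test_insufficient_class_size_rejected(self):
        ds = make_dataset(np.random.default_rng(1).normal(size=(4, 6)),
                          [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            stability_experiment(ds, n_repeats=2, per_class_train=3, seed=0, m=2)


def LabeledDatasetUnion(data):
    """Train and test blocks merged back into one pool of labeled samples."""
    from mcsd.data_io import ExpressionMatrix, LabeledDataset

    tr, te = data.train_blocks[0], data.test_blocks[0]
    values = np.hstack([tr.matrix.values, te.matrix.values])
    sample_ids = tr.matrix.sample_ids + te.matrix.sample_ids
    matrix = ExpressionMatrix(tr.matrix.probe_ids, sample_ids, values)
    labels = dict(tr.labels) | dict(te.labels)
    return LabeledDataset(matrix, labels, tr.class_names)
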