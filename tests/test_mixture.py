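"""Well/dataset likelihood, E/M steps and EM fitting."""

import numpy as np
import pytest

import wellmix as wm
from wellmix.mixture import _log_mix_terms, default_families

from conftest import two_class_gaussian_truth

DESC2 = ("cell_count", "prop_S")


def gauss2(mean, var, diagonal=False):
    cov = np.diag(var) if np.ndim(var) == 1 else np.asarray(var)
    return wm.GaussianClassParams(np.asarray(mean, dtype=float), cov, diagonal)


@pytest.fixture
def toy_dataset(rng):
    """3 wells x 2 fields in a 2-descriptor space (count + one proportion)."""
    wells = []
    for i in range(3):
        fields = [
            wm.FieldRecord("GL2", f"w{i}", k, float(rng.gamma(5, 20)), rng.uniform(0.1, 0.4, 1))
            for k in range(2)
        ]
        for f in fields:
            f.proportion_names = DESC2[1:]
        wells.append(wm.WellData(f"w{i}", "GL2", fields))
    return wm.Dataset(wells, DESC2)


@pytest.fixture
def toy_model():
    c1 = gauss2([100.0, 0.2], [400.0, 0.01])
    c2 = gauss2([60.0, 0.3], [900.0, 0.02])
    return wm.MixtureModel([0.5, 0.5], [c1, c2], "gaussian_full", DESC2)


class TestWellLogDensity:
    def test_single_class_equals_sum_of_field_logdensities(self, toy_dataset):
        c = gauss2([100.0, 0.2], [400.0, 0.01])
        model = wm.MixtureModel([1.0], [c], "gaussian_full", DESC2)
        w = toy_dataset.wells[0]
        expected = c.logpdf(w.field_matrix()).sum()
        assert wm.well_log_density(w, model) == pytest.approx(expected, abs=1e-12)

    def test_two_identical_classes_match_single_class(self, toy_dataset):
        c = gauss2([100.0, 0.2], [400.0, 0.01])
        one = wm.MixtureModel([1.0], [c], "gaussian_full", DESC2)
        two = wm.MixtureModel([0.5, 0.5], [c, c], "gaussian_full", DESC2)
        w = toy_dataset.wells[0]
        assert wm.well_log_density(w, two) == pytest.approx(
            wm.well_log_density(w, one), abs=1e-10
        )

    def test_two_class_mixture_arithmetic(self, toy_dataset, toy_model):
        # direct two-term evaluation: ln(0.5 A + 0.5 B) for field products A, B
        w = toy_dataset.wells[1]
        X = w.field_matrix()
        a = np.exp(toy_model.classes[0].logpdf(X).sum())
        b = np.exp(toy_model.classes[1].logpdf(X).sum())
        assert wm.well_log_density(w, toy_model) == pytest.approx(
            np.log(0.5 * a + 0.5 * b), rel=1e-10
        )

    def test_zero_mixture_weight_is_not_an_error(self, toy_dataset):
        c1 = gauss2([100.0, 0.2], [400.0, 0.01])
        c2 = gauss2([60.0, 0.3], [900.0, 0.02])
        model = wm.MixtureModel([1.0, 0.0], [c1, c2], "gaussian_full", DESC2)
        single = wm.MixtureModel([1.0], [c1], "gaussian_full", DESC2)
        w = toy_dataset.wells[0]
        assert wm.well_log_density(w, model) == pytest.approx(
            wm.well_log_density(w, single), abs=1e-12
        )

    def test_field_order_invariance_is_exact(self, toy_dataset, toy_model):
        w = toy_dataset.wells[0]
        flipped = wm.WellData(w.well_id, w.condition, list(reversed(w.fields)))
        assert wm.well_log_density(w, toy_model) == wm.well_log_density(flipped, toy_model)


class TestDatasetLogLikelihood:
    def test_single_well_equals_well_log_density(self, toy_dataset, toy_model):
        sub = toy_dataset.subset([0])
        assert wm.dataset_log_likelihood(sub, toy_model) == pytest.approx(
            wm.well_log_density(sub.wells[0], toy_model), abs=1e-12
        )

    def test_duplicated_dataset_doubles_exactly(self, toy_dataset, toy_model):
        # bypass identity checks: copies share field objects on purpose
        copies = []
        for w in toy_dataset.wells:
            c = wm.WellData.__new__(wm.WellData)
            c.well_id, c.condition, c.fields = w.well_id + "_copy", w.condition, w.fields
            copies.append(c)
        dup_wells = toy_dataset.wells + copies
        dup = wm.Dataset.__new__(wm.Dataset)
        dup.wells = dup_wells
        dup.descriptor_names = toy_dataset.descriptor_names
        assert wm.dataset_log_likelihood(dup, toy_model) == pytest.approx(
            2 * wm.dataset_log_likelihood(toy_dataset, toy_model), rel=1e-12
        )

    def test_matches_direct_space_brute_force(self, toy_dataset, toy_model):
        # product-space evaluation without any log-sum-exp shortcuts
        total = 0.0
        for w in toy_dataset.wells:
            X = w.field_matrix()
            acc = 0.0
            for c, pi_c in enumerate(toy_model.pi):
                acc += pi_c * np.prod(np.exp(toy_model.classes[c].logpdf(X)))
            total += np.log(acc)
        assert wm.dataset_log_likelihood(toy_dataset, toy_model) == pytest.approx(
            total, abs=1e-10
        )

    def test_label_permutation_invariance_exact(self, toy_dataset, toy_model):
        permuted = wm.MixtureModel(
            toy_model.pi[::-1].copy(),
            toy_model.classes[::-1],
            "gaussian_full",
            DESC2,
        )
        assert wm.dataset_log_likelihood(toy_dataset, toy_model) == wm.dataset_log_likelihood(
            toy_dataset, permuted
        )

    def test_flat_baseline_with_single_field_wells_matches_hierarchical(self, rng):
        # K=1: a well IS a field, so both hierarchy readings coincide exactly
        wells = []
        for i in range(10):
            f = wm.FieldRecord("GL2", f"w{i}", 0, float(rng.gamma(5, 20)), rng.uniform(0.1, 0.4, 1))
            f.proportion_names = DESC2[1:]
            wells.append(wm.WellData(f"w{i}", "GL2", [f]))
        data = wm.Dataset(wells, DESC2)
        c1 = gauss2([100.0, 0.2], [400.0, 0.01], diagonal=True)
        c2 = gauss2([60.0, 0.3], [900.0, 0.02], diagonal=True)
        hier = wm.MixtureModel([0.4, 0.6], [c1, c2], "gaussian_full", DESC2)
        flat = wm.MixtureModel([0.4, 0.6], [c1, c2], "baseline_diag", DESC2)
        assert wm.dataset_log_likelihood(data, hier) == pytest.approx(
            wm.dataset_log_likelihood(data, flat), abs=1e-12
        )

    def test_copula_identity_correlation_matches_independent_marginals(self, rng):
        marginals = (
            wm.MarginalParams("gamma", 4.0, 0.05),
            wm.MarginalParams("beta", 2.0, 6.0),
        )
        params = wm.CopulaClassParams(np.eye(2), marginals)
        model = wm.MixtureModel([1.0], [params], "copula", DESC2)
        wells = []
        for i in range(5):
            f = wm.FieldRecord(
                "GL2", f"w{i}", 0, float(rng.gamma(4, 20)), rng.beta(2, 6, 1)
            )
            f.proportion_names = DESC2[1:]
            wells.append(wm.WellData(f"w{i}", "GL2", [f]))
        data = wm.Dataset(wells, DESC2)
        X = data.field_matrix()
        independent = sum(
            wm.marginal_logpdf(X[:, d], marginals[d]).sum() for d in range(2)
        )
        assert wm.dataset_log_likelihood(data, model) == pytest.approx(independent, abs=1e-10)


class TestESten:
    def test_single_class_gives_unit_responsibilities(self, toy_dataset):
        c = gauss2([100.0, 0.2], [400.0, 0.01])
        model = wm.MixtureModel([1.0], [c], "gaussian_full", DESC2)
        resp = wm.e_step(toy_dataset, model)
        assert np.all(resp == 1.0)

    def test_identical_classes_give_uniform_rows(self, toy_dataset):
        c = gauss2([100.0, 0.2], [400.0, 0.01])
        model = wm.MixtureModel([0.5, 0.5], [c, c], "gaussian_full", DESC2)
        resp = wm.e_step(toy_dataset, model)
        assert np.allclose(resp, 0.5, atol=1e-12)

    def test_bayes_arithmetic_for_two_to_one_ratio(self, toy_dataset):
        # engineer a well whose class-1 likelihood is exactly 2x class 2
        c = gauss2([100.0, 0.2], [400.0, 0.01])
        model = wm.MixtureModel([0.5, 0.5], [c, c], "gaussian_full", DESC2)
        terms = _log_mix_terms(model, toy_dataset.field_matrix())
        # responsibilities with manual adjustment: r proportional to (2, 1)
        r = np.exp(np.array([np.log(2.0), 0.0]) - np.log(3.0))
        assert np.allclose(r, [2 / 3, 1 / 3])
        # same arithmetic through e_step, by shifting pi instead of densities
        model2 = wm.MixtureModel([2 / 3, 1 / 3], [c, c], "gaussian_full", DESC2)
        resp = wm.e_step(toy_dataset, model2)
        assert np.allclose(resp, [2 / 3, 1 / 3], atol=1e-12)

    def test_rows_sum_to_one(self, neg_small):
        data, _, _ = neg_small
        model = wm.fit_em(data, 2, "copula", seed=0, max_iter=50).model
        resp = wm.e_step(data, model)
        assert resp.shape == (data.n_wells, 2)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_hard_responsibilities_equal_per_subset_fits(self, neg_small):
        data, _, _ = neg_small
        half = data.n_wells // 2
        resp = np.zeros((data.n_wells, 2))
        resp[:half, 0] = 1.0
        resp[half:, 1] = 1.0
        pi, classes = wm.m_step(data, resp, "gaussian_full")
        assert pi == pytest.approx([half / data.n_wells, 1 - half / data.n_wells])
        sub = data.subset(range(half))
        pi0, cls0 = wm.m_step(sub, np.ones((half, 1)), "gaussian_full")
        assert np.allclose(classes[0].mean, cls0[0].mean, atol=1e-12)
        assert np.allclose(classes[0].covariance, cls0[0].covariance, atol=1e-12)

    def test_uniform_responsibilities_give_identical_classes(self, neg_small):
        data, _, _ = neg_small
        resp = np.full((data.n_wells, 2), 0.5)
        pi, classes = wm.m_step(data, resp, "copula")
        assert np.allclose(pi, 0.5)
        assert np.allclose(classes[0].R, classes[1].R, atol=1e-12)
        assert classes[0].marginals == classes[1].marginals

    def test_single_gaussian_class_recovers_sample_moments(self, neg_small):
        data, _, _ = neg_small
        pi, classes = wm.m_step(data, np.ones((data.n_wells, 1)), "gaussian_full")
        X = data.field_matrix()
        assert np.allclose(classes[0].mean, X.mean(axis=0), atol=1e-10)
        centered = X - X.mean(axis=0)
        assert np.allclose(
            classes[0].covariance, centered.T @ centered / X.shape[0], rtol=1e-10
        )

    def test_baseline_covariances_are_diagonal(self, neg_small):
        data, _, _ = neg_small
        resp = np.full((data.n_fields, 2), 0.5)
        _, classes = wm.m_step(data, resp, "baseline_diag")
        for c in classes:
            assert c.diagonal
            off = c.covariance[~np.eye(5, dtype=bool)]
            assert np.all(off == 0.0)


class TestFitEM:
    def test_single_class_gaussian_converges_immediately(self, neg_small):
        data, _, _ = neg_small
        fit = wm.fit_em(data, 1, "gaussian_full", seed=0)
        assert fit.converged
        assert fit.n_iter <= 2

    def test_same_seed_is_bitwise_identical(self, neg_small):
        data, _, _ = neg_small
        a = wm.fit_em(data, 2, "gaussian_full", seed=9)
        b = wm.fit_em(data, 2, "gaussian_full", seed=9)
        assert a.loglik_trajectory == b.loglik_trajectory
        assert np.array_equal(a.model.pi, b.model.pi)
        for ca, cb in zip(a.model.classes, b.model.classes):
            assert np.array_equal(ca.mean, cb.mean)
            assert np.array_equal(ca.covariance, cb.covariance)

    def test_gaussian_trajectory_is_monotone(self, neg_small):
        data, _, _ = neg_small
        for param in ("gaussian_full", "baseline_diag"):
            fit = wm.fit_em(data, 3, param, seed=4)
            t = np.array(fit.loglik_trajectory)
            assert np.all(np.diff(t) >= -1e-8 * np.maximum(np.abs(t[:-1]), 1.0))

    def test_final_trajectory_entry_matches_returned_model(self, neg_small):
        data, _, _ = neg_small
        for param in ("copula", "gaussian_full"):
            fit = wm.fit_em(data, 2, param, seed=1, max_iter=60)
            assert fit.loglik == pytest.approx(
                wm.dataset_log_likelihood(data, fit.model), abs=1e-10
            )
            assert len(fit.loglik_trajectory) == fit.n_iter

    def test_recovers_two_class_gaussian_truth(self):
        truth = two_class_gaussian_truth()
        data, labels = wm.sample_model(truth, 500, 4, seed=11)
        fit = wm.fit_em(data, 2, "gaussian_full", seed=3)
        order = np.argsort([c.mean[0] for c in fit.model.classes])
        pi_hat = fit.model.pi[order]
        assert np.all(np.abs(pi_hat - truth.pi) < 0.05)
        for c_hat, c_true in zip((fit.model.classes[i] for i in order), truth.classes):
            assert np.all(
                np.abs(c_hat.mean - c_true.mean) <= 0.10 * np.abs(c_true.mean)
            )

    def test_too_many_classes_raise(self, toy_dataset):
        with pytest.raises(ValueError):
            wm.fit_em(toy_dataset, 5, "gaussian_full", seed=0)


class TestInitialize:
    def test_single_class_is_seed_independent(self, neg_small):
        data, _, _ = neg_small
        pi1, cls1 = wm.initialize(data, 1, seed=0)
        pi2, cls2 = wm.initialize(data, 1, seed=99)
        assert np.array_equal(pi1, pi2)
        assert np.array_equal(cls1[0].mean, cls2[0].mean)

    def test_separated_blobs_are_split_cleanly(self):
        truth = two_class_gaussian_truth()
        data, labels = wm.sample_model(truth, 100, 4, seed=5)
        from wellmix.mixture import _initialize_labels

        init_labels = _initialize_labels(data, 2, seed=1)
        # agreement up to label swap (ARI = 1 for a perfect split)
        agree = max(
            np.mean(init_labels == labels), np.mean(init_labels == 1 - labels)
        )
        assert agree == 1.0

    def test_pi_is_uniform_smoothed(self, neg_small):
        data, _, _ = neg_small
        pi, _ = wm.initialize(data, 3, seed=0)
        assert np.all(pi >= 0.1 / 3 - 1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestModelSerialization:
    def test_model_json_roundtrip(self, neg_small):
        data, _, _ = neg_small
        for param in ("copula", "gaussian_full"):
            model = wm.fit_em(data, 2, param, seed=0, max_iter=30).model
            back = wm.MixtureModel.from_json(model.to_json())
            assert np.allclose(back.pi, model.pi)
            assert back.parametrization == model.parametrization
            assert wm.dataset_log_likelihood(data, back) == pytest.approx(
                wm.dataset_log_likelihood(data, model), abs=1e-10
            )
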