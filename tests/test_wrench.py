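import numpy as np
import pytest

from wrenchnorm import (
    CountMatrix,
    GroupDesign,
    compositional_factors,
    compute_ratios,
    compute_reference,
    estimate_regularized_ratios,
    estimate_variance_components,
    fit_hurdle,
    normalization_factors,
    normalize_counts,
    wrench,
)
from wrenchnorm.wrench import (
    EPS_PI,
    HurdleFit,
    RatioTable,
    RegularizedRatios,
    VarianceComponents,
    WrenchNormalizer,
)


def _ratio_table(r, pooled, groups=("g",), labels=None):
    r = np.asarray(r, dtype=float)
    pooled = np.asarray(pooled, dtype=float)
    labels = np.asarray(labels if labels is not None else ["g"] * r.shape[1])
    return RatioTable(r=r, pooled_r=pooled, mask=np.ones(r.shape[0], bool),
                      group_labels=labels, groups=list(groups))


class TestReference:
    def test_mean_of_per_sample_proportions(self, two_sample_counts):
        q0 = compute_reference(two_sample_counts).q0
        assert np.allclose(q0, [0.25, 0.25, 0.5])

    def test_single_sample_gives_its_proportions(self):
        cm = CountMatrix(np.array([[2, 2], [3, 3], [5, 5]]))
        assert np.allclose(compute_reference(cm).q0, [0.2, 0.3, 0.5])

    def test_identical_samples_give_common_proportions(self, identical_counts):
        q0 = compute_reference(identical_counts).q0
        assert np.allclose(q0, identical_counts.proportions[:, 0])
        assert q0.sum() == pytest.approx(1.0, abs=1e-12)


class TestRatios:
    def test_sample_ratios_hand_example(self, two_sample_counts, single_group_design):
        ref = compute_reference(two_sample_counts)
        rt = compute_ratios(two_sample_counts, single_group_design(two_sample_counts), ref)
        assert np.allclose(rt.r[:, 0], [2.0, 2.0, 0.0])

    def test_sample_matching_reference_has_unit_ratios(self):
        cm = CountMatrix(np.array([[2, 4], [3, 6], [5, 10]]))
        ref = compute_reference(cm)
        rt = compute_ratios(cm, GroupDesign.from_labels(cm.sample_ids, ["g", "g"]), ref)
        assert np.allclose(rt.r, 1.0)

    def test_singleton_group_pooled_equals_sample_ratios(self):
        cm = CountMatrix(np.array([[2, 1], [3, 1], [5, 8]]))
        ref = compute_reference(cm)
        design = GroupDesign.from_labels(cm.sample_ids, ["a", "b"])
        rt = compute_ratios(cm, design, ref)
        assert np.allclose(rt.pooled_r[:, 0], rt.r[:, 0])
        assert np.allclose(rt.pooled_r[:, 1], rt.r[:, 1])

    def test_zero_reference_features_masked(self):
        cm = CountMatrix(np.array([[0, 0], [3, 1], [5, 8]]))
        ref = compute_reference(cm)
        design = GroupDesign.from_labels(cm.sample_ids, ["g", "g"])
        rt = compute_ratios(cm, design, ref)
        assert not rt.mask[0]
        assert np.all(np.isnan(rt.r[0]))


class TestVarianceComponents:
    def test_pooled_ratio_hand_example(self):
        rt = _ratio_table(np.array([[2.0], [2.0], [0.0]]), np.array([[2.0], [2.0], [0.0]]))
        design = GroupDesign.from_labels(["s0"], ["g"])
        vc = estimate_variance_components(rt, design)
        assert vc.zeta0[0] == pytest.approx(4 / 3)
        assert vc.eta2_0[0] == pytest.approx(0.0, abs=1e-12)

    def test_group_matching_reference_is_unit_scale(self):
        rt = _ratio_table(np.ones((4, 2)), np.ones((4, 1)), labels=["g", "g"])
        vc = estimate_variance_components(rt, GroupDesign.from_labels(["a", "b"], ["g", "g"]))
        assert vc.zeta0[0] == pytest.approx(1.0)
        assert vc.eta2_0[0] == pytest.approx(0.0, abs=1e-12)

    def test_eta2_is_population_variance_of_logs(self):
        pooled = np.array([[np.exp(-1.0)], [np.exp(1.0)]])
        rt = _ratio_table(np.tile(pooled, (1, 2)), pooled, labels=["g", "g"])
        vc = estimate_variance_components(rt, GroupDesign.from_labels(["a", "b"], ["g", "g"]))
        assert vc.eta2_0[0] == pytest.approx(1.0)

    def test_group_without_positive_pooled_ratios_errors(self):
        rt = _ratio_table(np.zeros((3, 1)), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="'g'"):
            estimate_variance_components(rt, GroupDesign.from_labels(["s0"], ["g"]))

    def test_single_positive_feature_falls_back_with_warning(self):
        r = np.array([[2.0, 2.0], [0.0, 3.0]])
        pooled = np.array([[2.0, 2.0], [0.0, 3.0]])
        rt = _ratio_table(r, pooled, groups=("g1", "g2"), labels=["g1", "g2"])
        design = GroupDesign.from_labels(["a", "b"], ["g1", "g2"])
        with pytest.warns(UserWarning, match="g1"):
            vc = estimate_variance_components(rt, design)
        assert np.all(vc.eta2_0 >= 0)


class TestHurdle:
    def test_constant_features_clip_without_error(self):
        cm = CountMatrix(np.array([[5, 6, 7, 8], [0, 0, 0, 0], [1, 1, 1, 1]]))
        fit = fit_hurdle(cm)
        assert np.allclose(fit.pi_hat[0], EPS_PI)
        assert np.allclose(fit.pi_hat[1], 1 - EPS_PI)

    def test_equal_depths_reduce_to_empirical_zero_fraction(self):
        # depths equal => slope unidentifiable => intercept-only MLE = 1/4
        cm = CountMatrix(
            np.array([[0, 1, 1, 1], [10, 9, 9, 9]])
        )
        fit = fit_hurdle(cm)
        assert np.allclose(fit.pi_hat[0], 0.25, atol=1e-3)

    def test_pi_increases_for_zeros_at_low_depth(self):
        # feature zero exactly in the shallow samples: fitted zero probability
        # must be higher at low depth than at high depth
        depths = np.array([100, 120, 5000, 6000, 90, 5500])
        target = np.where(depths < 1000, 0, 30)
        filler = depths - target  # sets the column sums to `depths`
        cm = CountMatrix(np.vstack([target, filler]))
        assert np.array_equal(cm.depths, depths)
        fit = fit_hurdle(cm)
        lo, hi = np.argmin(depths), np.argmax(depths)
        assert fit.pi_hat[0, lo] > fit.pi_hat[0, hi]
        assert fit.beta2[0] < 0  # zeros less likely as depth grows


class TestRegularizedRatios:
    def _vc(self, zeta, eta2, sigma2, groups=("g",)):
        return VarianceComponents(np.atleast_1d(zeta), np.atleast_1d(eta2),
                                  np.asarray(sigma2, float), list(groups))

    def test_zero_prior_variance_shrinks_to_group_scale(self):
        r = np.array([[2.0], [0.5], [1.0]])
        rt = _ratio_table(r, r)
        vc = self._vc(1.2, 0.0, [0.1, 0.1, 0.1])
        design = GroupDesign.from_labels(["s0"], ["g"])
        reg = estimate_regularized_ratios(rt, vc, design, pooling="sample")
        assert np.allclose(reg.a_hat, 0.0)
        assert np.allclose(reg.theta_hat[:, 0], vc.zeta0[0] * np.exp(reg.mu_hat[0]))

    def test_noiseless_positives_recover_raw_ratios(self):
        r = np.array([[2.0], [0.5], [4.0]])
        rt = _ratio_table(r, r)
        vc = self._vc(1.0, 1.0, [1e-8] * 3)
        design = GroupDesign.from_labels(["s0"], ["g"])
        reg = estimate_regularized_ratios(rt, vc, design, pooling="sample")
        assert np.allclose(reg.theta_hat[:, 0], r[:, 0], rtol=1e-6)

    def test_single_positive_feature_sample(self):
        r = np.array([[3.0], [0.0], [0.0]])
        rt = _ratio_table(r, r)
        vc = self._vc(1.5, 0.7, [0.2, 0.2, 0.2])
        design = GroupDesign.from_labels(["s0"], ["g"])
        reg = estimate_regularized_ratios(rt, vc, design, pooling="sample")
        assert reg.mu_hat[0] == pytest.approx(np.log(3.0) - np.log(1.5))
        assert np.allclose(reg.a_hat, 0.0)
        assert np.allclose(reg.theta_hat[:, 0], 3.0)

    def test_zero_entries_carry_group_sample_location(self):
        r = np.array([[2.0], [0.0], [1.0]])
        rt = _ratio_table(r, r)
        vc = self._vc(1.0, 0.5, [0.3, 0.3, 0.3])
        design = GroupDesign.from_labels(["s0"], ["g"])
        reg = estimate_regularized_ratios(rt, vc, design, pooling="sample")
        assert reg.a_hat[1, 0] == 0.0
        assert reg.theta_hat[1, 0] == pytest.approx(
            vc.zeta0[0] * np.exp(reg.mu_hat[0])
        )
        assert np.all(reg.theta_hat[:, 0] > 0)

    def test_pooled_mode_shares_location_within_group(self):
        r = np.array([[2.0, 1.0], [0.5, 2.0], [1.0, 1.0]])
        pooled = np.array([[1.5], [1.0], [1.0]])
        rt = _ratio_table(r, pooled, labels=["g", "g"])
        vc = self._vc(1.1, 0.4, [0.2, 0.2, 0.2])
        design = GroupDesign.from_labels(["a", "b"], ["g", "g"])
        reg = estimate_regularized_ratios(rt, vc, design, pooling="pooled")
        assert reg.mu_hat[0] == reg.mu_hat[1]
        assert np.allclose(reg.theta_hat[:, 0], reg.theta_hat[:, 1], equal_nan=True)

    def test_printed_shrinkage_orientation_flips_coefficient(self):
        r = np.array([[2.0], [0.5]])
        rt = _ratio_table(r, r)
        vc = self._vc(1.0, 3.0, [1.0, 1.0])
        design = GroupDesign.from_labels(["s0"], ["g"])
        blup = estimate_regularized_ratios(rt, vc, design, shrinkage="blup", pooling="sample")
        printed = estimate_regularized_ratios(rt, vc, design, shrinkage="printed", pooling="sample")
        # blup keeps eta2/(s2+eta2)=0.75 of residual; printed keeps 0.25
        ratio = printed.a_hat[0, 0] / blup.a_hat[0, 0]
        assert ratio == pytest.approx(1.0 / 3.0)


class TestCompositionalFactors:
    def _setup(self, theta, pi, sigma2, eta2=0.0):
        p = len(theta)
        theta = np.asarray(theta, float)[:, None]
        reg = RegularizedRatios(
            mu_hat=np.zeros(1), a_hat=np.zeros((p, 1)), theta_hat=theta,
            mask=np.ones(p, bool), group_labels=np.array(["g"]), groups=["g"],
        )
        hurdle = HurdleFit(np.asarray(pi, float)[:, None], np.zeros(p), np.zeros(p))
        vc = VarianceComponents(np.array([1.0]), np.array([eta2]),
                                np.asarray(sigma2, float), ["g"])
        return reg, hurdle, vc

    def test_constant_theta_returns_constant(self):
        reg, hurdle, vc = self._setup([2.5, 2.5, 2.5], [0.1, 0.5, 0.9], [0.2, 0.2, 0.2])
        for est in ("W0", "W1", "W2"):
            assert compositional_factors(reg, hurdle, vc, est, debias=False)[0] == pytest.approx(2.5)

    def test_w1_hand_example(self):
        reg, hurdle, vc = self._setup([1.0, 3.0], [1e-9, 0.5], [1e-4, 1e-4])
        w1 = compositional_factors(reg, hurdle, vc, "W1", debias=False)[0]
        assert w1 == pytest.approx(7 / 3, rel=1e-6)

    def test_w0_plain_mean(self):
        reg, hurdle, vc = self._setup([1.0, 3.0], [1e-9, 0.5], [1e-4, 1e-4])
        assert compositional_factors(reg, hurdle, vc, "W0", debias=False)[0] == pytest.approx(2.0)

    def test_w3_inflates_by_inclusion_probability(self):
        reg, hurdle, vc = self._setup([2.0, 2.0], [0.5, 0.5], [0.3, 0.3])
        w3 = compositional_factors(reg, hurdle, vc, "W3", debias=False)[0]
        assert w3 == pytest.approx(4.0)

    def test_debias_divides_by_half_variance_exponential(self):
        reg, hurdle, vc = self._setup([2.0], [0.2], [0.5])
        on = compositional_factors(reg, hurdle, vc, "W0", debias=True)[0]
        off = compositional_factors(reg, hurdle, vc, "W0", debias=False)[0]
        assert on == pytest.approx(off * np.exp(-0.25))

    def test_w2_stays_within_theta_range(self, sparse_sim):
        res = wrench(sparse_sim.counts, sparse_sim.design, estimator="W2", debias=False,
                     centering="none")
        theta = res.diagnostics["regularized"].theta_hat
        lo = np.nanmin(theta, axis=0)
        hi = np.nanmax(theta, axis=0)
        assert np.all(res.ccf >= lo - 1e-12)
        assert np.all(res.ccf <= hi + 1e-12)

    def test_unknown_estimator_rejected(self):
        reg, hurdle, vc = self._setup([1.0], [0.5], [0.1])
        with pytest.raises(ValueError):
            compositional_factors(reg, hurdle, vc, "W9")


class TestNormalizationFactors:
    def test_geometric_centering_hand_example(self):
        res = normalization_factors(np.array([1.0, 1.0]), np.array([100.0, 400.0]))
        assert np.allclose(res.nf, [0.5, 2.0])
        assert np.prod(res.nf) == pytest.approx(1.0)

    def test_no_centering_is_plain_product(self):
        res = normalization_factors(np.array([2.0]), np.array([10.0]), centering="none")
        assert res.nf[0] == pytest.approx(20.0)

    def test_constant_inputs_center_to_one(self):
        res = normalization_factors(np.array([3.0, 3.0]), np.array([7.0, 7.0]))
        assert np.allclose(res.nf, 1.0)
        assert np.allclose(res.ccf, 1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalization_factors(np.array([0.0]), np.array([1.0]))

    def test_normalize_counts_divides_columns(self):
        cm = CountMatrix(np.array([[2, 4], [2, 4]]))
        res = normalization_factors(np.array([1.0, 1.0]), np.array([2.0, 2.0]),
                                    centering="none", sample_ids=list(cm.sample_ids))
        out = normalize_counts(cm, res)
        assert np.allclose(out, cm.counts / res.nf[None, :])
        assert np.all(out[cm.counts == 0] == 0)


class TestPipelineProperties:
    def test_permutation_equivariance(self, sparse_sim):
        cm, design = sparse_sim.counts, sparse_sim.design
        base = wrench(cm, design).ccf
        rng = np.random.default_rng(5)
        fperm = rng.permutation(cm.n_features)
        sperm = rng.permutation(cm.n_samples)
        permuted = CountMatrix(
            cm.counts[np.ix_(fperm, sperm)],
            feature_ids=[cm.feature_ids[i] for i in fperm],
            sample_ids=[cm.sample_ids[j] for j in sperm],
        )
        out = wrench(permuted, design).ccf
        assert np.allclose(out, base[sperm], rtol=1e-10)

    def test_w0_depth_scaling_invariance(self, sparse_sim):
        # scaling a sample's counts leaves its proportions, hence its ratios
        # and regularized ratios, unchanged; with each sample its own group
        # (the sample-wise normalization view) its W0 factor is preserved
        # exactly, since W0 uses no hurdle probabilities
        cm = sparse_sim.counts
        singleton = GroupDesign.from_labels(cm.sample_ids, cm.sample_ids)
        base = wrench(cm, singleton, estimator="W0", centering="none").ccf
        scaled_counts = cm.counts.copy()
        scaled_counts[:, 3] *= 7
        scaled = CountMatrix(scaled_counts, sample_ids=cm.sample_ids)
        out = wrench(scaled, singleton, estimator="W0", centering="none").ccf
        assert out[3] == pytest.approx(base[3], rel=1e-12)

    def test_degenerate_prior_gives_unit_factors(self, identical_counts):
        for est in ("W0", "W1", "W2", "W3"):
            res = wrench(identical_counts, estimator=est)
            assert np.allclose(res.ccf, 1.0, atol=1e-8)

    def test_sklearn_estimator_interface(self, sparse_sim):
        X = sparse_sim.counts.counts.T
        y = sparse_sim.design.labels_for(sparse_sim.counts.sample_ids)
        norm = WrenchNormalizer(estimator="W2").fit(X, y)
        assert norm.ccf_.shape == (X.shape[0],)
        assert np.allclose(np.exp(np.mean(np.log(norm.nf_))), 1.0)
        out = norm.transform(X)
        assert np.allclose(out, X / norm.nf_[:, None])
        params = norm.get_params()
        assert params["estimator"] == "W2"
        clone_params = WrenchNormalizer(**params).get_params()
        assert clone_params == params
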