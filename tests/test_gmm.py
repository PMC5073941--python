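import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gmmkin import parse_network, sample_snapshots
from gmmkin.gmm import (
    EstimationError,
    MomentConditionSpec,
    OptimizerConfig,
    diagnose_weights,
    estimate_F1,
    estimate_F2,
    estimate_parameters,
    gmm_objective,
    sample_moment_vector,
    symmetric_pinv,
    theoretical_moment_vector,
    weight_identity,
)
from gmmkin.ssa import SnapshotDataset


def make_dataset(counts, times=(1.0,), species=("X",)):
    arr = np.asarray(counts, dtype=np.int64)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return SnapshotDataset(times=tuple(times), species=tuple(species), counts=arr)


@pytest.fixture()
def toy_pairs():
    # two observed species, samples (X, Y) = (1, 2) and (3, 4)
    return make_dataset([[1, 2], [3, 4]], species=("X", "Y"))


@pytest.fixture(scope="module")
def birth_net():
    return parse_network(
        "[species]\nX 0\n\n[reactions]\n0 -> X @ c\n\n[parameters]\nc in [0.0, 1.0]\n"
    )


class TestSampleMoments:
    def test_scalar_orders(self):
        ds = make_dataset([[1], [2], [3]])
        spec = MomentConditionSpec(("X",), 2, (1.0,))
        m = sample_moment_vector(ds, spec)[1.0]
        assert m[0] == pytest.approx(2.0)
        assert m[1] == pytest.approx(14 / 3)

    def test_mixed_moment(self, toy_pairs):
        spec = MomentConditionSpec(("X", "Y"), 2, (1.0,))
        m = sample_moment_vector(toy_pairs, spec)[1.0]
        k = spec.indices.index((1, 1))
        assert m[k] == pytest.approx(7.0)  # (1*2 + 3*4)/2

    def test_condition_count(self):
        spec = MomentConditionSpec(("X", "Y"), 2, (1.0, 2.0))
        assert spec.n_conditions_per_time == 5
        assert spec.n_conditions == 10


class TestCovarianceEstimators:
    def test_f2_toy_cross_covariance(self, toy_pairs):
        spec = MomentConditionSpec(("X", "Y"), 2, (1.0,))
        F2 = estimate_F2(toy_pairs, spec)[1.0]
        i_xy = spec.indices.index((1, 1))
        i_x2 = spec.indices.index((2, 0))
        # (1/2)[(2-7)(1-5) + (12-7)(9-5)] = 20
        assert F2[i_xy, i_x2] == pytest.approx(20.0)
        assert F2[i_x2, i_xy] == pytest.approx(20.0)

    def test_f2_constant_samples_zero(self):
        ds = make_dataset([[4], [4], [4]])
        spec = MomentConditionSpec(("X",), 2, (1.0,))
        assert np.allclose(estimate_F2(ds, spec)[1.0], 0.0)

    def test_f2_sample_order_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(30, 2))
        spec = MomentConditionSpec(("X", "Y"), 3, (1.0,))
        a = estimate_F2(make_dataset(counts, species=("X", "Y")), spec)[1.0]
        b = estimate_F2(make_dataset(counts[::-1], species=("X", "Y")), spec)[1.0]
        assert np.allclose(a, b)

    def test_f1_identical_samples_exact_theta_is_zero_and_flagged(self, birth_net):
        # at t=0 the theoretical moments equal the point-mass moments exactly
        ds = make_dataset([[0], [0], [0]], times=(0.0,))
        spec = MomentConditionSpec(("X",), 2, (0.0,))
        F1 = estimate_F1(ds, {"c": 0.3}, spec, birth_net)[0.0]
        assert np.allclose(F1, 0.0)
        _, info = symmetric_pinv(F1)
        assert info["singular"]

    def test_f1_equals_f2_plus_outer_product(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [20.0], ["mRNA"], 500, seed=4)
        spec = MomentConditionSpec(("mRNA",), 3, (20.0,))
        theta_tilde = {"a": 0.25, "b": 0.25, "c": 0.35}
        F1 = estimate_F1(ds, theta_tilde, spec, gene_expression)[20.0]
        F2 = estimate_F2(ds, spec)[20.0]
        g = (
            sample_moment_vector(ds, spec)[20.0]
            - theoretical_moment_vector(gene_expression, theta_tilde, spec)[20.0]
        )
        assert np.allclose(F1, F2 + np.outer(g, g), rtol=1e-12, atol=1e-8)

    def test_f1_brute_force_two_samples(self, birth_net):
        ds = make_dataset([[1], [3]], times=(0.0,))
        spec = MomentConditionSpec(("X",), 2, (0.0,))
        # m(theta) at t=0 is (0, 0) for X(0)=0
        F1 = estimate_F1(ds, {"c": 0.5}, spec, birth_net)[0.0]
        f1 = np.array([1.0, 1.0])
        f2 = np.array([3.0, 9.0])
        expected = (np.outer(f1, f1) + np.outer(f2, f2)) / 2
        assert np.allclose(F1, expected)


class TestObjective:
    def test_zero_cost_vector(self):
        spec = MomentConditionSpec(("X",), 2, (1.0,))
        W = weight_identity(spec)
        assert gmm_objective({1.0: np.zeros(2)}, W) == 0.0

    def test_identity_reduces_to_sum_of_squares(self):
        spec = MomentConditionSpec(("X",), 2, (1.0,))
        W = weight_identity(spec)
        assert gmm_objective({1.0: np.array([1.0, 2.0])}, W) == pytest.approx(5.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gmm_objective({1.0: np.ones(3)}, {1.0: np.eye(2)})

    @settings(max_examples=40, deadline=None)
    @given(
        g=arrays(np.float64, (4,), elements=st.floats(-5, 5)),
        a=arrays(np.float64, (4, 4), elements=st.floats(-2, 2)),
    )
    def test_matches_brute_force_double_sum(self, g, a):
        W = 0.5 * (a + a.T)
        expected = sum(
            g[r] * W[r, s] * g[s] for r in range(4) for s in range(4)
        )
        assert gmm_objective({0.0: g}, {0.0: W}) == pytest.approx(expected, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=5)
        A = rng.normal(size=(5, 5))
        W = A @ A.T
        perm = rng.permutation(5)
        before = gmm_objective({0.0: g}, {0.0: W})
        after = gmm_objective({0.0: g[perm]}, {0.0: W[np.ix_(perm, perm)]})
        assert after == pytest.approx(before)

    def test_identity_weight_dimensions(self):
        spec2 = MomentConditionSpec(("X", "Y"), 2, (1.0,))
        assert weight_identity(spec2).matrices[1.0].shape == (5, 5)
        spec1 = MomentConditionSpec(("X",), 1, (1.0,))
        assert weight_identity(spec1).matrices[1.0].shape == (1, 1)
        spec_t = MomentConditionSpec(("X",), 2, (1.0, 2.0))
        assert set(weight_identity(spec_t).matrices) == {1.0, 2.0}


class TestTheoreticalMoments:
    def test_point_mass_at_t0(self, gene_expression, ge_truth):
        spec = MomentConditionSpec(("mRNA",), 3, (0.0,))
        for engine in ("standard", "hybrid"):
            m = theoretical_moment_vector(gene_expression, ge_truth, spec, engine)[0.0]
            assert m == pytest.approx([10.0, 100.0, 1000.0])

    def test_telegraph_mrna_mean_closed_form(self, gene_expression, ge_truth):
        # mRNA mean = m0 + c * int_0^t p_on(s) ds with p_on from the two-state
        # telegraph process started in the OFF state
        a, b, c = ge_truth["a"], ge_truth["b"], ge_truth["c"]
        t = 37.0
        spec = MomentConditionSpec(("mRNA",), 1, (t,))
        m = theoretical_moment_vector(gene_expression, ge_truth, spec)[t]
        pstat = a / (a + b)
        integral = pstat * t - pstat / (a + b) * (1 - np.exp(-(a + b) * t))
        assert m[0] == pytest.approx(10.0 + c * integral, rel=1e-6)

    def test_engines_agree_on_linear_network(self, gene_expression, ge_truth):
        spec = MomentConditionSpec(("mRNA",), 3, (50.0,))
        m_std = theoretical_moment_vector(gene_expression, ge_truth, spec, "standard")[50.0]
        m_hyb = theoretical_moment_vector(gene_expression, ge_truth, spec, "hybrid")[50.0]
        assert m_hyb == pytest.approx(m_std, rel=1e-6)


class TestEstimation:
    def test_underidentified_rejected(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [10.0], ["mRNA"], 50, seed=1)
        spec = MomentConditionSpec(("mRNA",), 1, (10.0,))
        with pytest.raises(EstimationError, match="under-identified"):
            estimate_parameters(ds, gene_expression, spec, "identity")

    def test_underidentified_override(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [10.0], ["mRNA"], 50, seed=1)
        spec = MomentConditionSpec(("mRNA",), 1, (10.0,))
        res = estimate_parameters(
            ds, gene_expression, spec, "identity",
            config=OptimizerConfig(n_starts=2, maxiter=30),
            allow_underidentified=True,
        )
        assert set(res.theta) == {"a", "b", "c"}

    def test_exactly_identified_zero_objective(self, birth_net):
        # birth process: E[X(t)] = c t; a dataset whose mean is exactly c0*t
        # gives objective 0 at theta0 for any PSD weight
        c0, t = 0.2, 5.0  # mean 1.0
        ds = make_dataset([[0], [2]], times=(t,))
        spec = MomentConditionSpec(("X",), 1, (t,))
        for estimator in ("identity", "demean_diagonal"):
            res = estimate_parameters(
                ds, birth_net, spec, estimator,
                config=OptimizerConfig(n_starts=4, maxiter=80), seed=0,
            )
            assert res.theta["c"] == pytest.approx(c0, abs=1e-4)
            assert res.objective < 1e-12

    def test_result_contract(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [30.0], ["mRNA"], 2000, seed=8)
        spec = MomentConditionSpec(("mRNA",), 3, (30.0,))
        res = estimate_parameters(
            ds, gene_expression, spec, "demean",
            config=OptimizerConfig(n_starts=3, maxiter=80), seed=5,
        )
        for p, v in res.theta.items():
            lo, hi = res.bounds[p]
            assert lo <= v <= hi
        final = res.steps[-1]
        assert final.objective == min(final.candidate_objectives)
        assert res.estimator == "demean"

    def test_two_step_records_both_steps(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [30.0], ["mRNA"], 2000, seed=8)
        spec = MomentConditionSpec(("mRNA",), 3, (30.0,))
        res = estimate_parameters(
            ds, gene_expression, spec, "two_step",
            config=OptimizerConfig(n_starts=2, maxiter=60), seed=5,
        )
        assert len(res.steps) == 2
        assert res.steps[0].weights.method == "identity"
        assert res.steps[1].weights.method == "two_step_F1"

    def test_iterated_runs_extra_steps(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [30.0], ["mRNA"], 2000, seed=8)
        spec = MomentConditionSpec(("mRNA",), 3, (30.0,))
        res = estimate_parameters(
            ds, gene_expression, spec, "iterated",
            config=OptimizerConfig(n_starts=2, maxiter=60, iterated_max_steps=2),
            seed=5,
        )
        assert 2 <= len(res.steps) <= 3

    def test_continuous_update_runs(self, birth_net):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, size=(200, 1))
        ds = make_dataset(counts, times=(5.0,))
        spec = MomentConditionSpec(("X",), 2, (5.0,))
        res = estimate_parameters(
            ds, birth_net, spec, "continuous_update",
            config=OptimizerConfig(n_starts=2, maxiter=40), seed=2,
        )
        assert 0.0 <= res.theta["c"] <= 1.0
        assert res.steps[-1].weights.method == "continuous_update"

    def test_estimation_deterministic_in_seed(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [30.0], ["mRNA"], 1000, seed=8)
        spec = MomentConditionSpec(("mRNA",), 3, (30.0,))
        cfg = OptimizerConfig(n_starts=3, maxiter=60)
        r1 = estimate_parameters(ds, gene_expression, spec, "demean", config=cfg, seed=9)
        r2 = estimate_parameters(ds, gene_expression, spec, "demean", config=cfg, seed=9)
        assert r1.theta == r2.theta

    def test_prescale_is_a_reparametrization(self, gene_expression, ge_truth):
        # scaling each condition by its sample SD only reconditions W; the
        # demean estimate should be essentially unchanged
        ds = sample_snapshots(gene_expression, ge_truth, [30.0], ["mRNA"], 3000, seed=19)
        spec = MomentConditionSpec(("mRNA",), 3, (30.0,))
        base = estimate_parameters(
            ds, gene_expression, spec, "demean",
            config=OptimizerConfig(n_starts=3, maxiter=100), seed=7,
        )
        scaled = estimate_parameters(
            ds, gene_expression, spec, "demean",
            config=OptimizerConfig(n_starts=3, maxiter=100, prescale=True), seed=7,
        )
        for p in base.theta:
            assert scaled.theta[p] == pytest.approx(base.theta[p], abs=0.02)

    def test_sample_moments_unbiased(self, gene_expression, ge_truth):
        # average m_hat over many small datasets matches the exact engine
        t, n_sets, n = 20.0, 200, 100
        spec = MomentConditionSpec(("mRNA",), 2, (t,))
        m_theory = theoretical_moment_vector(gene_expression, ge_truth, spec)[t]
        all_m = []
        for s in range(n_sets):
            ds = sample_snapshots(gene_expression, ge_truth, [t], ["mRNA"], n, seed=5000 + s)
            all_m.append(sample_moment_vector(ds, spec)[t])
        all_m = np.array(all_m)
        mean = all_m.mean(axis=0)
        se = all_m.std(axis=0) / np.sqrt(n_sets)
        assert np.all(np.abs(mean - m_theory) < 3.5 * se)


class TestWeightDiagnostics:
    def test_self_comparison_zero(self):
        W = {1.0: np.array([[2.0, 0.5], [0.5, 1.0]])}
        rep = diagnose_weights(W, W)
        assert rep["max_discrepancy"] == 0.0

    def test_normalization_entry_is_one(self):
        W = {1.0: np.array([[2.0, 0.5], [0.5, 1.0]])}
        V = {1.0: np.array([[4.0, 1.2], [1.2, 2.0]])}
        rep = diagnose_weights(W, V)
        assert rep["normalized_twostep"][1.0][0, 0] == 1.0
        assert rep["normalized_demean"][1.0][0, 0] == 1.0

    def test_gene_expression_weight_sign_pattern(self, gene_expression, ge_truth):
        # mean/second and second/third moment conditions are negatively
        # correlated, so the normalized off-diagonal weights are negative
        ds = sample_snapshots(gene_expression, ge_truth, [100.0], ["mRNA"], 10_000, seed=13)
        spec = MomentConditionSpec(("mRNA",), 3, (100.0,))
        F2 = estimate_F2(ds, spec)
        W_demean, _ = symmetric_pinv(F2[100.0])
        theta_near = {"a": 0.3, "b": 0.2, "c": 0.4}
        F1 = estimate_F1(ds, theta_near, spec, gene_expression)
        W_twostep, _ = symmetric_pinv(F1[100.0])
        rep = diagnose_weights({100.0: W_twostep}, {100.0: W_demean})
        for key in ("normalized_twostep", "normalized_demean"):
            N = rep[key][100.0]
            assert N[0, 0] == 1.0
            assert N[0, 1] < 0  # mean vs second moment
            assert N[1, 2] < 0  # second vs third moment
        assert rep["max_discrepancy"] < 0.05

    def test_weight_matrices_psd(self, gene_expression, ge_truth):
        ds = sample_snapshots(gene_expression, ge_truth, [50.0], ["mRNA"], 2000, seed=17)
        spec = MomentConditionSpec(("mRNA",), 3, (50.0,))
        for F in (estimate_F2(ds, spec)[50.0],):
            W, _ = symmetric_pinv(F)
            evals = np.linalg.eigvalsh(W)
            assert evals.min() > -1e-10
            assert np.allclose(W, W.T, atol=1e-10)
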