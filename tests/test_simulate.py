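import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mcrtsim import (Allocation, GenerativeParams, RngStream, TrialData, TrialDesign,
                     allocate, generate_trial, icc_to_sigma_b2, scenario, true_se_beta1)


class TestIccMapping:
    @pytest.mark.parametrize("icc, expected", [(0.05, 1 / 19), (0.0, 0.0), (0.75, 3.0),
                                               (0.45, 9 / 11), (0.5, 1.0)])
    def test_catalogued_values(self, icc, expected):
        assert icc_to_sigma_b2(icc, 1.0) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("icc", [-0.1, 1.0, 1.5])
    def test_domain_errors(self, icc):
        with pytest.raises(ValueError):
            icc_to_sigma_b2(icc, 1.0)
        with pytest.raises(ValueError):
            icc_to_sigma_b2(0.1, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(icc=st.floats(0.0, 0.97), sigma_e2=st.floats(1e-3, 1e3))
    def test_roundtrip_to_machine_precision(self, icc, sigma_e2):
        sb2 = icc_to_sigma_b2(icc, sigma_e2)
        assert sb2 / (sb2 + sigma_e2) == pytest.approx(icc, abs=1e-12)

    def test_params_derive_and_from_variances(self):
        p = GenerativeParams(0.0, 0.5, 1.0, 0.2)
        assert p.sigma_b2 == pytest.approx(0.25, rel=1e-15)
        q = GenerativeParams.from_variances(1.34, 1.26, 7.0, 1.0)
        assert q.sigma_b2 == 1.0 and q.icc == 0.125


class TestAllocate:
    def test_balanced_exact_within_centre_counts(self):
        design = scenario(1).design
        arm = allocate(design, np.random.default_rng(0))
        per_centre = arm.reshape(45, 4).sum(axis=1)
        assert np.all(per_centre == 2)

    def test_complete_fixed_overall_margin(self):
        design = scenario(4).design
        for s in range(5):
            arm = allocate(design, np.random.default_rng(s))
            assert arm.sum() == 90

    def test_complete_odd_total_margin(self):
        design = TrialDesign((3, 4), Allocation.COMPLETE)
        arm = allocate(design, np.random.default_rng(1))
        assert arm.sum() == 4  # ceil(7/2) treatment

    def test_complete_within_centre_counts_are_hypergeometric(self):
        # small trial: 3 centres of 4, 6 of 12 treated; the count of treated
        # patients in centre 1 must follow Hypergeometric(N=12, K=6, n=4)
        design = TrialDesign((4, 4, 4), Allocation.COMPLETE)
        rng = np.random.default_rng(42)
        n_draws = 4000
        counts = np.array([allocate(design, rng)[:4].sum() for _ in range(n_draws)])
        pmf = stats.hypergeom(12, 6, 4).pmf(np.arange(5))
        freq = np.bincount(counts, minlength=5) / n_draws
        se = np.sqrt(pmf * (1 - pmf) / n_draws)
        assert np.all(np.abs(freq - pmf) < 4 * se + 1e-12)

    def test_permuted_blocks_split_every_block(self):
        design = TrialDesign((4, 8), Allocation.PERMUTED_BLOCK, block_size=2)
        for s in range(10):
            arm = allocate(design, np.random.default_rng(s))
            assert np.all(arm.reshape(-1, 2).sum(axis=1) == 1)

    def test_incomplete_final_block_bounds_imbalance(self):
        design = TrialDesign((5, 7), Allocation.PERMUTED_BLOCK, block_size=4)
        for s in range(50):
            arm = allocate(design, np.random.default_rng(s))
            n_t1, n_t2 = arm[:5].sum(), arm[5:].sum()
            assert abs(2 * n_t1 - 5) <= 2  # |n_t - n_c| <= block_size / 2
            assert abs(2 * n_t2 - 7) <= 2

    @pytest.mark.parametrize("sid", range(1, 7))
    def test_overall_arm_counts_differ_by_at_most_one(self, sid):
        # exact 1:1 margin holds for the balanced and chance-imbalance designs
        design = scenario(sid).design
        arm = allocate(design, np.random.default_rng(7))
        assert abs(int(arm.sum()) - (design.N - int(arm.sum()))) <= 1

    @pytest.mark.parametrize("sid", [7, 8, 9])
    def test_blocked_within_centre_imbalance_bound(self, sid):
        # permuted blocks bound per-centre imbalance by block_size / 2
        design = scenario(sid).design
        arm = allocate(design, np.random.default_rng(7))
        n_t = np.bincount(np.repeat(np.arange(design.J), design.centre_sizes),
                          weights=arm, minlength=design.J)
        imbalance = np.abs(2 * n_t - np.array(design.centre_sizes))
        assert np.all(imbalance <= design.block_size // 2)

    def test_balanced_rejects_odd_centre(self):
        design = TrialDesign((3, 4), Allocation.COMPLETE)  # valid container
        object.__setattr__(design, "allocation", Allocation.BALANCED)
        with pytest.raises(ValueError, match="even"):
            allocate(design, np.random.default_rng(0))


class TestGenerateTrial:
    def test_degenerate_noise_limit(self):
        params = GenerativeParams(beta0=2.0, beta1=0.5, sigma_e2=1e-18, icc=0.0)
        data = generate_trial(scenario(1).design, params, np.random.default_rng(0))
        np.testing.assert_allclose(data.y[data.arm == 0], 2.0, atol=1e-6)
        np.testing.assert_allclose(data.y[data.arm == 1], 2.5, atol=1e-6)

    def test_record_counts_match_design(self):
        spec = scenario(9)
        data = generate_trial(spec.design, spec.params, np.random.default_rng(0))
        assert data.n_patients == 511 and data.n_centres == 46
        counts = np.bincount(data.centre)[1:]
        assert tuple(counts) == spec.design.centre_sizes

    def test_empirical_icc_matches_target(self):
        # one-way ANOVA moment estimator over a large balanced trial
        icc = 0.2
        n_per, J = 10, 2000
        design = TrialDesign((n_per,) * J, Allocation.BALANCED)
        params = GenerativeParams(0.0, 0.0, 1.0, icc)
        data = generate_trial(design, params, np.random.default_rng(5))
        groups = data.y.reshape(J, n_per)
        msb = n_per * groups.mean(axis=1).var(ddof=1)
        msw = groups.var(axis=1, ddof=1).mean()
        icc_hat = (msb - msw) / (msb + (n_per - 1) * msw)
        assert icc_hat == pytest.approx(icc, abs=0.02)

    def test_marginal_variance_scenario_nine(self):
        # Var(Y | arm) = sigma_b^2 + sigma_e^2 = 8
        spec = scenario(9)
        resid = []
        for k in range(60):
            data = generate_trial(spec.design, spec.params, np.random.default_rng(k))
            resid.append(data.y - spec.params.beta1 * data.arm)
        v = np.concatenate(resid).var(ddof=1)
        assert v == pytest.approx(8.0, rel=0.05)

    def test_seed_determinism_and_stream_independence(self):
        spec = scenario(2)
        s1 = RngStream(123, (2, 50000, 0))
        a = generate_trial(spec.design, spec.params.with_icc(0.05), s1)
        b = generate_trial(spec.design, spec.params.with_icc(0.05), RngStream(123, (2, 50000, 0)))
        c = generate_trial(spec.design, spec.params.with_icc(0.05), RngStream(123, (2, 50000, 1)))
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.arm, b.arm)
        assert not np.array_equal(a.y, c.y)


class TestTrueSe:
    def test_single_centre_two_per_arm(self):
        params = GenerativeParams(0.0, 0.5, 1.0, 0.0)
        se = true_se_beta1([1, 1, 1, 1], [1, 1, 0, 0], params)
        assert se == pytest.approx(1.0, rel=1e-12)

    def test_all_one_arm_is_singular(self):
        params = GenerativeParams(0.0, 0.5, 1.0, 0.1)
        with pytest.raises(ValueError, match="singular"):
            true_se_beta1([1, 1, 2, 2], [1, 1, 1, 1], params)

    @pytest.mark.parametrize("icc", [0.0, 0.2, 0.5])
    def test_balanced_reduces_to_two_sample_formula(self, icc):
        design = scenario(2).design
        centre = np.repeat(np.arange(1, 19), 10)
        arm = np.tile([1, 0], 90)
        params = GenerativeParams(0.0, 0.5, 1.0, icc)
        se = true_se_beta1(centre, arm, params)
        assert se == pytest.approx(np.sqrt(1 / 90 + 1 / 90), rel=1e-10)

    def test_matches_dense_matrix_inverse(self):
        # independent oracle: build V explicitly and invert
        rng = np.random.default_rng(3)
        centre = np.repeat([1, 2, 3], [3, 5, 2])
        arm = np.array([1, 0, 1, 0, 0, 1, 1, 0, 1, 0])
        params = GenerativeParams(0.0, 0.5, 2.0, 0.3)
        V = params.sigma_e2 * np.eye(10)
        for cid in (1, 2, 3):
            mask = np.equal(centre, cid)
            V += params.sigma_b2 * np.outer(mask, mask)
        X = np.column_stack([np.ones(10), arm])
        cov = np.linalg.inv(X.T @ np.linalg.inv(V) @ X)
        assert true_se_beta1(centre, arm, params) == pytest.approx(
            np.sqrt(cov[1, 1]), rel=1e-12)


def test_trial_data_csv_roundtrip(tmp_path):
    spec = scenario(2)
    data = generate_trial(spec.design, spec.params.with_icc(0.1), np.random.default_rng(0))
    path = tmp_path / "trial.csv"
    data.to_csv(path)
    assert path.read_text().splitlines()[0] == "centre,arm,y"
    back = TrialData.from_csv(path)
    np.testing.assert_array_equal(back.centre, data.centre)
    np.testing.assert_array_equal(back.arm, data.arm)
    np.testing.assert_allclose(back.y, data.y)


def test_trial_data_validation():
    with pytest.raises(ValueError, match="arm"):
        TrialData(np.array([1, 1]), np.array([0, 2]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="equal length"):
        TrialData(np.array([1]), np.array([0, 1]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="missing"):
        TrialData.from_csv(io.StringIO("a,b\n1,2\n"))
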