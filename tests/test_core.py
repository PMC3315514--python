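"""Unit and property tests for the coreferentiality statistic and its
permutation test."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from coref import (
    DegenerateDataError,
    DimensionError,
    ParameterError,
    ReferenceSet,
    TestPair,
    bystander_control_test,
    coreferentiality_coefficient,
    correlation_profile,
    permutation_test,
    simulate_dataset,
    SimulationSpec,
)


class TestCorrelationProfile:
    def test_self_correlation_gives_all_ones(self):
        x = np.array([0.3, 1.7, -2.0, 0.5, 4.0])
        Y = np.column_stack([x, x, x])
        prof = correlation_profile(x, Y)
        assert np.allclose(prof.r, 1.0)

    def test_perfect_anticorrelation_is_scale_invariant(self):
        x = np.array([1.0, -1, 1, -1, 1])
        Y = np.column_stack([-2.0 * x, x + 0.5, 3.0 * x])
        prof = correlation_profile(x, Y)
        assert prof.r[0] == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self, five_sample_fixture):
        # oracle values from the plain-sum Pearson formula on 5 points
        pair, Y = five_sample_fixture
        prof = correlation_profile(pair.x1, Y)
        assert prof.r == pytest.approx([0.8, -1.0, 0.8], abs=1e-12)

    def test_zero_variance_column_is_named(self):
        x = np.arange(5.0)
        Y = np.column_stack([x, np.full(5, 3.0), x + 1])
        with pytest.raises(DegenerateDataError, match="Y002.*zero variance"):
            correlation_profile(x, Y)

    def test_length_mismatch(self, five_sample_fixture):
        _, Y = five_sample_fixture
        with pytest.raises(DimensionError):
            correlation_profile(np.arange(6.0), Y)


class TestCoefficient:
    def test_identical_vectors_give_unity(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        same = TestPair(x1=pair.x1, x2=pair.x1.copy())
        assert coreferentiality_coefficient(same, Y) == pytest.approx(1.0)

    def test_negation_flips_sign(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        rc = coreferentiality_coefficient(pair, Y)
        flipped = TestPair(x1=pair.x1, x2=-pair.x2)
        assert coreferentiality_coefficient(flipped, Y) == pytest.approx(-rc)

    def test_matches_hand_computed_profile_correlation(self, five_sample_fixture):
        # profiles (0.8, -1.0, 0.8) and (0.7, -0.8, 0.7) are exactly
        # proportional after centering, so their correlation is 1
        pair, Y = five_sample_fixture
        assert coreferentiality_coefficient(pair, Y) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_the_pair(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        swapped = TestPair(x1=pair.x2, x2=pair.x1)
        assert coreferentiality_coefficient(pair, Y) == pytest.approx(
            coreferentiality_coefficient(swapped, Y), abs=1e-12
        )

    def test_constant_profile_is_degenerate(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal(10), rng.standard_normal(10)
        col = rng.standard_normal(10)
        Y = np.column_stack([col, col, col])  # identical columns
        with pytest.raises(DegenerateDataError, match="profile"):
            coreferentiality_coefficient(TestPair(x1=x1, x2=x2), Y)

    def test_too_few_reference_variables(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DimensionError):
            coreferentiality_coefficient(
                TestPair(x1=rng.standard_normal(8), x2=rng.standard_normal(8)),
                rng.standard_normal((8, 2)),
            )

    @settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        col=st.integers(0, 11),
    )
    def test_affine_invariance(self, gaussian_dataset, a, b, col):
        """R_C is invariant to positive affine maps of x1, x2 or any Y column."""
        pair, Y = gaussian_dataset
        rc = coreferentiality_coefficient(pair, Y)
        assert coreferentiality_coefficient(
            TestPair(x1=a * pair.x1 + b, x2=pair.x2), Y
        ) == pytest.approx(rc, abs=1e-9)
        y2 = Y.y.copy()
        y2[:, col] = a * y2[:, col] + b
        assert coreferentiality_coefficient(pair, y2) == pytest.approx(rc, abs=1e-9)


class TestPermutationTest:
    def test_exhaustive_matches_hand_enumeration(self, five_sample_fixture):
        # 120 joint permutations of the 5-sample fixture: 24 reach the
        # observed |R_C| (independent brute-force enumeration)
        pair, Y = five_sample_fixture
        res = permutation_test(pair, Y, exhaustive=True)
        assert res.exhaustive
        assert res.n_perm == 120
        assert res.p_value == pytest.approx(24 / 120)

    def test_monte_carlo_converges_to_exhaustive(self, five_sample_fixture):
        """The MC p at n_perm=10000 agrees with the exact enumeration p
        within 3 binomial standard errors."""
        pair, Y = five_sample_fixture
        exact = permutation_test(pair, Y, exhaustive=True).p_value
        mc = permutation_test(pair, Y, n_perm=10000, seed=5, exhaustive=False).p_value
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(mc - exact) < 3 * se + 1e-4

    def test_auto_mode_enumerates_small_samples(self, five_sample_fixture):
        pair, Y = five_sample_fixture
        assert permutation_test(pair, Y, exhaustive="auto").exhaustive

    def test_specificity_under_pure_noise(self):
        """With x1, x2 and Y all independent noise, the test rejects at
        about the nominal 5% level."""
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            ds = simulate_dataset(
                SimulationSpec(n=50, k=30, delta=0.0, mode="null", seed=i)
            )
            res = permutation_test(ds.pair, ds.Y, n_perm=200, seed=10_000 + i)
            rejections += res.p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_p_value_affine_invariance(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        res = permutation_test(pair, Y, n_perm=300, seed=3)
        shifted = TestPair(x1=2.0 * pair.x1 + 7.0, x2=pair.x2)
        res2 = permutation_test(shifted, Y, n_perm=300, seed=3)
        assert 0.0 < res.p_value <= 1.0
        assert res2.p_value == pytest.approx(res.p_value)
        assert res2.r_c == pytest.approx(res.r_c, abs=1e-12)

    def test_null_mean_defaults_to_pair_correlation(self):
        """With Y independent of the pair, the permutation null of R_C is
        centred on the direct correlation r(x1, x2), not on zero."""
        ds = simulate_dataset(
            SimulationSpec(n=300, k=130, delta=0.0, r_x=0.4, mode="null", seed=7)
        )
        res = permutation_test(ds.pair, ds.Y, n_perm=2000, seed=8)
        assert res.null_mean == pytest.approx(res.r_x1x2, abs=0.05)

    def test_seed_reproducibility(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        a = permutation_test(pair, Y, n_perm=100, seed=42)
        b = permutation_test(pair, Y, n_perm=100, seed=42)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_rc, b.null_rc)

    def test_literal_counting_mode(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        lit = permutation_test(pair, Y, n_perm=500, seed=1, counting="literal")
        cor = permutation_test(pair, Y, n_perm=500, seed=1)
        # literal mode drops the add-one correction, so it is never larger
        assert lit.p_value <= cor.p_value
        assert cor.p_value > 0.0

    def test_spearman_option_is_rank_invariant(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        res = permutation_test(pair, Y, n_perm=200, seed=2, spearman=True)
        # a monotone transform of x1 leaves the rank-based test unchanged
        warped = TestPair(x1=np.exp(pair.x1), x2=pair.x2)
        res2 = permutation_test(warped, Y, n_perm=200, seed=2, spearman=True)
        assert res2.r_c == pytest.approx(res.r_c, abs=1e-12)
        assert res2.p_value == res.p_value

    @pytest.mark.parametrize(
        "kwargs", [{"n_perm": 0}, {"counting": "bogus"}, {"exhaustive": "maybe"}]
    )
    def test_parameter_errors(self, gaussian_dataset, kwargs):
        pair, Y = gaussian_dataset
        with pytest.raises(ParameterError):
            permutation_test(pair, Y, **kwargs)

    def test_exhaustive_refused_for_large_n(self):
        rng = np.random.default_rng(0)
        pair = TestPair(x1=rng.standard_normal(20), x2=rng.standard_normal(20))
        with pytest.raises(ParameterError, match="exhaustive"):
            permutation_test(pair, rng.standard_normal((20, 5)), exhaustive=True)


class TestBystanderControl:
    def test_calibrated_under_its_own_null(self):
        """When x2 really is a pure bystander of x1, the control p is
        approximately uniform: rejection at 0.05 stays near 5%."""
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            ds = simulate_dataset(
                SimulationSpec(n=100, k=40, delta=0.05, r_x=0.3,
                               mode="bystander", seed=i)
            )
            rc = coreferentiality_coefficient(ds.pair, ds.Y)
            bp = bystander_control_test(ds.pair, ds.Y, rc, n_sim=200, seed=50_000 + i)
            rejections += bp < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_detects_genuine_coreferentiality(self):
        """When both variables genuinely drive Y, the observed R_C exceeds
        the bystander expectation in most datasets."""
        ps = []
        for i in range(100):
            ds = simulate_dataset(
                SimulationSpec(n=200, k=130, delta=0.1, r_x=0.2,
                               mode="both_informative", seed=i)
            )
            rc = coreferentiality_coefficient(ds.pair, ds.Y)
            ps.append(bystander_control_test(ds.pair, ds.Y, rc, n_sim=200,
                                             seed=60_000 + i))
        assert np.median(ps) < 0.05

    def test_empty_null_is_an_error(self, gaussian_dataset):
        pair, Y = gaussian_dataset
        with pytest.raises(ParameterError):
            bystander_control_test(pair, Y, 0.5, n_sim=0, seed=0)

    def test_perfectly_correlated_pair_is_degenerate(self, gaussian_dataset):
        _, Y = gaussian_dataset
        x = np.random.default_rng(3).standard_normal(40)
        with pytest.raises(DegenerateDataError):
            bystander_control_test(TestPair(x1=x, x2=2 * x + 1), Y, 0.5,
                                   n_sim=10, seed=0)


class TestValidation:
    def test_minimum_sample_size(self):
        with pytest.raises(DimensionError):
            TestPair(x1=np.array([1.0, 2, 3]), x2=np.array([3.0, 1, 2]))

    def test_missing_values_rejected(self):
        with pytest.raises(DegenerateDataError, match="non-finite"):
            TestPair(x1=np.array([1.0, np.nan, 3, 4]), x2=np.arange(4.0))

    def test_reference_missing_cell_names_coordinates(self):
        y = np.random.default_rng(0).standard_normal((6, 3))
        y[2, 1] = np.inf
        with pytest.raises(DegenerateDataError, match="row 2"):
            ReferenceSet(y=y, labels=("a", "b", "c"))
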