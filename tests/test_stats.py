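"""Permutation, rank-sum/FDR and age-association statistics."""

import numpy as np
import pandas as pd
import pytest

from volent import (
    age_association,
    capacity_group_test,
    capacity_tables,
    network_from_measurements,
    permutation_entropy_test,
    solve_volume_entropy,
    synthetic_timeseries,
)


def small_group(rng, p=8, n=10, shift=0.0):
    X = rng.standard_normal((p, n))
    X[: p // 2] += shift * rng.standard_normal((1, n))  # shared module signal
    return X


class TestPermutationEntropyTest:
    def test_deterministic_under_seed(self, rng):
        A, B = small_group(rng), small_group(rng)
        r1 = permutation_entropy_test(A, B, n_perm=30, seed=5, kernel_k=3)
        r2 = permutation_entropy_test(A, B, n_perm=30, seed=5, kernel_k=3)
        np.testing.assert_array_equal(r1.null_A, r2.null_A)
        assert r1.p_difference == r2.p_difference

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 1"):
            permutation_entropy_test(
                small_group(rng), small_group(rng), n_perm=0
            )

    def test_low_permutation_warning_flag(self, rng):
        with pytest.warns(UserWarning, match="coarse"):
            res = permutation_entropy_test(
                small_group(rng), small_group(rng), n_perm=20, seed=0,
                kernel_k=3,
            )
        assert res.low_permutation_warning

    def test_addone_pvalues_in_unit_interval(self, rng):
        res = permutation_entropy_test(
            small_group(rng), small_group(rng), n_perm=50, seed=1, kernel_k=3
        )
        for p in (res.p_lower_A, res.p_upper_A, res.p_lower_B,
                  res.p_upper_B, res.p_difference):
            assert 1.0 / 51.0 <= p <= 1.0

    def test_detects_less_modular_group(self):
        """Power check.  With fixed kernel widths, a strongly modular
        correlation structure produces heterogeneous distances (short
        within modules, long between), which raises the volume entropy at
        fixed volume; the weakly modular group B therefore lands in the
        lower tail of the permutation null."""
        from volent.kernel import (
            KernelWidths,
            MeasurementMatrix,
            build_network,
            correlation_kernel,
            kernel_distance_matrix,
        )

        def builder(X):
            M = MeasurementMatrix.from_array(X)
            K = correlation_kernel(M, KernelWidths(np.ones(M.p)))
            return build_network(kernel_distance_matrix(K), labels=M.labels)

        A = synthetic_timeseries(
            p=10, n=14, n_modules=2, within_corr=0.7, between_corr=0.1,
            seed=1,
        ).values
        B = synthetic_timeseries(
            p=10, n=14, n_modules=2, within_corr=0.15, between_corr=0.1,
            seed=2,
        ).values
        res = permutation_entropy_test(
            A, B, n_perm=200, seed=3, network_builder=builder
        )
        assert res.observed_B < res.observed_A
        assert res.p_lower_B < 0.05

    def test_type_one_error_calibrated_under_null(self):
        """Exchangeable groups: P(p_diff <= alpha) stays near alpha.

        Nested simulation at reduced n_perm; the acceptance suite repeats
        this at the full 500 permutations.
        """
        rng = np.random.default_rng(7)
        alpha = 0.1
        n_outer = 40
        hits = 0
        for _ in range(n_outer):
            A, B = rng.standard_normal((7, 8)), rng.standard_normal((7, 8))
            res = permutation_entropy_test(
                A, B, n_perm=120, seed=int(rng.integers(2**31 - 1)),
                kernel_k=3,
            )
            hits += res.p_difference <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_outer)
        assert hits / n_outer <= alpha + 2 * se + 1.0 / 121.0


class TestCapacityGroupTest:
    def test_identical_samples_give_p_one(self):
        A = np.tile(np.arange(5.0), (6, 1))
        out = capacity_group_test(A, A.copy())
        assert np.all(out["p"] == 1.0)
        assert not out["significant"].any()

    def test_shifted_node_detected(self):
        """A 3-pooled-SD shift in one node capacity at 19 vs 19 subjects
        survives FDR in nearly every replicate."""
        rng = np.random.default_rng(11)
        detected = 0
        reps = 30
        for _ in range(reps):
            A = rng.standard_normal((19, 12))
            B = rng.standard_normal((19, 12))
            B[:, 4] += 3.0
            out = capacity_group_test(A, B, alpha=0.05)
            detected += bool(out.loc[4, "significant"])
        assert detected >= 0.9 * reps

    def test_bh_qvalues_dominate_raw_p(self, rng):
        A = rng.standard_normal((10, 25))
        B = rng.standard_normal((10, 25))
        out = capacity_group_test(A, B)
        assert np.all(out["q"] >= out["p"] - 1e-15)

    def test_mismatched_features_rejected(self, rng):
        with pytest.raises(ValueError, match="feature counts differ"):
            capacity_group_test(rng.standard_normal((5, 3)),
                                rng.standard_normal((5, 4)))

    def test_dataframe_feature_order_checked(self, rng):
        A = pd.DataFrame(rng.standard_normal((5, 3)), columns=["a", "b", "c"])
        B = pd.DataFrame(rng.standard_normal((5, 3)), columns=["b", "a", "c"])
        with pytest.raises(ValueError, match="orderings"):
            capacity_group_test(A, B)

    def test_all_null_fdr_controlled(self):
        """BH at 0.05 on pure-noise capacity tables: the empirical FDR
        (here = fraction of replicates with any discovery) stays at or
        below nominal plus Monte-Carlo slack."""
        rng = np.random.default_rng(3)
        reps, false_disc = 150, 0
        for _ in range(reps):
            A = rng.standard_normal((12, 20))
            B = rng.standard_normal((12, 20))
            out = capacity_group_test(A, B, alpha=0.05)
            false_disc += bool(out["significant"].any())
        fdr = false_disc / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert fdr <= 0.05 + 2 * se

    def test_flows_from_capacity_pipeline(self):
        """End-to-end: per-subject node capacities from solved kernel
        networks feed the group test without shape mismatches."""
        caps = []
        for seed in range(6):
            X = synthetic_timeseries(p=8, n=30, n_modules=2, seed=seed)
            res = solve_volume_entropy(network_from_measurements(X, k=3))
            caps.append(capacity_tables(res).node_capacity)
        caps = np.array(caps)
        out = capacity_group_test(caps[:3], caps[3:])
        assert len(out) == 8


class TestAgeAssociation:
    def test_noiseless_linear_slope_exact(self):
        ages = np.linspace(22, 71, 38)
        fit = age_association(2.0 * ages, ages, model="linear")
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.p_values["age"] < 1e-10

    def test_quadratic_vertex_at_45(self):
        ages = np.linspace(22, 71, 38)
        fit = age_association((ages - 45.0) ** 2, ages, model="quadratic")
        assert fit.vertex_age == pytest.approx(45.0, abs=1e-8)
        assert fit.curvature > 0  # U-shape

    def test_declining_entropy_detected_in_synthetic_cohort(self):
        """1-SD-per-age-range effect at the cohort size n = 38."""
        rng = np.random.default_rng(123)
        ages = rng.uniform(22, 71, 38)
        # the decline over the full age range equals ~4 noise SDs
        values = -ages / (ages.max() - ages.min()) + rng.standard_normal(38) * 0.25 + 5
        fit = age_association(values, ages, model="linear")
        assert fit.slope < 0
        assert fit.p_values["age"] < 0.005

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            age_association(np.arange(5.0), np.arange(5.0))

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_association(np.arange(12.0), np.full(12, 50.0))
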