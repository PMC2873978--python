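"""Permutation null, ratio-of-proportions FDR, multi-cohort validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewascan.fdr import (NullDistribution, count_validations,
                         estimate_fdr, estimate_validation_fdr,
                         permute_labels, permutation_null,
                         select_significant, validate_multicohort)
from ewascan.screen import AssociationResult


def _res(symbol, cohort, p):
    return AssociationResult(symbol=symbol, env_class="c", cohort_id=cohort,
                             term=symbol, beta=0.1, se=0.1, or_point=1.1,
                             ci_low=0.9, ci_high=1.3, p_value=p, n_obs=100,
                             n_case=10, n_control=90,
                             error=None if np.isfinite(p) else "failed")


class TestPermuteLabels:
    def test_case_count_conserved_every_replicate(self):
        status = np.r_[np.ones(17, dtype=int), np.zeros(83, dtype=int)]
        perms = permute_labels(status, B=25, seed=3)
        assert perms.shape == (25, 100)
        np.testing.assert_array_equal(perms.sum(axis=1), 17)

    def test_same_seed_reproduces_sequence(self):
        status = np.r_[np.ones(10, dtype=int), np.zeros(90, dtype=int)]
        a = permute_labels(status, B=10, seed=11)
        b = permute_labels(status, B=10, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        status = np.r_[np.ones(50, dtype=int), np.zeros(450, dtype=int)]
        a = permute_labels(status, B=1, seed=1)
        b = permute_labels(status, B=1, seed=2)
        assert not np.array_equal(a, b)

    def test_b_below_one_rejected(self):
        with pytest.raises(ValueError):
            permute_labels(np.array([0, 1]), B=0, seed=0)


class TestEstimateFdr:
    def test_defining_ratio(self):
        # null fraction 0.002, observed fraction 0.02 -> FDR 0.10
        null_p = np.r_[np.full(2, 0.01), np.full(998, 0.5)]
        obs_p = np.r_[np.full(2, 0.01), np.full(98, 0.5)]
        est = estimate_fdr(obs_p, null_p, alpha=0.02)
        assert est.fdr == pytest.approx(0.1)

    def test_pooled_counts_arithmetic(self):
        null_p = np.r_[np.zeros(2000), np.ones(198000)]
        obs_p = np.r_[np.zeros(10), np.ones(190)]
        est = estimate_fdr(obs_p, null_p, alpha=0.02)
        assert est.prop_null_significant == pytest.approx(0.01)
        assert est.prop_observed_significant == pytest.approx(0.05)
        assert est.fdr == pytest.approx(0.2)

    def test_no_observed_discoveries_gives_missing(self):
        est = estimate_fdr([0.5, 0.9], [0.001, 0.5], alpha=0.02)
        assert not est.defined

    def test_missing_pvalues_excluded_from_pools(self):
        est = estimate_fdr([0.01, np.nan], [0.01, np.nan, 0.5], alpha=0.02)
        assert est.prop_observed_significant == pytest.approx(1.0)
        assert est.prop_null_significant == pytest.approx(0.5)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr([], [0.5], alpha=0.02)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=5, max_size=50),
           st.integers(0, 40), st.integers(0, 40))
    def test_monotone_in_null_exceedance(self, obs, k1, k2):
        """Enlarging the null exceedance fraction at fixed observed fraction
        never decreases the estimated FDR."""
        lo, hi = sorted((k1, k2))
        null_small = [0.01] * lo + [0.9] * (41 - lo)
        null_large = [0.01] * hi + [0.9] * (41 - hi)
        e_small = estimate_fdr(obs, null_small, alpha=0.02)
        e_large = estimate_fdr(obs, null_large, alpha=0.02)
        if e_small.defined and e_large.defined:
            assert e_large.fdr >= e_small.fdr


class TestSelectSignificant:
    def test_boundary_inclusive(self):
        results = [_res("A", "c1", 0.02), _res("B", "c1", 0.0200001)]
        assert select_significant(results, alpha=0.02) == {"A"}

    def test_missing_p_never_discovers(self):
        assert select_significant([_res("A", "c1", np.nan)], 0.02) == set()

    def test_empty_results_empty_set(self):
        assert select_significant([], 0.02) == set()


class TestValidateMulticohort:
    def test_significant_in_two_of_three_measured_validates(self):
        results = {"c1": [_res("A", "c1", 0.01)],
                   "c2": [_res("A", "c2", 0.015)],
                   "c3": [_res("A", "c3", 0.5)],
                   "c4": []}
        report = validate_multicohort(results, alpha=0.02)
        assert report.validated == ["A"]
        row = report.table.iloc[0]
        assert row["n_measured"] == 3 and row["n_significant"] == 2

    def test_single_cohort_factor_ineligible_even_if_tiny_p(self):
        report = validate_multicohort({"c1": [_res("A", "c1", 0.001)],
                                       "c2": []}, alpha=0.02)
        row = report.table.iloc[0]
        assert not row["eligible"] and not row["validated"]

    def test_one_significant_cohort_is_not_validation(self):
        results = {"c1": [_res("A", "c1", 0.01)],
                   "c2": [_res("A", "c2", 0.03)],
                   "c3": [_res("A", "c3", 0.03)]}
        report = validate_multicohort(results, alpha=0.02)
        row = report.table.iloc[0]
        assert row["eligible"] and not row["validated"]

    def test_registry_overrides_measured_count(self):
        # factor measured in two cohorts but its model failed in one
        results = {"c1": [_res("A", "c1", 0.01)],
                   "c2": [_res("A", "c2", np.nan)]}
        rep = validate_multicohort(results, 0.02,
                                   registry={"A": ["c1", "c2"]})
        assert rep.table.iloc[0]["n_measured"] == 2
        assert rep.table.iloc[0]["eligible"]


class TestValidationFdr:
    def _nulls(self, counts_per_replicate, cohorts=("c1", "c2")):
        """Construct paired null distributions whose per-replicate
        >=2-cohort significance counts are exactly `counts_per_replicate`."""
        B = len(counts_per_replicate)
        n_factors = max(counts_per_replicate) + 1
        syms = [f"F{i}" for i in range(n_factors)]
        nulls = {}
        for cid in cohorts:
            P = np.full((B, n_factors), 0.9)
            for b, c in enumerate(counts_per_replicate):
                P[b, :c] = 0.001
            nulls[cid] = NullDistribution(cohort_id=cid,
                                          p_values=pd.DataFrame(P,
                                                                columns=syms),
                                          B=B, seed=0)
        return nulls

    def _report(self, n_validated):
        table = pd.DataFrame({
            "symbol": [f"V{i}" for i in range(n_validated)],
            "n_measured": 2, "n_significant": 2, "eligible": True,
            "validated": True})
        from ewascan.fdr import ValidationReport
        return ValidationReport(alpha=0.02, table=table)

    def test_ratio_matches_hand_arithmetic(self):
        # mean permuted validation count 0.1 over observed 5 -> 0.02
        nulls = self._nulls([1] + [0] * 9)
        rep = estimate_validation_fdr(nulls, self._report(5))
        assert rep.expected_false_validations == pytest.approx(0.1)
        assert rep.validation_fdr == pytest.approx(0.02)

    def test_zero_permuted_validations_gives_zero_fdr(self):
        rep = estimate_validation_fdr(self._nulls([0, 0, 0]),
                                      self._report(3))
        assert rep.validation_fdr == 0.0

    def test_no_observed_validations_gives_missing(self):
        rep = estimate_validation_fdr(self._nulls([1, 0]), self._report(0))
        assert np.isnan(rep.validation_fdr)

    def test_mismatched_replicate_counts_rejected(self):
        nulls = self._nulls([0, 0])
        nulls["c2"] = dataclasses.replace(
            nulls["c2"], B=5,
            p_values=pd.concat([nulls["c2"].p_values] * 2 + [
                nulls["c2"].p_values.iloc[:1]], ignore_index=True))
        with pytest.raises(ValueError, match="replicate"):
            estimate_validation_fdr(nulls, self._report(1))

    def test_permutation_consistency_with_validate(self):
        """Counting validations on one permuted replicate via the validation
        rule equals the per-replicate count used by the FDR estimator."""
        rng = np.random.default_rng(0)
        syms = [f"F{i}" for i in range(30)]
        p1 = rng.random(30) * 0.06
        p2 = rng.random(30) * 0.06
        per_cohort = {
            "c1": [_res(s, "c1", p) for s, p in zip(syms, p1)],
            "c2": [_res(s, "c2", p) for s, p in zip(syms, p2)],
        }
        rep = validate_multicohort(per_cohort, alpha=0.02)
        direct = count_validations(np.c_[p1, p2], alpha=0.02)
        assert rep.n_validated == direct


class TestPermutationNullIntegration:
    def test_deterministic_and_shared_across_factors(self, lognormal_cohort,
                                                     two_factor_codebook):
        nd1 = permutation_null(lognormal_cohort, two_factor_codebook,
                               ["EXPA", "EXPB"], B=4, seed=5)
        nd2 = permutation_null(lognormal_cohort, two_factor_codebook,
                               ["EXPA", "EXPB"], B=4, seed=5)
        pd.testing.assert_frame_equal(nd1.p_values, nd2.p_values)
        assert nd1.B == 4
        assert list(nd1.p_values.columns) == ["EXPA", "EXPB"]
        assert np.isfinite(nd1.p_values.to_numpy()).all()
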