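"""Normalization, the t-test, and differential-expression calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix
from mirshift.diffexpr import (
    asymmetry_summary,
    call_de,
    fpkm,
    normalize_by_references,
    normalize_total_counts,
    two_sample_t,
)
from mirshift.errors import DataError, ParameterError
from oracles import oracle_fpkm, oracle_t_pvalue, oracle_t_statistic


class TestNormalizeTotalCounts:
    def test_equal_totals_is_identity(self):
        m = make_matrix([[10, 10], [20, 20]])
        out = normalize_total_counts(m)
        assert np.allclose(out.values, m.values)

    def test_scales_to_common_mean(self):
        # totals 1e6 and 2e6 -> common mean 1.5e6; 200 in sample 2 -> 150
        m = make_matrix([[1e6 - 100, 2e6 - 200], [100, 200]])
        out = normalize_total_counts(m)
        assert out.values.iloc[1, 1] == pytest.approx(150.0)
        assert np.allclose(out.values.sum(axis=0), 1.5e6)

    def test_column_sums_equal_on_random_matrices(self, rng):
        for _ in range(20):
            m = make_matrix(rng.uniform(0.1, 100, size=(30, 6)))
            out = normalize_total_counts(m)
            sums = out.values.sum(axis=0).to_numpy()
            assert np.allclose(sums, sums[0])

    def test_idempotent(self, rng):
        m = make_matrix(rng.uniform(0.1, 100, size=(20, 4)))
        once = normalize_total_counts(m)
        twice = normalize_total_counts(once)
        assert np.allclose(once.values, twice.values)

    def test_scale_invariance_of_one_sample(self, rng):
        values = rng.uniform(0.1, 100, size=(20, 4))
        scaled = values.copy()
        scaled[:, 2] *= 7.5
        a = normalize_total_counts(make_matrix(values))
        b = normalize_total_counts(make_matrix(scaled))
        # totals differ, so compare within-sample proportions
        pa = a.values / a.values.sum(axis=0)
        pb = b.values / b.values.sum(axis=0)
        assert np.allclose(pa, pb)

    def test_zero_total_sample_rejected(self):
        m = make_matrix([[0, 10], [0, 20]])
        with pytest.raises(DataError):
            normalize_total_counts(m)


class TestFpkm:
    def test_formula(self):
        m = make_matrix(
            [[100, 100], [1e6 - 100, 1e6 - 100]], lengths=[1000, 5000]
        )
        out = fpkm(m)
        assert out.values.iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count_gives_zero(self):
        m = make_matrix([[0, 0], [10, 10]], lengths=[500, 500])
        assert fpkm(m).values.iloc[0, 0] == 0.0

    def test_missing_lengths_rejected(self):
        with pytest.raises(DataError):
            fpkm(make_matrix([[1, 1], [2, 2]]))

    def test_matches_scalar_loop_oracle(self, rng):
        values = rng.integers(0, 500, size=(15, 4)).astype(float)
        lengths = rng.integers(200, 5000, size=15).astype(float)
        m = make_matrix(values, lengths=lengths)
        out = fpkm(m).values.to_numpy()
        totals = values.sum(axis=0)
        for i in range(15):
            for j in range(4):
                assert out[i, j] == pytest.approx(
                    oracle_fpkm(values[i, j], lengths[i], totals[j])
                )


class TestNormalizeByReferences:
    def test_already_equal_references_is_identity(self):
        m = make_matrix([[100, 100], [7, 20]])
        out = normalize_by_references(m, ["g0"])
        assert np.allclose(out.values, m.values)

    def test_single_reference_scaling(self):
        # ref 100 vs 400 -> grand geometric mean 200; 200 in B -> 100
        m = make_matrix([[100, 400], [50, 200]])
        out = normalize_by_references(m, ["g0"])
        assert out.values.iloc[0, 0] == pytest.approx(200.0)
        assert out.values.iloc[0, 1] == pytest.approx(200.0)
        assert out.values.iloc[1, 1] == pytest.approx(100.0)

    def test_reference_geometric_means_equalized(self, rng):
        values = rng.uniform(10, 1000, size=(20, 6))
        m = make_matrix(values)
        out = normalize_by_references(m, ["g3", "g7"])
        gm = np.exp(np.log(out.values.loc[["g3", "g7"]]).mean(axis=0))
        assert np.allclose(gm, gm.iloc[0])

    def test_missing_reference_rejected(self):
        with pytest.raises(DataError):
            normalize_by_references(make_matrix([[1, 1]]), ["nope"])

    def test_zero_reference_rejected(self):
        with pytest.raises(DataError):
            normalize_by_references(make_matrix([[0, 5], [1, 1]]), ["g0"])


class TestTwoSampleT:
    def test_identical_samples(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_worked_example(self):
        t, p = two_sample_t([1, 2], [3, 4])
        t_oracle, df = oracle_t_statistic([1, 2], [3, 4])
        assert df == 2
        assert t == pytest.approx(-2.828, abs=5e-4)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert p == pytest.approx(oracle_t_pvalue(t_oracle, df), abs=1e-10)

    def test_large_separation_example(self):
        t, _p = two_sample_t([9, 11], [29, 31])
        assert abs(t) == pytest.approx(14.14, abs=5e-3)

    def test_degenerate_zero_variance_unequal_means(self):
        t, p = two_sample_t([5, 5], [7, 7])
        assert t == -np.inf and p == 0.0

    def test_too_few_observations(self):
        with pytest.raises(DataError):
            two_sample_t([1], [2, 3])

    def test_matches_textbook_oracle_on_random_samples(self, rng):
        """1000 random small samples agree with the independent textbook
        implementation to 1e-10 (statistic) and integration oracle (p)."""
        for i in range(1000):
            n1 = int(rng.integers(2, 8))
            n2 = int(rng.integers(2, 8))
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 2, n2)
            t, p = two_sample_t(x, y)
            t_oracle, df = oracle_t_statistic(x, y)
            assert abs(t - t_oracle) < 1e-10
            if i % 100 == 0:  # integration oracle is slow; spot-check p
                assert p == pytest.approx(oracle_t_pvalue(t_oracle, df), abs=1e-8)

    def test_welch_flag(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        t, p = two_sample_t(x, y, equal_var=False)
        ts, ps = stats.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(float(ts)) and p == pytest.approx(float(ps))


class TestCallDe:
    def _matrix(self, sham, tac, **kw):
        arr = np.column_stack([np.asarray(sham).T, np.asarray(tac).T])
        return make_matrix(arr, n_sham=np.asarray(sham).shape[0], **kw)

    def test_fold_change_direction(self):
        m = make_matrix([[10, 10, 30, 30], [500, 500, 500, 500]])
        de = call_de(m, "count", 5.0, 2.0, 0.05, pseudocount=0.0)
        assert de.loc["g0", "fold_change"] == pytest.approx(3.0)
        assert de.loc["g0", "direction"] == "up"

    def test_boundary_fold_change_is_unchanged(self):
        # fold exactly 2.0 at threshold 2.0 -> strict > -> unchanged
        m = make_matrix([[10, 10, 20, 20], [500, 500, 500, 500]])
        de = call_de(m, "count", 5.0, 2.0, 0.05, pseudocount=0.0)
        assert de.loc["g0", "fold_change"] == pytest.approx(2.0)
        assert de.loc["g0", "status"] == "unchanged"

    def test_abundance_filter_marks_filtered(self):
        m = make_matrix([[1, 1, 2, 2], [500, 500, 1500, 1400]])
        de = call_de(m, "count", 100.0, 1.7, 0.05)
        assert de.loc["g0", "status"] == "filtered"
        assert de.loc["g1", "status"] == "up"

    def test_min_filter_mode(self):
        m = make_matrix([[150, 90, 200, 200], [500, 500, 500, 500]])
        mean_de = call_de(m, "count", 100.0, 2.0, 0.05, filter_mode="mean")
        min_de = call_de(m, "count", 100.0, 2.0, 0.05, filter_mode="min")
        assert mean_de.loc["g0", "status"] != "filtered"
        assert min_de.loc["g0", "status"] == "filtered"

    def test_requires_replicates(self):
        m = make_matrix([[1, 2]], n_sham=1)
        with pytest.raises(DataError):
            call_de(m, "count", 1.0, 2.0, 0.05)

    def test_bad_alpha_rejected(self):
        m = make_matrix([[1, 1, 2, 2]])
        with pytest.raises(ParameterError):
            call_de(m, "count", 1.0, 2.0, 1.5)

    def test_p_values_match_two_sample_t(self, rng):
        m = make_matrix(rng.uniform(50, 500, size=(25, 8)))
        de = call_de(m, "count", 1.0, 1.5, 0.05)
        sham_cols = m.samples_of("sham")
        tac_cols = m.samples_of("TAC")
        for g in m.feature_ids:
            _t, p = two_sample_t(
                m.values.loc[g, sham_cols], m.values.loc[g, tac_cols]
            )
            assert de.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)


class TestAsymmetrySummary:
    def test_no_calls(self):
        df = pd.DataFrame({"status": ["unchanged", "filtered"]})
        n_up, n_down, ratio = asymmetry_summary(df)
        assert (n_up, n_down) == (0, 0) and np.isnan(ratio)

    def test_ratio(self):
        df = pd.DataFrame({"status": ["up"] * 3 + ["down"] * 9})
        assert asymmetry_summary(df) == (3, 9, 3.0)

    def test_infinite_ratio(self):
        df = pd.DataFrame({"status": ["down", "down"]})
        assert asymmetry_summary(df)[2] == np.inf
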