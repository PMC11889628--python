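import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readcov import scmatrix
from readcov.exceptions import (
    DegenerateRegionError,
    DesignError,
    ValidationError,
)

# the ten pairwise permutation p values reported for the typical- vs
# poor-reading children comparison of the five-region reading network
PAIRWISE_P = {
    ("IPL", "STG"): 0.005,
    ("IPL", "VWFA_per"): 0.007,
    ("IFG", "VWFA_per"): 0.09,
    ("IPL", "IFG"): 0.11,
    ("IPL", "VWFA_lex"): 0.15,
    ("IFG", "STG"): 0.94,
    ("IFG", "VWFA_lex"): 0.32,
    ("STG", "VWFA_lex"): 0.89,
    ("STG", "VWFA_per"): 0.64,
    ("VWFA_lex", "VWFA_per"): 0.84,
}


def group_frames(n_a=30, n_b=25, n_regions=4, seed=0, corr_a=0.0, corr_b=0.0):
    rng = np.random.default_rng(seed)
    cols = [f"r{i}" for i in range(n_regions)]

    def draw(n, rho):
        c = np.full((n_regions, n_regions), rho)
        np.fill_diagonal(c, 1.0)
        z = rng.standard_normal((n, n_regions)) @ np.linalg.cholesky(c).T
        return pd.DataFrame(z, columns=cols)

    return draw(n_a, corr_a), draw(n_b, corr_b)


class TestResidualize:
    def test_hand_computed_ols(self):
        # volume (1,2,4) on TIV (1,2,3): slope 3/2, residuals (1/6,-1/3,1/6)
        values = pd.DataFrame({"roi": [1.0, 2.0, 4.0]})
        cov = pd.DataFrame({"tiv": [1.0, 2.0, 3.0]})
        resid = scmatrix.residualize(values, cov)
        np.testing.assert_allclose(
            resid["roi"], [1 / 6, -1 / 3, 1 / 6], atol=1e-12
        )

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        tiv = rng.normal(1.4e6, 1e5, 50)
        age = rng.uniform(7, 12, 50)
        values = pd.DataFrame({
            "a": 0.5 + 3e-7 * tiv + rng.normal(0, 0.05, 50),
            "b": 0.6 + 0.01 * age + rng.normal(0, 0.05, 50),
        })
        cov = pd.DataFrame({"tiv": tiv, "age": age})
        resid = scmatrix.residualize(values, cov)
        assert np.abs(resid.mean()).max() < 1e-10
        for col in resid:
            for c in cov:
                dot = np.dot(resid[col] - resid[col].mean(),
                             cov[c] - cov[c].mean())
                denom = np.linalg.norm(resid[col]) * np.linalg.norm(
                    cov[c] - cov[c].mean()
                )
                assert abs(dot) / max(denom, 1e-30) < 1e-10

    def test_volume_proportional_to_tiv_collapses_downstream(self):
        tiv = pd.DataFrame({"tiv": [1.0, 2.0, 3.0, 4.0]})
        values = pd.DataFrame({
            "flat": [2.0, 4.0, 6.0, 8.0],
            "ok": [1.0, 3.0, 2.0, 5.0],
        })
        resid = scmatrix.residualize(values, tiv)
        np.testing.assert_allclose(resid["flat"], 0.0, atol=1e-12)
        with pytest.raises(DegenerateRegionError, match="flat"):
            scmatrix.sc_matrix(resid)

    def test_collinear_covariates_rejected(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 2.5]})
        cov = pd.DataFrame({
            "tiv": [1.0, 2.0, 3.0, 4.0, 5.0],
            "tiv_l": [10.0, 20.0, 30.0, 40.0, 50.0],
        })
        with pytest.raises(DesignError, match="collinear"):
            scmatrix.residualize(values, cov)

    def test_zero_variance_input_region_rejected(self):
        values = pd.DataFrame({"const": [1.0, 1.0, 1.0, 1.0]})
        cov = pd.DataFrame({"tiv": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(DegenerateRegionError, match="const"):
            scmatrix.residualize(values, cov)

    def test_too_few_subjects_rejected(self):
        values = pd.DataFrame({"a": [1.0, 2.0]})
        cov = pd.DataFrame({"tiv": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            scmatrix.residualize(values, cov)


class TestSCMatrix:
    def test_identical_columns_give_unit_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        m = scmatrix.sc_matrix(df, group="g")
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        m = scmatrix.sc_matrix(df)
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 3.0, 2.0, 4.0]})
        m = scmatrix.sc_matrix(df)
        assert m.values[0, 1] == pytest.approx(0.8)

    def test_invariants_on_random_data(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((20, 6)))
        m = scmatrix.sc_matrix(df)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert np.all(np.abs(m.values) <= 1.0)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValidationError):
            scmatrix.sc_matrix(df)


class TestCompareOverall:
    def test_deterministic_under_fixed_seed(self):
        a, b = group_frames(seed=1)
        r1 = scmatrix.compare_sc_overall(a, b, n_perm=200, rng_seed=9)
        r2 = scmatrix.compare_sc_overall(a, b, n_perm=200, rng_seed=9)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null, r2.null)

    def test_label_swap_negates_statistic(self):
        a, b = group_frames(seed=2, corr_a=0.5)
        r_ab = scmatrix.compare_sc_overall(a, b, n_perm=300, rng_seed=5)
        r_ba = scmatrix.compare_sc_overall(b, a, n_perm=300, rng_seed=5)
        assert r_ba.observed == pytest.approx(-r_ab.observed)

    def test_p_bounds(self):
        a, b = group_frames(seed=3, corr_a=0.8, n_a=60, n_b=60)
        r = scmatrix.compare_sc_overall(a, b, n_perm=250, rng_seed=1)
        assert 1.0 / 251 <= r.p <= 1.0

    def test_zero_observed_statistic_gives_p_one(self):
        # identical groups: observed diff is exactly 0, |null| >= 0 always
        a, _ = group_frames(seed=6)
        r = scmatrix.compare_sc_overall(a, a.copy(), n_perm=150, rng_seed=2)
        assert r.observed == 0.0
        assert r.p == 1.0

    def test_strong_difference_detected(self):
        a, b = group_frames(seed=7, corr_a=0.7, corr_b=0.0, n_a=110, n_b=68)
        r = scmatrix.compare_sc_overall(a, b, n_perm=500, rng_seed=3)
        assert r.p <= 0.05
        assert r.observed > 0

    def test_region_mismatch_rejected(self):
        a, b = group_frames(seed=8)
        b.columns = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValidationError, match="mismatch"):
            scmatrix.compare_sc_overall(a, b)

    def test_fisher_z_flag_changes_tag_not_determinism(self):
        a, b = group_frames(seed=9)
        r = scmatrix.compare_sc_overall(a, b, n_perm=150, rng_seed=4,
                                        fisher_z=True)
        assert "fisher_z" in r.statistic
        assert 0 < r.p <= 1


class TestComparePairwise:
    def test_pair_count(self):
        a, b = group_frames(n_regions=5, seed=10)
        out = scmatrix.compare_sc_pairwise(a, b, n_perm=150, rng_seed=0)
        assert len(out) == 10

    def test_identical_groups_zero_differences(self):
        a, _ = group_frames(seed=11)
        out = scmatrix.compare_sc_pairwise(a, a.copy(), n_perm=150, rng_seed=0)
        np.testing.assert_allclose(out["observed"], 0.0, atol=1e-12)

    def test_planted_pair_attains_minimum_p(self):
        rng = np.random.default_rng(12)
        n_a, n_b, R = 110, 68, 5
        corr = np.eye(R)
        corr[0, 1] = corr[1, 0] = 0.7
        a = pd.DataFrame(
            rng.standard_normal((n_a, R)) @ np.linalg.cholesky(corr).T,
            columns=list("abcde"),
        )
        b = pd.DataFrame(rng.standard_normal((n_b, R)), columns=list("abcde"))
        out = scmatrix.compare_sc_pairwise(a, b, n_perm=500, rng_seed=1)
        top = out.iloc[0]
        assert {top["region_i"], top["region_j"]} == {"a", "b"}

    def test_rejections_monotone_in_p(self):
        a, b = group_frames(n_regions=5, seed=13, corr_a=0.6, n_a=80, n_b=80)
        out = scmatrix.compare_sc_pairwise(a, b, n_perm=400, rng_seed=2)
        rejected_p = out.loc[out["rejected"], "p"]
        kept_p = out.loc[~out["rejected"], "p"]
        if len(rejected_p) and len(kept_p):
            assert rejected_p.max() <= kept_p.min()


class TestBHFDR:
    def test_reading_network_pairwise_worked_example(self):
        """Only the IPL-STG and IPL-VWFA_per comparisons survive BH at q=0.05."""
        pairs = list(PAIRWISE_P)
        rejected = scmatrix.bh_fdr([PAIRWISE_P[p] for p in pairs], q=0.05)
        surviving = {pairs[i] for i in np.flatnonzero(rejected)}
        assert surviving == {("IPL", "STG"), ("IPL", "VWFA_per")}

    def test_all_ones_rejects_nothing(self):
        assert not scmatrix.bh_fdr([1.0] * 8).any()

    def test_step_up_rejects_all_when_under_thresholds(self):
        # thresholds at q=0.05, m=4: 0.0125, 0.025, 0.0375, 0.05
        assert scmatrix.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            scmatrix.bh_fdr([0.5, 1.5])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(25):
            p = rng.random(rng.integers(1, 40))
            reject_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(scmatrix.bh_fdr(p, q=0.05), reject_sm)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=30,
        ),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_step_up(self, pvals, q):
        """Against a direct transcription of the step-up definition."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        np.testing.assert_array_equal(scmatrix.bh_fdr(p, q=q), expected)


def test_result_json_roundtrip(tmp_path):
    a, b = group_frames(seed=14)
    r = scmatrix.compare_sc_overall(a, b, n_perm=150, rng_seed=8)
    path = tmp_path / "res.json"
    scmatrix.write_result_json(r, path)
    text1 = path.read_text()
    scmatrix.write_result_json(r, path)
    assert path.read_text() == text1
    assert '"n_perm": 150' in text1
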