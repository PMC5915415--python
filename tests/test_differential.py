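"""Size factors, BH adjustment, the NB Wald test and DE categories."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from apsflow.differential import (
    benjamini_hochberg,
    categorize,
    gene_level_counts,
    size_factors,
    test_de as run_de_test,
)


class TestSizeFactors:
    def test_identical_libraries_get_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 5], "B": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_library_closed_form(self):
        # B = 2A everywhere: geometric-mean reference gives (1/sqrt(2),
        # sqrt(2)), so the factor ratio B/A is exactly 2
        counts = pd.DataFrame({"A": [10, 20, 5, 80], "B": [20, 40, 10, 160]})
        sf = size_factors(counts)
        assert sf["A"] == pytest.approx(1 / math.sqrt(2))
        assert sf["B"] == pytest.approx(math.sqrt(2))

    def test_scaling_one_library_scales_its_factor(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(
            rng.poisson(50, size=(200, 3)) + 1, columns=["A", "B", "C"]
        )
        sf0 = size_factors(base)
        scaled = base.copy()
        scaled["C"] = scaled["C"] * 4
        sf1 = size_factors(scaled)
        # shared geometric-mean reference shifts all factors by 4^(1/3)
        shift = 4.0 ** (1 / 3)
        assert np.allclose(sf1["C"] / sf0["C"], 4.0 / shift, rtol=1e-9)
        assert np.allclose(sf1["A"] / sf0["A"], 1.0 / shift, rtol=1e-9)

    def test_label_equivariance_under_permutation(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(30, size=(100, 4)) + 1, columns=list("ABCD")
        )
        sf = size_factors(counts)
        perm = counts[["C", "A", "D", "B"]]
        sf_perm = size_factors(perm)
        assert np.allclose(sf_perm.to_numpy(), sf[["C", "A", "D", "B"]].to_numpy())

    def test_fallback_when_no_row_is_all_positive(self, caplog):
        counts = pd.DataFrame({"A": [10, 0, 30], "B": [0, 25, 0], "C": [9, 22, 28]})
        with caplog.at_level("WARNING"):
            sf = size_factors(counts)
        assert (sf > 0).all()
        assert "fall back" in caplog.text


class TestBenjaminiHochberg:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_statsmodels_step_up(self, pvals):
        ours = benjamini_hochberg(np.array(pvals))
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_passthrough(self):
        adj = benjamini_hochberg(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1])
        assert not np.isnan(adj[[0, 2]]).any()


class TestTestDe:
    def test_flat_feature_is_ns(self, conditions_2v2):
        counts = pd.DataFrame(
            {"KO_1": [50, 100], "KO_2": [50, 100], "WT_1": [50, 100], "WT_2": [50, 100]}
        )
        res = run_de_test(counts, conditions_2v2)
        assert np.allclose(res.log2fc, 0.0, atol=1e-12)
        assert (res.p_value > 0.9).all()
        assert (res.category == "ns").all()

    def test_all_zero_features_excluded(self, conditions_2v2):
        counts = pd.DataFrame(
            {"KO_1": [0, 10], "KO_2": [0, 12], "WT_1": [0, 11], "WT_2": [0, 9]}
        )
        res = run_de_test(counts, conditions_2v2)
        assert len(res) == 1

    def test_strong_de_feature_categorised_up(self, conditions_2v2, de_count_simulator):
        rng = np.random.default_rng(4)
        counts, true_lfc = de_count_simulator(
            rng, n_features=500, de_fraction=0.1, log2fc=3.0, depth=200.0
        )
        res = run_de_test(counts, conditions_2v2)
        up_truth = counts.index[(true_lfc > 0) & (counts.sum(axis=1) > 0)]
        frac_up = (res.loc[up_truth, "category"] == "up").mean()
        assert frac_up >= 0.9

    def test_log2fc_sign_is_ko_minus_wt(self, conditions_2v2):
        # unit factors: with one feature, median-of-ratios normalisation
        # would absorb the whole effect by construction
        counts = pd.DataFrame(
            {"KO_1": [80], "KO_2": [90], "WT_1": [20], "WT_2": [25]}
        )
        factors = pd.Series(1.0, index=counts.columns)
        res = run_de_test(counts, conditions_2v2, factors=factors)
        assert res.log2fc.iloc[0] > 0

    def test_missing_condition_label_is_an_error(self):
        counts = pd.DataFrame({"KO_1": [1], "MYSTERY": [2]})
        with pytest.raises(KeyError):
            run_de_test(counts, {"KO_1": "KO"})

    def test_single_condition_rejected(self):
        counts = pd.DataFrame({"KO_1": [1], "KO_2": [2]})
        with pytest.raises(ValueError, match="WT"):
            run_de_test(counts, {"KO_1": "KO", "KO_2": "KO"})


class TestCategorize:
    def test_gained_requires_all_wt_zero(self):
        assert categorize(0.01, 5.0, np.array([40, 35]), np.array([0, 0])) == "gained"
        assert categorize(0.01, 5.0, np.array([40, 35]), np.array([0, 1])) == "up"

    def test_lost_requires_all_ko_zero(self):
        assert categorize(0.01, -5.0, np.array([0, 0]), np.array([50, 60])) == "lost"

    def test_up_down_by_fold_change_sign(self):
        assert categorize(0.05, 2.0, np.array([80, 90]), np.array([20, 25])) == "up"
        assert categorize(0.05, -2.0, np.array([20, 25]), np.array([80, 90])) == "down"

    def test_not_significant_is_ns(self):
        assert categorize(0.2, 3.0, np.array([40, 35]), np.array([0, 0])) == "ns"

    def test_zero_fold_change_degenerate_warns(self):
        with pytest.warns(UserWarning, match="zero fold change"):
            assert categorize(0.01, 0.0, np.array([10, 10]), np.array([10, 10])) == "ns"


class TestGeneLevelCounts:
    def _sites(self):
        return pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4"],
                "count_KO_1": [6, 4, 20, 9],
                "count_WT_1": [4, 2, 30, 9],
            }
        )

    def _annotations(self, codes):
        return pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4"],
                "gene_id": ["g1", "g1", "g2", "g3"],
                "class_code": codes,
            }
        )

    def test_sixteen_read_gene_cutoff_boundary(self):
        # g1 totals exactly 16 (10 + 6) and is retained; g3 totals 18
        out = gene_level_counts(
            self._sites(), self._annotations(["c", "i", "e", "p"]), min_reads=16
        )
        assert set(out.index) == {"g1", "g2", "g3"}
        assert out.loc["g1"].sum() == 16
        out15 = gene_level_counts(
            self._sites().assign(count_WT_1=[3, 2, 30, 9]),
            self._annotations(["c", "i", "e", "p"]),
        )
        assert "g1" not in out15.index

    def test_antisense_sites_not_summed_into_host_gene(self):
        out = gene_level_counts(
            self._sites(), self._annotations(["c", "x", "e", "p"]), min_reads=1
        )
        assert out.loc["g1"].sum() == 10  # s2 (class x) excluded

    def test_site_and_gene_level_categories_not_forced_equal(
        self, conditions_2v2, de_count_simulator
    ):
        rng = np.random.default_rng(5)
        counts, _ = de_count_simulator(rng, n_features=300)
        site_res = run_de_test(counts, conditions_2v2)
        # pair consecutive sites into genes
        gene_ids = [f"g{i // 2}" for i in range(len(counts))]
        gene_counts = counts.groupby(gene_ids).sum()
        gene_res = run_de_test(gene_counts, conditions_2v2)
        assert len(gene_res) <= len(site_res)


class TestCalibration:
    def test_fdr_sensitivity_and_lfc_recovery(self, conditions_2v2, de_count_simulator):
        rng = np.random.default_rng(6)
        counts, true_lfc = de_count_simulator(rng)
        res = run_de_test(counts, conditions_2v2)
        kept = counts.sum(axis=1) > 0
        is_de = (true_lfc != 0)[kept]
        sig = (res.category != "ns").to_numpy()
        fdr = (sig & ~is_de).sum() / max(sig.sum(), 1)
        sens = (sig & is_de).sum() / is_de.sum()
        assert fdr <= 0.2
        assert sens >= 0.5
        med = np.median(np.abs(res.log2fc.to_numpy()[is_de]))
        assert abs(med - 2.0) <= 0.3
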