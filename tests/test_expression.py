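"""Normalisation, expression filters, specificity, response and association."""

import numpy as np
import pandas as pd
import pytest

from erv_atlas import expression, simulate


def toy_matrix():
    counts = pd.DataFrame(
        {"s1": [10.0, 10.0], "s2": [20.0, 20.0]}, index=["f1", "f2"]
    )
    lengths = pd.Series({"f1": 1000, "f2": 2000})
    return counts, lengths


class TestNormalize:
    def test_single_feature_tpm_is_1e6(self):
        counts = pd.DataFrame({"s1": [7.0]}, index=["f"])
        tpm = expression.normalize_counts(counts, {"f": 500}, "TPM")
        assert tpm.loc["f", "s1"] == pytest.approx(1e6)

    def test_two_features_length_ratio(self):
        counts, lengths = toy_matrix()
        tpm = expression.normalize_counts(counts, lengths, "TPM")
        assert tpm.loc["f1", "s1"] == pytest.approx(2e6 / 3)
        assert tpm.loc["f2", "s1"] == pytest.approx(1e6 / 3)

    def test_tpm_columns_sum_to_1e6_random(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 8)).astype(float),
            index=[f"f{i}" for i in range(30)],
        )
        lengths = pd.Series(rng.integers(200, 5000, 30), index=counts.index)
        tpm = expression.normalize_counts(counts, lengths, "TPM")
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_fpkm_formula_and_scaling_invariance(self):
        counts, lengths = toy_matrix()
        f = expression.normalize_counts(counts, lengths, "FPKM")
        # count*1e9 / (length * library)
        assert f.loc["f1", "s1"] == pytest.approx(10 * 1e9 / (1000 * 20))
        f2 = expression.normalize_counts(counts * 7, lengths, "FPKM")
        assert np.allclose(f, f2)

    def test_missing_length_raises(self):
        counts, _ = toy_matrix()
        with pytest.raises(KeyError):
            expression.normalize_counts(counts, {"f1": 1000}, "TPM")


class TestExpressedSet:
    def _sheet(self):
        return pd.DataFrame(
            {"sample": ["s1", "s2"], "condition": ["a", "b"], "replicate": [1, 1]}
        )

    def test_threshold_rule(self):
        mat = pd.DataFrame({"s1": [150.0, 50.0], "s2": [10.0, 10.0]}, index=["f1", "f2"])
        sets = expression.expressed_set(mat, self._sheet(), threshold=100)
        assert sets == {"a": {"f1"}, "b": set()}

    def test_zero_threshold_keeps_nonzero(self):
        mat = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 2.0]}, index=["f1", "f2"])
        sets = expression.expressed_set(mat, self._sheet(), threshold=0)
        assert sets == {"a": {"f1"}, "b": {"f2"}}

    def test_unknown_sample_raises(self):
        mat = pd.DataFrame({"sX": [1.0]}, index=["f"])
        with pytest.raises(KeyError):
            expression.expressed_set(mat, self._sheet(), threshold=0)


class TestSpecificityOverlap:
    def test_disjoint_sets_all_specific(self):
        sets = {"a": {"x", "y"}, "b": {"z"}}
        specific, table = expression.specificity_and_overlap(sets)
        assert specific == {"a": {"x", "y"}, "b": {"z"}}

    def test_identical_sets_none_specific(self):
        sets = {"a": {"x"}, "b": {"x"}}
        specific, table = expression.specificity_and_overlap(sets)
        assert specific == {"a": set(), "b": set()}
        row = table[table.conditions == "a+b"].iloc[0]
        assert row.exact_count == 1

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(6)
        universe = [f"f{i}" for i in range(40)]
        sets = {
            c: {f for f in universe if rng.random() < 0.4} for c in ("a", "b", "c")
        }
        specific, table = expression.specificity_and_overlap(sets)
        union = set().union(*sets.values())
        # sum of exact (disjoint) Venn regions reconstructs the union
        assert table.exact_count.sum() == len(union)
        # inclusion-exclusion over intersection counts
        singles = table[table.conditions.str.count("\\+") == 0].intersection_count.sum()
        pairs = table[table.conditions.str.count("\\+") == 1].intersection_count.sum()
        triple = table[table.conditions.str.count("\\+") == 2].intersection_count.sum()
        assert singles - pairs + triple == len(union)

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            expression.specificity_and_overlap({"a": {"x"}})


class TestVirusResponsive:
    def test_no_change_empty(self):
        m = pd.DataFrame({"r1": [10.0], "r2": [12.0]}, index=["f"])
        assert expression.virus_responsive(m, m) == set()

    def test_fourfold_flagged(self):
        ctrl = pd.DataFrame({"r1": [10.0]}, index=["f"])
        inf = pd.DataFrame({"r1": [40.0]}, index=["f"])
        assert expression.virus_responsive(ctrl, inf, min_log2fc=1.0) == {"f"}

    def test_empty_condition_raises(self):
        m = pd.DataFrame({"r1": [1.0]}, index=["f"])
        with pytest.raises(ValueError):
            expression.virus_responsive(m, m.iloc[:, :0])

    def test_simulated_recall_and_fpr(self):
        els = [f"e{i}" for i in range(100)]
        resp = {f"e{i}": 2.0 for i in range(40)}
        design = simulate.ExpressionDesign(
            conditions=("ctrl", "inf"), replicates=3,
            infected_condition="inf", control_condition="ctrl",
            response_map=resp, noise_sigma=0.2, baseline_mean=50, seed=11,
        )
        counts, sheet, _ = simulate.simulate_expression(els, [], {f: 1000 for f in els}, design)
        ctrl_cols = sheet[sheet.condition == "ctrl"]["sample"]
        inf_cols = sheet[sheet.condition == "inf"]["sample"]
        up = expression.virus_responsive(
            counts.loc[els, ctrl_cols], counts.loc[els, inf_cols], min_log2fc=1.0
        )
        tp = len(up & set(resp))
        fp = len(up - set(resp))
        assert tp / len(resp) >= 0.9
        assert fp / (len(els) - len(resp)) <= 0.05


class TestCisNeighbors:
    def test_nearby_gene_distance(self):
        els = {"e": ("chr1", 100_000, 105_000)}
        genes = {"g": ("chr1", 110_000, 112_000)}
        hits = expression.cis_neighbors(els, genes, window=10_000)
        assert len(hits) == 1 and hits[0].distance == 5000

    def test_far_gene_excluded(self):
        els = {"e": ("chr1", 0, 1000)}
        genes = {"g": ("chr1", 16_000, 17_000)}
        assert expression.cis_neighbors(els, genes, window=10_000) == []

    def test_overlap_distance_zero_and_symmetry(self):
        els = {"e": ("chr1", 0, 2000)}
        genes = {"g": ("chr1", 1000, 3000)}
        hits = expression.cis_neighbors(els, genes)
        assert hits[0].distance == 0
        # symmetric in ordering of element/gene intervals
        hits2 = expression.cis_neighbors(
            {"e": genes["g"]}, {"g": els["e"]}
        )
        assert hits2[0].distance == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        els = {
            f"e{i}": ("chr1", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(0, 500_000, 40))
        }
        genes = {
            f"g{i}": ("chr1", int(s), int(s) + 800)
            for i, s in enumerate(rng.integers(0, 500_000, 40))
        }
        hits = {
            (h.element_id, h.gene_id)
            for h in expression.cis_neighbors(els, genes, window=10_000)
        }
        brute = set()
        for e, (ec, es, ee) in els.items():
            for g, (gc_, gs, ge) in genes.items():
                if max(gs - ee, es - ge, 0) <= 10_000:
                    brute.add((e, g))
        assert hits == brute


class TestTransPartners:
    def _frames(self, n=12, seed=3):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        e = pd.DataFrame([z, rng.standard_normal(n)], index=["e0", "e1"])
        g = pd.DataFrame([z * 2 + 5, rng.standard_normal(n)], index=["g0", "g1"])
        e.columns = g.columns = [f"s{i}" for i in range(n)]
        return e, g

    def test_perfect_pair_retained_with_r_one(self):
        e, g = self._frames()
        df = expression.trans_partners(e, g)
        row = df[(df.element_id == "e0") & (df.gene_id == "g0")].iloc[0]
        assert row.R == pytest.approx(1.0)
        assert row.trans

    def test_null_retention_rate_low(self):
        rng = np.random.default_rng(21)
        n = 12
        e = pd.DataFrame(rng.standard_normal((40, n)), index=[f"e{i}" for i in range(40)])
        g = pd.DataFrame(rng.standard_normal((40, n)), index=[f"g{i}" for i in range(40)])
        e.columns = g.columns = [f"s{i}" for i in range(n)]
        df = expression.trans_partners(e, g)
        frac = df.trans.mean()
        # 0.01 nominal + 3 sigma binomial slack
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / len(df))

    def test_sign_symmetry(self):
        e, g = self._frames()
        df1 = expression.trans_partners(e, g)
        df2 = expression.trans_partners(e, -g)
        m1 = df1.set_index(["element_id", "gene_id"])
        m2 = df2.set_index(["element_id", "gene_id"])
        assert np.allclose(m1.R.abs(), m2.R.abs())
        assert (m1.trans == m2.trans).all()

    def test_zero_variance_feature_skipped(self):
        e, g = self._frames()
        e.loc["e1"] = 3.0
        df = expression.trans_partners(e, g)
        assert "e1" not in set(df.element_id)

    def test_too_few_samples_raise(self):
        e, g = self._frames(n=2)
        with pytest.raises(ValueError):
            expression.trans_partners(e, g)

    def test_p_value_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        r, p_ref = stats.pearsonr(x, y)
        assert expression.correlation_pvalue(r, 10) == pytest.approx(p_ref)
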