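import numpy as np
import pandas as pd
import pytest

from pathcrosstalk import (
    CnaCallSet,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    ResamplingParams,
    filter_nonsilent_mutations,
    integrate_candidates,
    resampled_differential_test,
)


def make_expression(values: np.ndarray, n_tumor: int, n_normal: int) -> ExpressionMatrix:
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    sc = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        sample_class=sc,
    )


def spiked_matrix(n_genes=200, n_spiked=10, n_tumor=30, n_normal=18, shift=4.0, seed=5):
    rng = np.random.default_rng(seed)
    vals = rng.normal(8.0, 1.0, size=(n_genes, n_tumor + n_normal))
    vals[:n_spiked, :n_tumor] += shift
    return make_expression(vals, n_tumor, n_normal), [f"g{i}" for i in range(n_spiked)]


class TestResampledTest:
    def test_defaults_are_the_study_conditions(self):
        p = ResamplingParams()
        assert (p.n_resamples, p.subsample_size, p.fdr_cut, p.fc_cut, p.freq_cut) == (
            1000, 18, 0.001, 2.0, 0.10)

    def test_constant_gene_never_called(self):
        vals = np.ones((3, 40))
        vals[1] = np.random.default_rng(0).normal(size=40)  # one noisy gene
        m = make_expression(vals, 22, 18)
        res = resampled_differential_test(m, ResamplingParams(n_resamples=20, seed=1))
        assert res.table.loc["g0", "frequency"] == 0.0
        assert res.table.loc["g0", "direction"] == "none"

    def test_spiked_genes_recovered_and_null_clean(self):
        m, spiked = spiked_matrix()
        res = resampled_differential_test(m, ResamplingParams(n_resamples=50, seed=2))
        t = res.table
        assert (t.loc[spiked, "frequency"] >= 0.9).all()
        assert (t.loc[spiked, "direction"] == "up").all()
        null = t.drop(index=spiked)
        assert null["called"].mean() <= 0.01

    def test_single_resample_matches_naive_oracle(self):
        """One resampling round must agree with a per-gene scipy t-test
        plus statsmodels BH, run on the same tumor subsample."""
        from scipy import stats as sps
        from statsmodels.stats.multitest import multipletests

        m, _ = spiked_matrix(n_genes=80, n_spiked=8, seed=9)
        params = ResamplingParams(n_resamples=1, subsample_size=18, fdr_cut=0.05,
                                  freq_cut=0.5, seed=42)
        res = resampled_differential_test(m, params)

        tumor, normal = m.split_classes()
        idx = np.random.default_rng(42).choice(tumor.shape[1], size=18, replace=False)
        sub = tumor[:, idx]
        pv = np.array([
            sps.ttest_ind(sub[i], normal[i], equal_var=False).pvalue
            for i in range(sub.shape[0])
        ])
        padj = multipletests(pv, method="fdr_bh")[1]
        delta = sub.mean(axis=1) - normal.mean(axis=1)
        sig = (padj < params.fdr_cut) & (np.abs(delta) > np.log2(params.fc_cut))
        assert np.array_equal(res.table["frequency"].to_numpy() > 0, sig)

    def test_seed_determinism(self):
        m, _ = spiked_matrix()
        p = ResamplingParams(n_resamples=15, seed=3)
        a = resampled_differential_test(m, p).table
        b = resampled_differential_test(m, p).table
        pd.testing.assert_frame_equal(a, b)

    def test_raising_freq_cut_never_adds_calls(self):
        m, _ = spiked_matrix()
        lo = resampled_differential_test(m, ResamplingParams(n_resamples=30, freq_cut=0.1, seed=4))
        hi = resampled_differential_test(m, ResamplingParams(n_resamples=30, freq_cut=0.5, seed=4))
        called_lo = set(lo.table.index[lo.table["called"]])
        called_hi = set(hi.table.index[hi.table["called"]])
        assert called_hi <= called_lo

    def test_global_null_calls_below_one_percent(self):
        rng = np.random.default_rng(8)
        m = make_expression(rng.normal(size=(300, 48)), 30, 18)
        res = resampled_differential_test(m, ResamplingParams(n_resamples=30, seed=8))
        assert res.table["called"].mean() < 0.01

    def test_methylation_uses_delta_beta(self):
        rng = np.random.default_rng(3)
        vals = np.clip(rng.normal(0.5, 0.03, size=(50, 48)), 0.01, 0.99)
        vals[:5, :30] = np.clip(vals[:5, :30] + 0.3, 0.01, 0.99)
        samples = [f"T{i}" for i in range(30)] + [f"N{i}" for i in range(18)]
        sc = pd.Series(["tumor"] * 30 + ["normal"] * 18, index=samples)
        m = MethylationMatrix(
            values=pd.DataFrame(vals, index=pd.Index([f"g{i}" for i in range(50)], name="gene"),
                                columns=samples),
            sample_class=sc,
        )
        res = resampled_differential_test(m, ResamplingParams(n_resamples=30, fdr_cut=0.01, seed=3))
        assert res.layer == "methylation"
        called = set(res.table.index[res.table["called"]])
        assert called == {f"g{i}" for i in range(5)}
        assert (res.table.loc[sorted(called), "direction"] == "up").all()

    def test_subsample_larger_than_cohort_is_error(self):
        m, _ = spiked_matrix(n_tumor=10)
        with pytest.raises(ValueError, match="subsample"):
            resampled_differential_test(m, ResamplingParams(subsample_size=18, seed=0))


class TestMutationFilter:
    def test_case_insensitive_silent_rule(self):
        tbl = MutationTable(records=pd.DataFrame(
            [("g1", "s1", "Silent"), ("g1", "s2", "Missense"), ("g2", "s1", "silent")],
            columns=["gene", "sample", "mutation_class"]))
        assert filter_nonsilent_mutations(tbl) == {"g1"}

    def test_all_silent_empty(self):
        tbl = MutationTable(records=pd.DataFrame(
            [("g1", "s1", "silent"), ("g2", "s2", "Silent")],
            columns=["gene", "sample", "mutation_class"]))
        assert filter_nonsilent_mutations(tbl) == set()

    def test_counts_distinct_genes(self):
        tbl = MutationTable(records=pd.DataFrame(
            [("g1", "s1", "missense"), ("g1", "s2", "nonsense"), ("g2", "s1", "silent"),
             ("g3", "s1", "frameshift"), ("g3", "s3", "silent")],
            columns=["gene", "sample", "mutation_class"]))
        assert len(filter_nonsilent_mutations(tbl)) == 2


def call_result(calls: dict):
    """Build a ResampledCallResult-like object from {gene: direction}."""
    from pathcrosstalk.candidate_genes import ResampledCallResult
    genes = sorted(calls)
    tab = pd.DataFrame({
        "frequency": [1.0 if calls[g] else 0.0 for g in genes],
        "direction": [calls[g] or "none" for g in genes],
        "called": [bool(calls[g]) for g in genes],
    }, index=pd.Index(genes, name="gene"))
    return ResampledCallResult(table=tab, layer="expression", params=ResamplingParams())


class TestIntegration:
    def toy(self):
        de = call_result({"g1": "up", "g2": "down", "g3": "up", "g4": "down",
                          "g5": "up", "g6": "up"})
        dm = call_result({"g1": "down", "g2": "up", "g3": None, "g4": None,
                          "g5": None, "g6": None})     # dm up = hypermethylated
        cna = CnaCallSet(calls={"g3": "amplified", "g4": "deleted"})
        return de, dm, cna, {"g5"}

    def test_toy_groups_and_union(self):
        de, dm, cna, mut = self.toy()
        cand = integrate_candidates(de, dm, cna, mut)
        assert cand.genes_in_group("i_meth") == {"g1", "g2"}
        assert cand.genes_in_group("ii_cna") == {"g3", "g4"}
        assert cand.genes_in_group("iii_mut") == {"g5"}
        assert set(cand.candidates) == {"g1", "g2", "g3", "g4", "g5"}

    def test_sign_inconsistent_pair_excluded(self):
        de = call_result({"g1": "up"})
        dm = call_result({"g1": "up"})      # up-expressed AND hypermethylated
        cand = integrate_candidates(de, dm, CnaCallSet(), set())
        assert cand.candidates == []
        # ... but the flags are still recorded
        assert cand.flags.loc["g1", ["over_expr", "hyper_meth"]].all()

    def test_underexpression_with_deletion_is_group_ii(self):
        de = call_result({"g1": "down"})
        dm = call_result({"g1": None})
        cand = integrate_candidates(de, dm, CnaCallSet(calls={"g1": "deleted"}), set())
        assert cand.genes_in_group("ii_cna") == {"g1"}

    def test_order_invariance(self):
        de, dm, cna, mut = self.toy()
        a = integrate_candidates(de, dm, cna, mut)
        de2 = call_result({"g6": "up", "g5": "up", "g4": "down", "g3": "up",
                           "g2": "down", "g1": "up"})
        b = integrate_candidates(de2, dm, cna, mut)
        assert a.candidates == b.candidates
        pd.testing.assert_frame_equal(a.groups, b.groups)

    def test_namespace_mismatch_is_fatal(self):
        de = call_result({"g1": "up"})
        dm = call_result({"h1": "down"})
        with pytest.raises(ValueError, match="namespace"):
            integrate_candidates(de, dm, CnaCallSet(calls={"h2": "deleted"}), {"h3"})
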