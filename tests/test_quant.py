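import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeokit.errors import InputError
from homeokit.quant import (
    CountMatrix,
    bh_fdr,
    de_test,
    estimate_fold,
    filter_expressed,
    fpkm,
    partition_sets,
)
from homeokit.synthetic_data import simulate_rnaseq_counts


def brute_bh(p):
    """Independent BH step-up oracle."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * n / rank_from_top, 1.0)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def make_cm(counts, lengths=None, genotype="G", treatments=None):
    counts = pd.DataFrame(counts)
    if lengths is None:
        lengths = pd.Series(1000.0, index=counts.index)
    if treatments is None:
        treatments = ["pre"] * len(counts.columns)
    meta = pd.DataFrame({
        "genotype": genotype,
        "treatment": treatments,
        "replicate": range(1, len(counts.columns) + 1),
    }, index=counts.columns)
    return CountMatrix(counts=counts, gene_lengths=lengths, meta=meta)


class TestFpkm:
    def test_formula_identity(self):
        cm = make_cm({"s1": [100]}, lengths=pd.Series([2000.0]))
        cm.library_sizes = pd.Series({"s1": 1e6})
        assert fpkm(cm).iloc[0, 0] == pytest.approx(50.0)

    def test_zero_counts(self):
        cm = make_cm({"s1": [0, 5]})
        cm.library_sizes = pd.Series({"s1": 1e6})
        assert fpkm(cm).iloc[0, 0] == 0.0

    def test_matches_elementwise_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(200, 6)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(6)],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=200).astype(float),
                            index=counts.index)
        libs = pd.Series(rng.integers(10**5, 10**7, size=6).astype(float),
                         index=counts.columns)
        cm = make_cm(counts, lengths)
        cm.library_sizes = libs
        mat = fpkm(cm)
        for g in counts.index[::23]:
            for s in counts.columns:
                expect = counts.loc[g, s] * 1e9 / (lengths[g] * libs[s])
                assert mat.loc[g, s] == pytest.approx(expect)

    def test_length_doubling_halves_fpkm(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 3)))
        cm1 = make_cm(counts, pd.Series(1000.0, index=counts.index))
        cm2 = make_cm(counts, pd.Series(2000.0, index=counts.index))
        cm2.library_sizes = cm1.library_sizes
        pd.testing.assert_frame_equal(fpkm(cm1) / 2.0, fpkm(cm2))

    def test_zero_library_size_rejected(self):
        cm = make_cm({"s1": [1]})
        cm.library_sizes = pd.Series({"s1": 0.0})
        with pytest.raises(InputError):
            fpkm(cm)

    def test_library_size_defaults_to_column_sum(self):
        cm = make_cm({"s1": [10, 30], "s2": [5, 5]})
        assert cm.library_sizes["s1"] == 40
        assert cm.library_sizes["s2"] == 10


class TestFilterExpressed:
    def test_kept_if_one_treatment_passes(self):
        mat = pd.DataFrame(
            [[5, 5, 5, 0, 0, 0]], index=["g1"],
            columns=["p1", "p2", "p3", "q1", "q2", "q3"],
        )
        groups = {s: s[0] for s in mat.columns}
        assert list(filter_expressed(mat, groups, 5.0)) == ["g1"]

    def test_dropped_if_no_treatment_has_all_replicates(self):
        mat = pd.DataFrame(
            [[5, 5, 4.9, 5, 5, 4.9]], index=["g1"],
            columns=["p1", "p2", "p3", "q1", "q2", "q3"],
        )
        groups = {s: s[0] for s in mat.columns}
        assert len(filter_expressed(mat, groups, 5.0)) == 0

    def test_missing_group_label_rejected(self):
        mat = pd.DataFrame([[1.0]], index=["g1"], columns=["s1"])
        with pytest.raises(InputError):
            filter_expressed(mat, {}, 5.0)

    def test_matches_set_comprehension_oracle(self, rng):
        mat = pd.DataFrame(
            rng.uniform(0, 10, size=(100, 6)),
            index=[f"g{i}" for i in range(100)],
            columns=["p1", "p2", "p3", "q1", "q2", "q3"],
        )
        groups = {s: s[0] for s in mat.columns}
        expect = {
            g for g in mat.index
            if any(
                all(mat.loc[g, s] >= 5.0 for s in mat.columns if groups[s] == grp)
                for grp in set(groups.values())
            )
        }
        assert set(filter_expressed(mat, groups, 5.0)) == expect


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(InputError):
            bh_fdr([-0.1])

    def test_fdr_dominates_p(self, rng):
        p = rng.uniform(size=500)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_matches_brute_force_on_1000_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_fdr(p), brute_bh(p), atol=1e-12)


def random_de(rng, genes, frac_sig=0.3):
    n = len(genes)
    return pd.DataFrame({
        "log2fc": rng.normal(0, 2, size=n),
        "pvalue": rng.uniform(size=n),
        "fdr": np.where(rng.uniform(size=n) < frac_sig,
                        rng.uniform(0, 0.05, size=n),
                        rng.uniform(0.05, 1.0, size=n)),
    }, index=genes)


class TestPartitionSets:
    def _toy(self, fc_a, fc_b):
        genes = ["g1", "g2", "g3"]
        de_a = pd.DataFrame({
            "log2fc": fc_a, "pvalue": [0.001, 0.001, 0.5],
            "fdr": [0.01, 0.01, 0.9],
        }, index=genes)
        de_b = pd.DataFrame({
            "log2fc": fc_b, "pvalue": [0.5, 0.001, 0.001],
            "fdr": [0.9, 0.01, 0.01],
        }, index=genes)
        idx = pd.Index(genes)
        return de_a, de_b, idx

    def test_simple_set_algebra(self):
        de_a, de_b, idx = self._toy([2.0, 2.0, 0.1], [0.1, 2.0, 2.0])
        s = partition_sets(de_a, de_b, idx, idx)
        assert s.per_genotype["A"].n_unique == 1
        assert s.per_genotype["B"].n_unique == 1
        assert s.n_common == 1
        assert s.n_opposite == 0
        assert s.n_common_up == 1

    def test_opposite_direction(self):
        de_a, de_b, idx = self._toy([2.0, 2.0, 0.1], [0.1, -2.0, 2.0])
        s = partition_sets(de_a, de_b, idx, idx)
        assert s.n_opposite == 1
        assert s.n_common_up == 0 and s.n_common_down == 0

    def test_random_tables_match_enumeration_oracle(self, rng):
        genes = [f"g{i}" for i in range(500)]
        de_a, de_b = random_de(rng, genes), random_de(rng, genes)
        expr_a = pd.Index(rng.choice(genes, size=400, replace=False))
        expr_b = pd.Index(rng.choice(genes, size=400, replace=False))
        s = partition_sets(de_a, de_b, expr_a, expr_b, fdr_cut=0.05, fold_cut=2.0)

        sig_a = {g for g in genes if g in expr_a and de_a.loc[g, "fdr"] <= 0.05}
        sig_b = {g for g in genes if g in expr_b and de_b.loc[g, "fdr"] <= 0.05}
        common = sig_a & sig_b
        assert s.per_genotype["A"].n_significant == len(sig_a)
        assert s.per_genotype["B"].n_significant == len(sig_b)
        assert s.n_common == len(common)
        assert s.per_genotype["A"].n_unique == len(sig_a - common)
        assert s.per_genotype["B"].n_unique == len(sig_b - common)
        up_a = {g for g in sig_a if de_a.loc[g, "log2fc"] >= 1.0}
        assert s.per_genotype["A"].n_up2x == len(up_a)
        opp = {g for g in common
               if np.sign(de_a.loc[g, "log2fc"]) != np.sign(de_b.loc[g, "log2fc"])}
        assert s.n_opposite == len(opp)

    def test_reconciliation_invariants(self, rng):
        for trial in range(10):
            genes = [f"g{i}" for i in range(200)]
            de_a, de_b = random_de(rng, genes), random_de(rng, genes)
            idx = pd.Index(genes)
            s = partition_sets(de_a, de_b, idx, idx)
            union = (
                s.per_genotype["A"].n_unique
                + s.per_genotype["B"].n_unique
                + s.n_common
            )
            sig_a = set(de_a.index[de_a["fdr"] <= 0.05])
            sig_b = set(de_b.index[de_b["fdr"] <= 0.05])
            assert union == len(sig_a | sig_b)
            assert s.n_common == s.n_common_up + s.n_common_down + s.n_opposite

    def test_to_frame_shape(self, rng):
        genes = [f"g{i}" for i in range(50)]
        s = partition_sets(
            random_de(rng, genes), random_de(rng, genes),
            pd.Index(genes), pd.Index(genes), genotypes=("CO46", "Joelle"),
        )
        frame = s.to_frame()
        assert list(frame.columns) == ["CO46", "Joelle"]
        assert "common_opposite" in frame.index


class TestEstimateFold:
    def test_sixteen_fold(self):
        mat = pd.DataFrame(
            [[32, 32, 32, 2, 2, 2]], index=["flc20"],
            columns=["w1", "w2", "w3", "s1", "s2", "s3"],
        )
        est = estimate_fold(mat, "flc20", ["w1", "w2", "w3"], ["s1", "s2", "s3"])
        assert est.ratio == pytest.approx(16.0)

    def test_equal_means(self):
        mat = pd.DataFrame([[3, 3]], index=["g"], columns=["a", "b"])
        assert estimate_fold(mat, "g", ["a"], ["b"]).ratio == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        mat = pd.DataFrame([[3, 0]], index=["g"], columns=["a", "b"])
        est = estimate_fold(mat, "g", ["a"], ["b"])
        assert est.infinite and est.ratio == float("inf")

    def test_unknown_gene_rejected(self):
        mat = pd.DataFrame([[3, 3]], index=["g"], columns=["a", "b"])
        with pytest.raises(InputError):
            estimate_fold(mat, "nope", ["a"], ["b"])

    def test_recovery_from_simulated_counts(self):
        """Programmed 16x fold recovered within 20% at NB dispersion 0.1,
        3 replicates (fixed seed)."""
        genes = pd.Index([f"g{i}" for i in range(20)])
        lengths = pd.Series(2000.0, index=genes)
        baseline = pd.Series(30.0, index=genes)
        fold = pd.DataFrame(1.0, index=genes, columns=[
            "winter:pre", "winter:post", "summer:pre", "summer:post"
        ])
        fold.loc["g0", "winter:pre"] = 16.0
        cm = simulate_rnaseq_counts(
            lengths, baseline, fold, ["winter", "summer"], ["pre", "post"],
            n_replicates=3, library_size=1e6, dispersion=0.1, rng=12345,
        )
        mat = fpkm(cm)
        est = estimate_fold(
            mat, "g0",
            cm.samples_where(genotype="winter", treatment="pre"),
            cm.samples_where(genotype="summer", treatment="pre"),
        )
        assert est.ratio == pytest.approx(16.0, rel=0.2)


class TestDeTestStandIn:
    def test_null_gene_not_significant_en_masse(self):
        genes = pd.Index([f"g{i}" for i in range(200)])
        lengths = pd.Series(1500.0, index=genes)
        baseline = pd.Series(20.0, index=genes)
        fold = pd.DataFrame(1.0, index=genes,
                            columns=["G:pre", "G:post"])
        cm = simulate_rnaseq_counts(
            lengths, baseline, fold, ["G"], ["pre", "post"],
            n_replicates=3, library_size=1e6, dispersion=0.05, rng=7,
        )
        de = de_test(cm, "G", "pre", "post", dispersion=0.05)
        assert (de["fdr"] <= 0.05).mean() < 0.05
        assert de["log2fc"].abs().mean() < 0.5

    def test_strong_effect_detected(self):
        genes = pd.Index([f"g{i}" for i in range(100)])
        lengths = pd.Series(1500.0, index=genes)
        baseline = pd.Series(50.0, index=genes)
        fold = pd.DataFrame(1.0, index=genes, columns=["G:pre", "G:post"])
        fold.loc["g0", "G:post"] = 20.0
        cm = simulate_rnaseq_counts(
            lengths, baseline, fold, ["G"], ["pre", "post"],
            n_replicates=3, library_size=1e6, dispersion=0.05, rng=8,
        )
        de = de_test(cm, "G", "pre", "post", dispersion=0.05)
        assert de.loc["g0", "fdr"] <= 0.05
        assert de.loc["g0", "log2fc"] > 3.0

    def test_fdr_column_is_bh_of_pvalues(self):
        genes = pd.Index([f"g{i}" for i in range(50)])
        lengths = pd.Series(1500.0, index=genes)
        baseline = pd.Series(20.0, index=genes)
        fold = pd.DataFrame(1.0, index=genes, columns=["G:pre", "G:post"])
        cm = simulate_rnaseq_counts(
            lengths, baseline, fold, ["G"], ["pre", "post"],
            n_replicates=3, library_size=1e6, dispersion=0.1, rng=9,
        )
        de = de_test(cm, "G", "pre", "post")
        np.testing.assert_allclose(de["fdr"], brute_bh(de["pvalue"]), atol=1e-12)


class TestCountMatrixValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            make_cm({"s1": [-1]})

    def test_missing_metadata_rejected(self):
        counts = pd.DataFrame({"s1": [1]})
        meta = pd.DataFrame({"genotype": [], "treatment": [], "replicate": []})
        with pytest.raises(InputError):
            CountMatrix(counts=counts, gene_lengths=pd.Series([100.0]), meta=meta)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(InputError):
            make_cm({"s1": [1]}, lengths=pd.Series([0.0]))
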