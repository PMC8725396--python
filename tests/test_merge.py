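"""Hit filtering, isoform collapsing, inner join, TMM, cpm filter and QC."""

import numpy as np
import pandas as pd
import pytest

from petalmorph.merge import (
    collapse_isoforms,
    cpm,
    cpm_and_filter,
    filter_hits,
    inner_join_species,
    qc_sample_similarity,
    tmm_factors,
    tmm_normalize,
)


def hit_frame(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


class TestFilterHits:
    def test_single_hit_below_threshold_retained(self):
        m = filter_hits(hit_frame([("i1", "gA", 1e-5, 100.0)]))
        assert m == {"i1": "gA"}

    def test_hit_above_threshold_discarded(self):
        m = filter_hits(hit_frame([("i1", "gA", 5e-3, 100.0)]), e_threshold=1e-3)
        assert m == {}

    def test_boundary_evalue_retained(self):
        m = filter_hits(hit_frame([("i1", "gA", 1e-3, 100.0)]), e_threshold=1e-3)
        assert m == {"i1": "gA"}

    def test_best_bitscore_wins(self):
        m = filter_hits(hit_frame([("i1", "gA", 1e-5, 100.0),
                                   ("i1", "gB", 1e-4, 120.0)]))
        assert m == {"i1": "gB"}

    def test_bitscore_tie_broken_by_evalue_then_gene(self):
        m = filter_hits(hit_frame([("i1", "gB", 1e-6, 100.0),
                                   ("i1", "gA", 1e-4, 100.0)]))
        assert m == {"i1": "gB"}
        m = filter_hits(hit_frame([("i1", "gB", 1e-6, 100.0),
                                   ("i1", "gA", 1e-6, 100.0)]))
        assert m == {"i1": "gA"}

    def test_all_hits_mode_keeps_multiple_genes(self):
        m = filter_hits(hit_frame([("i1", "gA", 1e-5, 100.0),
                                   ("i1", "gB", 1e-4, 90.0)]), best_hit_only=False)
        assert sorted(m["i1"]) == ["gA", "gB"]


class TestCollapse:
    def test_summing_example(self):
        counts = pd.DataFrame([[3, 7], [5, 0]], index=["i1", "i2"], columns=["s1", "s2"])
        out = collapse_isoforms(counts, {"i1": "g", "i2": "g"})
        assert out.loc["g"].tolist() == [8, 7]

    def test_unmapped_isoform_absent(self):
        counts = pd.DataFrame([[3], [5]], index=["i1", "i2"], columns=["s1"])
        out = collapse_isoforms(counts, {"i1": "g"})
        assert out.to_numpy().sum() == 3

    def test_count_conservation_when_fully_mapped(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (30, 4)),
                              index=[f"i{k}" for k in range(30)])
        mapping = {f"i{k}": f"g{k % 7}" for k in range(30)}
        out = collapse_isoforms(counts, mapping)
        assert out.to_numpy().sum() == counts.to_numpy().sum()
        # per-sample conservation is exact
        np.testing.assert_array_equal(out.sum(axis=0).to_numpy(),
                                      counts.sum(axis=0).to_numpy())


class TestInnerJoin:
    def _t(self, keys, cols):
        return pd.DataFrame(1, index=pd.Index(keys), columns=cols)

    def test_intersection(self):
        merged, rep = inner_join_species(self._t(["g1", "g2"], ["a1"]),
                                         self._t(["g2", "g3"], ["b1"]))
        assert list(merged.index) == ["g2"]
        assert rep["dropped_from_a"] == ["g1"] and rep["dropped_from_b"] == ["g3"]

    def test_disjoint_keys_warns_empty(self):
        with pytest.warns(UserWarning):
            merged, _ = inner_join_species(self._t(["g1"], ["a1"]),
                                           self._t(["g2"], ["b1"]))
        assert merged.empty

    def test_identical_keys_drop_nothing(self):
        merged, rep = inner_join_species(self._t(["g1", "g2"], ["a1"]),
                                         self._t(["g1", "g2"], ["b1"]))
        assert len(merged) == 2 and not rep["dropped_from_a"] and not rep["dropped_from_b"]

    def test_duplicate_keys_error(self):
        dup = pd.DataFrame(1, index=["g1", "g1"], columns=["a1"])
        with pytest.raises(ValueError, match="duplicate"):
            inner_join_species(dup, self._t(["g1"], ["b1"]))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        col = np.array([10, 200, 3000, 40, 500])
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), 1.0, atol=1e-12)

    def test_depth_scaled_column_unit_factor(self):
        """A column that is exactly twice another differs only in depth:
        all M-values against the scaled library cancel, so its TMM factor
        is 1 after the geometric-mean rescale."""
        rng = np.random.default_rng(8)
        ref = rng.integers(10, 1000, 40)
        counts = pd.DataFrame({"a": ref, "b": 2 * ref, "c": ref, "d": ref})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self, demo_counts):
        from petalmorph.merge import filter_hits as fh
        mapping = fh(demo_counts.hits)
        tables = {sp: collapse_isoforms(tbl, mapping)
                  for sp, tbl in demo_counts.isoform_counts.items()}
        merged, _ = inner_join_species(tables["A"], tables["B"])
        f = tmm_factors(merged)
        assert np.exp(np.mean(np.log(f.to_numpy()))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_edger_oracle(self):
        """Frozen oracle: edgeR::calcNormFactors(method='TMM') on this
        exact seeded fixture."""
        rng = np.random.default_rng(7)
        base = rng.lognormal(np.log(100), 1.0, 60)
        mat = rng.poisson(base[:, None] * np.array([1.0, 2.0, 0.7, 1.3, 1.0])[None, :])
        mat[:8, 1] *= 6
        counts = pd.DataFrame(mat, index=[f"g{i}" for i in range(60)],
                              columns=list("abcde"))
        expected = [1.1023410627, 0.6644149420, 1.1227173859, 1.1043441770,
                    1.1012089448]
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), expected, rtol=1e-6)

    def test_depth_invariance_of_cpm(self):
        """Scaling one sample's counts leaves its TMM-cpm almost unchanged."""
        rng = np.random.default_rng(15)
        base = rng.lognormal(np.log(100), 1.0, 500)
        counts = pd.DataFrame(rng.poisson(np.tile(base[:, None], (1, 4))),
                              columns=list("abcd"))
        scaled = counts.copy()
        scaled["a"] = counts["a"] * 5
        c1 = cpm(counts, tmm_factors(counts))["a"]
        c2 = cpm(scaled, tmm_factors(scaled))["a"]
        ok = np.abs(c2.to_numpy() / np.where(c1 > 0, c1, np.nan) - 1) < 0.01
        assert np.nanmean(ok) >= 0.99


class TestCpmFilter:
    def _norm(self, counts):
        return tmm_normalize(counts)

    def test_boundary_inclusive_three_samples(self):
        # gene kept iff cpm >= 1 in >= 3 of 13 samples, boundary inclusive
        n_samp = 13
        lib = 1_000_000
        counts = pd.DataFrame(
            np.full((4, n_samp), lib // 4, dtype=int),
            index=["g_hi3", "g_hi2", "g_zero", "g_filler"],
            columns=[f"s{j}" for j in range(n_samp)])
        counts.loc["g_hi3"] = [1, 1, 1] + [0] * 10   # exactly 1 cpm in 3 samples
        counts.loc["g_hi2"] = [1, 1, 0] + [0] * 10
        counts.loc["g_zero"] = 0
        counts.loc["g_filler"] = 333_333
        norm = self._norm(counts)
        norm.cpm = cpm(counts)  # unit factors: library sizes equal by construction
        kept, names = cpm_and_filter(norm, min_cpm=1.0, min_samples=3)
        assert "g_hi3" in names
        assert "g_hi2" not in names
        assert "g_zero" not in names

    def test_all_zero_gene_removed(self, demo_counts):
        counts = demo_counts.isoform_counts["A"].copy()
        counts.iloc[0] = 0
        norm = tmm_normalize(counts)
        _, names = cpm_and_filter(norm)
        assert counts.index[0] not in names


class TestQC:
    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.lognormal(3, 1, (200, 5)), columns=list("abcde"))
        mat["e"] = mat["a"]  # exact duplicate
        res = qc_sample_similarity(mat)
        first_merge = res["linkage"][0, :2].astype(int)
        assert sorted(first_merge) == [0, 4]
        assert res["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_groups_separate_on_pc1(self, demo_counts):
        from petalmorph.pipeline import Config, run_expression_arm
        res = run_expression_arm(Config(params={"seed": 1, "n_perm": 100}),
                                 isoform_counts=demo_counts.isoform_counts,
                                 hits=demo_counts.hits,
                                 annotation=demo_counts.annotation,
                                 sample_sheet=demo_counts.sample_sheet)
        qc = res["qc"]
        species = demo_counts.sample_sheet.loc[qc["samples"], "species"].to_numpy()
        pc1 = qc["pca_coordinates"][:, 0]
        a, b = pc1[species == "A"], pc1[species == "B"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.lognormal(3, 1, (100, 6)))
        res1 = qc_sample_similarity(mat)
        res2 = qc_sample_similarity(mat.sample(frac=1, random_state=0))
        np.testing.assert_allclose(np.abs(res1["pca_coordinates"]),
                                   np.abs(res2["pca_coordinates"]), atol=1e-8)

    def test_constant_matrix_errors(self):
        mat = pd.DataFrame(np.ones((50, 4)))
        with pytest.raises(ValueError):
            qc_sample_similarity(mat)
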