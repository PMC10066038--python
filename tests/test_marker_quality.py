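import dendropy
import numpy as np
import pandas as pd
import pytest

from phylocurate import (
    GenomeQuality, MarkerSet, assign_quality_tier, derive_auxiliary_markers,
    estimate_genome_size, exclude_constrained_markers, find_giant_orfs,
    group_compare, recompute_quality, size_quantile,
)


def quality(c, k, rrna=False, trna=0, gid="g"):
    return GenomeQuality(gid, c, k, has_5S=rrna, has_16S=rrna, has_23S=rrna,
                         trna_count=trna)


class TestRecomputeQuality:
    @pytest.mark.parametrize("counts,expected", [
        ([1] * 100, (1.0, 0.0)),
        ([1] * 90 + [0] * 10, (0.90, 0.0)),
        ([1] * 95 + [2] * 5, (1.0, 0.05)),
    ])
    def test_set_fraction_formulas(self, counts, expected):
        ms = MarkerSet([f"m{i}" for i in range(100)])
        row = pd.Series(counts, index=ms.marker_ids)
        q = recompute_quality(row, ms)
        assert (q.completeness, q.contamination) == pytest.approx(expected)

    def test_invariant_under_marker_reordering(self):
        rng = np.random.default_rng(7)
        ms = MarkerSet([f"m{i}" for i in range(50)])
        row = pd.Series(rng.integers(0, 3, 50), index=ms.marker_ids)
        q1 = recompute_quality(row, ms)
        perm = rng.permutation(50)
        q2 = recompute_quality(row.iloc[perm], ms)
        assert q1.completeness == q2.completeness
        assert q1.contamination == q2.contamination
        assert 0.0 <= q1.completeness <= 1.0

    def test_exclusion_changes_denominator(self):
        ms = MarkerSet(["a", "b", "c", "d"], excluded_ids=["d"])
        q = recompute_quality(pd.Series({"a": 1, "b": 1, "c": 0, "d": 5}), ms)
        assert q.completeness == pytest.approx(2 / 3)
        assert q.contamination == pytest.approx(0.0)

    def test_empty_effective_set_errors(self):
        ms = MarkerSet(["a"], excluded_ids=["a"])
        with pytest.raises(ValueError):
            recompute_quality(pd.Series({"a": 1}), ms)


def brute_force_patristic(tree):
    """Independent all-pairs path-length distances via root-paths and LCA."""
    depth, ancestors = {}, {}
    for leaf in tree.leaf_node_iter():
        d, anc, node = 0.0, [], leaf
        while node is not None:
            anc.append(id(node))
            d_edge = node.edge.length or 0.0
            node = node.parent_node
            if node is not None:
                d += d_edge
        # recompute cumulative depths per ancestor
        depth[leaf.taxon.label] = {}
        node, acc = leaf, 0.0
        while node is not None:
            depth[leaf.taxon.label][id(node)] = acc
            acc += node.edge.length or 0.0
            node = node.parent_node
        ancestors[leaf.taxon.label] = anc
    labels = sorted(ancestors)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            lca = next(x for x in ancestors[a] if x in set(ancestors[b]))
            out[(a, b)] = depth[a][lca] + depth[b][lca]
    return out


class TestExcludeConstrainedMarkers:
    def toy_tree(self):
        newick = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        return dendropy.Tree.get(data=newick, schema="newick")

    def matrix(self, cols):
        return pd.DataFrame(cols, index=list("ABCDEFGH"))

    def test_ubiquitous_marker_retained(self):
        m = self.matrix({"m_all": [1] * 8, "m_half": [1, 1, 1, 1, 0, 0, 0, 0]})
        assert "m_all" not in exclude_constrained_markers(
            m, self.toy_tree(), freq_threshold=0.5, dist_quantile=0.25)

    def test_single_genome_marker_excluded_unconditionally(self):
        m = self.matrix({"m_one": [1] + [0] * 7, "m_all": [1] * 8})
        assert "m_one" in exclude_constrained_markers(m, self.toy_tree())

    def test_clade_confined_marker_excluded_on_toy_tree(self):
        # marker confined to the {A, B, C} patch of one side of the root:
        # infrequent (3/8 < 0.5) and its bearers' mean patristic distance is
        # the smallest among the markers, below the 0.25 quantile.
        tree = self.toy_tree()
        m = self.matrix({
            "m_clade": [1, 1, 1, 0, 0, 0, 0, 0],
            "m_sp1": [1, 1, 1, 1, 1, 0, 0, 1],
            "m_sp2": [1, 0, 1, 1, 0, 1, 1, 1],
            "m_sp3": [0, 1, 1, 1, 1, 1, 1, 0],
            "m_all": [1] * 8,
        })
        bf = brute_force_patristic(tree)
        mean_d = {
            col: np.mean([bf[tuple(sorted((a, b)))]
                          for i, a in enumerate(bearers) for b in bearers[i + 1:]])
            for col, bearers in (
                (c, [g for g, v in zip("ABCDEFGH", m[c]) if v]) for c in m)
        }
        assert mean_d["m_clade"] == min(mean_d.values())  # oracle premise
        excluded = exclude_constrained_markers(
            m, tree, freq_threshold=0.5, dist_quantile=0.25)
        assert excluded == ["m_clade"]

    def test_missing_genome_named_in_error(self):
        m = pd.DataFrame({"m": [1, 1]}, index=["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            exclude_constrained_markers(m, self.toy_tree())

    def test_agrees_with_brute_force_on_random_trees(self):
        rng = np.random.default_rng(11)
        for rep in range(10):
            import random as _random
            ns = dendropy.TaxonNamespace([f"t{i}" for i in range(16)])
            tree = dendropy.simulate.treesim.pure_kingman_tree(
                taxon_namespace=ns, pop_size=1.0, rng=_random.Random(rep))
            genomes = sorted(t.label for t in ns)
            mat = pd.DataFrame(rng.integers(0, 2, (16, 12)), index=genomes,
                               columns=[f"m{j}" for j in range(12)])
            bf = brute_force_patristic(tree)
            stats = {}
            for c in mat.columns:
                bearers = [g for g in genomes if mat.loc[g, c] >= 1]
                if len(bearers) >= 2:
                    stats[c] = np.mean([bf[tuple(sorted((a, b)))]
                                        for i, a in enumerate(bearers)
                                        for b in bearers[i + 1:]])
            cutoff = np.quantile(list(stats.values()), 0.4)
            expected = sorted(
                c for c in mat.columns
                if (mat[c] >= 1).sum() <= 1
                or ((mat[c] >= 1).mean() < 0.45 and stats[c] < cutoff))
            got = sorted(exclude_constrained_markers(
                mat, tree, freq_threshold=0.45, dist_quantile=0.4))
            assert got == expected


class TestDeriveAuxiliaryMarkers:
    def test_degenerate_sigma_zero(self):
        genomes = [f"g{i}" for i in range(100)]
        qs = {g: quality(1.0, 0.0, gid=g) for g in genomes}
        m = pd.DataFrame({"present": [1] * 100, "absent": [0] * 100},
                         index=genomes)
        assert derive_auxiliary_markers(m, qs) == ["present"]

    def test_normal_band_accepts_70_rejects_60(self):
        # 100 genomes at p = 0.75: mu = 75, sigma = 4.330, band ~ [66.5, 83.5]
        genomes = [f"g{i}" for i in range(100)]
        qs = {g: quality(0.8, 0.05, gid=g) for g in genomes}
        m = pd.DataFrame({"m70": [1] * 70 + [0] * 30,
                          "m60": [1] * 60 + [0] * 40}, index=genomes)
        assert derive_auxiliary_markers(m, qs, occurrence="presence") == ["m70"]

    def test_clipping_warns(self):
        qs = {"a": quality(0.2, 0.5, gid="a"), "b": quality(1.0, 0.0, gid="b")}
        m = pd.DataFrame({"m": [1, 1]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="clipping"):
            derive_auxiliary_markers(m, qs)

    def test_empty_genome_set_errors(self):
        with pytest.raises(ValueError):
            derive_auxiliary_markers(pd.DataFrame(columns=["m"]), {})


class TestEstimateGenomeSize:
    @pytest.mark.parametrize("args,expected", [
        ((2_000_000, 1.0, 0.0), 2_000_000),
        ((1_800_000, 0.9, 0.0), 2_000_000),
        ((2_100_000, 0.9, 0.05), 2_216_666.67),
    ])
    def test_formula(self, args, expected):
        assert estimate_genome_size(*args) == pytest.approx(expected, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            estimate_genome_size(1e6, 0.0, 0.0)
        with pytest.raises(ValueError):
            estimate_genome_size(1e6, 0.9, 1.0)
        with pytest.raises(ValueError):
            estimate_genome_size(0, 0.9, 0.0)

    def test_monotonicity(self):
        comps = np.linspace(0.2, 1.0, 30)
        ests = [estimate_genome_size(2e6, c, 0.03) for c in comps]
        assert all(a > b for a, b in zip(ests, ests[1:]))  # falls as c rises
        conts = np.linspace(0.0, 0.5, 30)
        ests = [estimate_genome_size(2e6, 0.8, k) for k in conts]
        assert all(a > b for a, b in zip(ests, ests[1:]))  # falls as k rises


class TestQualityTiers:
    BOUNDARY = [
        ((0.95, 0.02, True, 20), "high"),
        ((0.95, 0.02, False, 20), "medium"),   # missing rRNAs
        ((0.95, 0.06, True, 20), "medium"),    # contamination too high for high
        ((0.91, 0.04, True, 18), "high"),      # 18 tRNAs suffice
        ((0.91, 0.04, True, 17), "medium"),
        ((0.90, 0.02, True, 20), "medium"),    # completeness must exceed 0.90
        ((0.60, 0.12, False, 0), "discard"),
        ((0.51, 0.09, False, 0), "medium"),
        ((0.50, 0.04, False, 0), "low"),
        ((0.30, 0.04, False, 0), "low"),
        ((0.10, 0.01, False, 0), "low"),       # 10% inclusive
        ((0.08, 0.01, False, 0), "discard"),
        ((0.30, 0.07, False, 0), "discard"),   # unmatched fall-through
    ]

    @pytest.mark.parametrize("args,expected", BOUNDARY)
    def test_boundary_table(self, args, expected, recwarn):
        c, k, rrna, trna = args
        assert assign_quality_tier(quality(c, k, rrna, trna)) == expected

    def test_totality_on_unit_square_grid(self, recwarn):
        tiers = {"high", "medium", "low", "discard"}
        for c in np.arange(0.0, 1.001, 0.01):
            for k in np.arange(0.0, 1.001, 0.01):
                for rrna, trna in ((True, 20), (False, 0)):
                    assert assign_quality_tier(
                        quality(round(c, 2), round(k, 2), rrna, trna)) in tiers


class TestGiantOrfs:
    def orfs(self, lengths):
        return pd.DataFrame({
            "genome_id": "g", "contig": "c1", "start": 1,
            "end": lengths, "strand": "+", "length_nt": lengths})

    def test_archetypal_giant_orf(self):
        # 39,678 aa -> 3*aa + 3 = 119,037 nt
        giants = find_giant_orfs(self.orfs([119_037, 1_500]))
        assert list(giants["length_nt"]) == [119_037]

    def test_boundary_is_strict(self):
        assert find_giant_orfs(self.orfs([20_000])).empty
        assert not find_giant_orfs(self.orfs([20_001])).empty

    def test_empty_table(self):
        assert find_giant_orfs(self.orfs([])[0:0]).empty

    def test_sorted_descending(self):
        giants = find_giant_orfs(self.orfs([25_000, 90_000, 30_000]))
        assert list(giants["length_nt"]) == [90_000, 30_000, 25_000]


class TestSizeQuantile:
    def test_minimum_of_tie_free_reference(self):
        ref = np.arange(1, 101) * 1e5
        assert size_quantile(ref[0], ref) == pytest.approx(0.005)

    def test_above_all(self):
        assert size_quantile(1e9, [1e6, 2e6]) == 1.0

    def test_constant_reference_symmetry(self):
        assert size_quantile(2e6, [2e6] * 50) == 0.5

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            size_quantile(1e6, [])


class TestGroupCompare:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0] * 2
        labels = ["a"] * 3 + ["b"] * 3
        res = group_compare(vals, labels)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert (res.table["p_adj"] == 1.0).all()

    def test_all_identical_flags_degenerate(self):
        res = group_compare([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.degenerate and np.isnan(res.f_stat)
        assert (res.table["p_adj"] == 1.0).all()

    def test_zero_within_variance_different_means(self):
        res = group_compare([1.0] * 3 + [2.0] * 3, ["a"] * 3 + ["b"] * 3)
        assert res.degenerate and np.isinf(res.f_stat)
        assert (res.table["p_adj"] == 0.0).all()

    def test_planted_shift_detected_in_monte_carlo(self):
        # three groups, one shifted by 2 sigma, n = 30: the shifted pairs
        # should dominate the significant calls across seeded replicates
        planted_hits, null_ok = 0, 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                                   rng.normal(2, 1, 30)])
            labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
            res = group_compare(vals, labels)
            tab = res.table.set_index(["group_a", "group_b"])
            planted_hits += (tab.loc[("a", "c"), "p_adj"] < 0.05
                             and tab.loc[("b", "c"), "p_adj"] < 0.05)
            null_ok += tab.loc[("a", "b"), "p_adj"] >= 0.05
        assert planted_hits / n_rep >= 0.95
        assert null_ok / n_rep >= 0.90

    def test_input_validation(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "b"])
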