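"""Presence matrix, common/shared/private classification, Venn counts, clonal tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somascape import heterogeneity as het
from somascape import simulate


def _matrix(rows, regions=("T1", "T2", "T3")):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", i + 1, "C", "T") for i in range(len(rows))],
        names=["chrom", "pos", "ref", "alt"],
    )
    return pd.DataFrame(rows, index=idx, columns=list(regions)).astype(bool)


def _calls(keys):
    return pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": r, "alt": a} for c, p, r, a in keys],
        columns=["chrom", "pos", "ref", "alt"],
    )


FIG6_ROWS = (
    [[1, 1, 1]] * 13 + [[1, 1, 0]] * 2 + [[1, 0, 0]] * 7 + [[0, 1, 0]] * 12 + [[0, 0, 1]] * 8
)


class TestBuildPresence:
    def test_union_and_membership(self):
        k1 = [("chr1", 1, "C", "T"), ("chr1", 2, "A", "G")]
        k2 = [("chr1", 2, "A", "G"), ("chr1", 3, "C", "A")]
        mat = het.build_presence({"T1": _calls(k1), "T2": _calls(k2)})
        assert len(mat) == 3
        assert mat.loc[("chr1", 2, "A", "G")].all()
        assert mat.loc[("chr1", 1, "C", "T"), "T1"] and not mat.loc[("chr1", 1, "C", "T"), "T2"]

    def test_duplicate_keys_rejected(self):
        k = [("chr1", 1, "C", "T"), ("chr1", 1, "C", "T")]
        with pytest.raises(ValueError, match="duplicate"):
            het.build_presence({"T1": _calls(k), "T2": _calls([])})

    def test_rescue_by_supporting_reads(self):
        k1 = [("chr1", 1, "C", "T")]
        ev = pd.DataFrame(
            [{"chrom": "chr1", "pos": 1, "ref": "C", "alt": "T", "t_alt": 3, "depth": 100}]
        )
        mat_off = het.build_presence({"T1": _calls(k1), "T2": _calls([])})
        assert not mat_off.loc[("chr1", 1, "C", "T"), "T2"]
        mat_on = het.build_presence(
            {"T1": _calls(k1), "T2": _calls([])}, evidence={"T2": ev}, rescue_alt=2
        )
        assert mat_on.loc[("chr1", 1, "C", "T"), "T2"]

    def test_needs_two_regions(self):
        with pytest.raises(ValueError):
            het.build_presence({"T1": _calls([])})


class TestClassify:
    def test_figure_worked_example(self):
        """13 all-present, 2 in two regions, 7/12/8 private: 31% common."""
        mat = _matrix(FIG6_ROWS)
        labels, counts = het.classify(mat)
        assert counts == {"common": 13, "shared": 2, "private": 27}
        assert het.percent_common(mat) == 31

    def test_all_common(self):
        _, counts = het.classify(_matrix([[1, 1, 1]] * 6))
        assert counts == {"common": 6, "shared": 0, "private": 0}

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_matches_row_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_regions = int(rng.integers(2, 5))
        rows = rng.integers(0, 2, size=(100, n_regions)).astype(bool)
        rows = rows[rows.any(axis=1)]
        mat = _matrix(rows, regions=[f"T{i+1}" for i in range(n_regions)])
        labels, counts = het.classify(mat)
        s = rows.sum(axis=1)
        assert counts["common"] == int((s == n_regions).sum())
        assert counts["private"] == int((s == 1).sum())
        assert counts["shared"] == int(((s > 1) & (s < n_regions)).sum())

    def test_region_order_invariance(self):
        mat = _matrix(FIG6_ROWS)
        shuffled = mat[["T3", "T1", "T2"]]
        assert het.classify(mat)[1] == het.classify(shuffled)[1]


class TestVenn:
    def test_figure_worked_example_cells(self):
        venn = het.venn_counts(_matrix(FIG6_ROWS))
        assert venn[frozenset({"T1", "T2", "T3"})] == 13
        assert venn[frozenset({"T1", "T2"})] == 2
        assert venn[frozenset({"T1"})] == 7
        assert venn[frozenset({"T2"})] == 12
        assert venn[frozenset({"T3"})] == 8
        assert venn[frozenset({"T1", "T3"})] == 0
        assert sum(venn.values()) == 42

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(60, 4)).astype(bool)
        rows = rows[rows.any(axis=1)]
        regions = ["A", "B", "C", "D"]
        mat = _matrix(rows, regions=regions)
        venn = het.venn_counts(mat)
        for subset, count in venn.items():
            mask = np.ones(len(rows), dtype=bool)
            for j, r in enumerate(regions):
                mask &= rows[:, j] == (r in subset)
            assert count == int(mask.sum())


class TestTree:
    def test_figure_worked_example_tree(self):
        tree = het.clonal_ordering_tree(_matrix(FIG6_ROWS))
        lengths = {tuple(sorted(k)): v for k, v in tree.branch_lengths().items()}
        assert lengths == {
            ("T1", "T2", "T3"): 13,
            ("T1", "T2"): 2,
            ("T1",): 7,
            ("T2",): 12,
            ("T3",): 8,
        }
        assert tree.total_mutations() == 42
        assert tree.conflicts == []
        nwk = tree.newick()
        assert nwk.endswith(":13;")
        assert "T3:8" in nwk

    def test_trunk_only_star(self):
        tree = het.clonal_ordering_tree(_matrix([[1, 1, 1]] * 5))
        lengths = tree.branch_lengths()
        assert lengths[frozenset({"T1", "T2", "T3"})] == 5
        assert all(lengths[frozenset({r})] == 0 for r in ("T1", "T2", "T3"))
        assert len(tree.root.children) == 3

    def test_four_region_nested_chain(self):
        """{ABCD} > {ABC} > {AB} nests into a chain, as built by hand."""
        regions = ("A", "B", "C", "D")
        rows = [[1, 1, 1, 1]] * 2 + [[1, 1, 1, 0]] * 3 + [[1, 1, 0, 0]] * 4 + [[1, 0, 0, 0]] * 1
        tree = het.clonal_ordering_tree(_matrix(rows, regions=regions))
        assert tree.conflicts == []
        root = tree.root
        assert root.count == 2
        abc = next(c for c in root.children if c.regions == frozenset("ABC"))
        assert abc.count == 3
        ab = next(c for c in abc.children if c.regions == frozenset("AB"))
        assert ab.count == 4
        a = next(c for c in ab.children if c.regions == frozenset("A"))
        assert a.count == 1
        # D never acquired private mutations but still appears as a leaf
        d = next(c for c in root.children if c.regions == frozenset("D"))
        assert d.count == 0

    def test_branch_lengths_conserve_mutations(self):
        rng = np.random.default_rng(13)
        rows = rng.integers(0, 2, size=(200, 4)).astype(bool)
        rows = rows[rows.any(axis=1)]
        mat = _matrix(rows, regions=["A", "B", "C", "D"])
        tree = het.clonal_ordering_tree(mat)
        assert tree.total_mutations() == len(mat)

    def test_branch_lengths_equal_subset_counts(self):
        rng = np.random.default_rng(14)
        rows = rng.integers(0, 2, size=(150, 3)).astype(bool)
        rows = rows[rows.any(axis=1)]
        regions = ["T1", "T2", "T3"]
        mat = _matrix(rows, regions=regions)
        tree = het.clonal_ordering_tree(mat)
        lengths = tree.branch_lengths()
        expected = {}
        for row in rows:
            s = frozenset(r for r, v in zip(regions, row) if v)
            expected[s] = expected.get(s, 0) + 1
        for subset, count in expected.items():
            assert lengths[subset] == count

    def test_conflicting_subsets_reported_not_fatal(self):
        rows = [[1, 1, 1, 1]] + [[1, 1, 0, 0]] * 3 + [[0, 1, 1, 0]] * 2
        tree = het.clonal_ordering_tree(_matrix(rows, regions=["A", "B", "C", "D"]))
        assert len(tree.conflicts) == 1
        assert tree.total_mutations() == 6 + 0  # all rows assigned despite conflict


class TestPlantedTopologyRecovery:
    def test_truth_matrix_reproduces_planted_tree(self):
        for seed in range(20):
            cfg = simulate.SimConfig(seed=500 + seed)
            _, truth = simulate.simulate_multiregion(cfg, 3, 5, 3, (4, 2, 6))
            mat = truth.region_assignment.set_index(["chrom", "pos", "ref", "alt"])
            tree = het.clonal_ordering_tree(mat[["T1", "T2", "T3"]].astype(bool))
            lengths = tree.branch_lengths()
            assert tree.conflicts == []
            assert lengths[frozenset({"T1", "T2", "T3"})] == 5
            assert lengths[frozenset({"T1", "T2"})] == 3
            assert lengths[frozenset({"T1"})] == 4
            assert lengths[frozenset({"T2"})] == 2
            assert lengths[frozenset({"T3"})] == 6
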