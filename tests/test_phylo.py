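"""MSA construction, p-distances, NJ correctness and bootstrap behavior."""

import numpy as np
import pytest
from skbio import TreeNode

from famscan.phylo import (
    MSA,
    DistanceMatrix,
    bipartitions,
    bootstrap,
    center_star_msa,
    neighbor_joining,
    p_distance,
    read_newick,
    robinson_foulds,
    tree_to_newick,
    write_newick,
)


def random_additive(n, rng):
    """Random n-leaf binary tree and its exact tip-to-tip distances."""
    avail = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(avail) > 3:
        i, j = sorted(rng.choice(len(avail), 2, replace=False))
        a, b = avail[j], avail[i]
        a.length = float(rng.uniform(0.05, 0.3))
        b.length = float(rng.uniform(0.05, 0.3))
        avail = [x for x in avail if x not in (a, b)] + [TreeNode(children=[b, a])]
    for x in avail:
        x.length = float(rng.uniform(0.05, 0.3))
    tree = TreeNode(children=avail)
    dmat = tree.tip_tip_distances()
    return list(dmat.ids), np.asarray(dmat.data), tree


class TestCenterStar:
    def test_identical_sequences_align_gap_free(self):
        msa = center_star_msa({"a": "MKVLWAAL", "b": "MKVLWAAL", "c": "MKVLWAAL"})
        assert msa.rows == ["MKVLWAAL"] * 3

    def test_single_insertion_creates_one_gap_column(self):
        msa = center_star_msa(
            {"a": "MKVLWAAL", "b": "MKVLQWAAL", "c": "MKVLWAAL"}, max_gap_frac=1.0
        )
        n_gap_cols = sum(1 for j in range(msa.n_columns)
                         if any(r[j] == "-" for r in msa.rows))
        assert n_gap_cols == 1

    def test_majority_gap_column_extracted(self):
        with_cols = center_star_msa(
            {"a": "MKVLWAAL", "b": "MKVLQWAAL", "c": "MKVLWAAL"}, max_gap_frac=1.0
        )
        extracted = center_star_msa(
            {"a": "MKVLWAAL", "b": "MKVLQWAAL", "c": "MKVLWAAL"}
        )
        assert extracted.n_columns == with_cols.n_columns - 1
        assert all("-" not in r for r in extracted.rows)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            center_star_msa({"a": "MKVL"})


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = p_distance(MSA(["a", "b"], ["MKVL", "MKVL"]))
        assert dm.d[0, 1] == 0.0

    def test_one_of_ten_columns(self):
        dm = p_distance(MSA(["a", "b"], ["MKVLWAALHE", "MKVLWAALHD"]))
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_pairwise_deletion_of_gap_columns(self):
        dm = p_distance(MSA(["a", "b"], ["MK-LW", "MKVLW"]))
        assert dm.d[0, 1] == 0.0  # 4 compared columns, 0 mismatches

    def test_matches_direct_column_count_oracle(self, rng):
        alpha = list("ACDG-")
        for _ in range(20):
            rows = ["".join(rng.choice(alpha, 30)) for _ in range(4)]
            msa = MSA([f"t{i}" for i in range(4)], rows)
            dm = p_distance(msa)
            for i in range(4):
                for j in range(i + 1, 4):
                    comp = mism = 0
                    for x, y in zip(rows[i], rows[j]):
                        if x != "-" and y != "-":
                            comp += 1
                            mism += x != y
                    expected = mism / comp if comp else 1.0
                    assert dm.d[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.4 - 0.5) / 2, abs=1e-9)
        assert lengths["B"] == pytest.approx((0.3 + 0.5 - 0.4) / 2, abs=1e-9)
        assert lengths["C"] == pytest.approx((0.4 + 0.5 - 0.3) / 2, abs=1e-9)

    def test_ultrametric_cherries_recovered(self):
        # two clear cherries: (A,B) and (C,D)
        d = np.array(
            [[0.0, 0.2, 1.0, 1.0],
             [0.2, 0.0, 1.0, 1.0],
             [1.0, 1.0, 0.0, 0.2],
             [1.0, 1.0, 0.2, 0.0]]
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_consistent_on_additive_distances(self, rng):
        for _ in range(25):
            taxa, d, true_tree = random_additive(8, rng)
            nj = neighbor_joining(DistanceMatrix(taxa, d))
            assert robinson_foulds(nj, true_tree) == 0

    def test_agrees_with_skbio_on_additive_matrices(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            taxa, d, _ = random_additive(7, rng)
            ours = neighbor_joining(DistanceMatrix(taxa, d))
            theirs = skbio_nj(SkbioDM(d, ids=taxa))
            assert robinson_foulds(ours, theirs) == 0


class TestNewick:
    def test_round_trip_is_identity(self, tmp_path, rng):
        taxa, d, _ = random_additive(6, rng)
        tree = neighbor_joining(DistanceMatrix(taxa, d))
        p1 = tmp_path / "t1.nwk"
        write_newick(tree, p1)
        back = read_newick(p1)
        assert {t.name for t in back.tips()} == set(taxa)
        p2 = tmp_path / "t2.nwk"
        write_newick(back, p2)
        assert p1.read_text() == p2.read_text()


class TestBootstrap:
    MSA_DUP = MSA(
        ["a", "b", "c", "d"],
        ["MKVLWAALHE", "MKVLWAALHE", "MPVDWAESHE", "MPVDWAESHD"],
    )

    def test_duplicate_taxa_cherry_supported_at_100(self):
        _, supports = bootstrap(self.MSA_DUP, n_reps=50, seed=5)
        assert set(supports.values()) == {100.0}

    def test_supports_bounded_and_seed_reproducible(self):
        _, s1 = bootstrap(self.MSA_DUP, n_reps=30, seed=9)
        _, s2 = bootstrap(self.MSA_DUP, n_reps=30, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_zero_reps_returns_plain_topology(self):
        t0, supports = bootstrap(self.MSA_DUP, n_reps=0, seed=1)
        assert supports == {}
        plain = neighbor_joining(p_distance(self.MSA_DUP))
        assert robinson_foulds(t0, plain) == 0
        assert all(n.name is None for n in t0.non_tips())
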