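"""Homolog clustering, nomenclature, duplication calling and orthology."""

import numpy as np
import pandas as pd
import pytest

from famscan.homology import (
    assign_nomenclature,
    cluster_homologs,
    find_duplications,
    find_orthologs,
)
from famscan.seqio import GeneModel, GenomeSet
from famscan.synthetic_data import back_translate


COLS = ["query", "subject", "score", "identity_pct", "aligned_length",
        "query_coverage", "e_value"]


def hits_df(rows):
    """rows: (query, subject, identity[, score]) with a passing e-value."""
    return pd.DataFrame(
        [
            (r[0], r[1], (r[3] if len(r) > 3 else 500.0), r[2], 100, 100.0, 1e-50)
            for r in rows
        ],
        columns=COLS,
    )


class TestClustering:
    def test_single_linkage_transitivity(self):
        hits = hits_df([("A", "B", 95), ("B", "C", 92), ("A", "C", 89)])
        clusters = cluster_homologs(hits, ["A", "B", "C"])
        assert [c.members for c in clusters] == [["A", "B", "C"]]

    def test_all_below_gate_gives_singletons(self):
        hits = hits_df([("A", "B", 89.9), ("B", "C", 85)])
        clusters = cluster_homologs(hits, ["A", "B", "C"])
        assert all(c.size == 1 for c in clusters)
        assert len(clusters) == 3

    def test_identity_gate_is_strict(self):
        hits = hits_df([("A", "B", 90.0)])
        clusters = cluster_homologs(hits, ["A", "B"])
        assert len(clusters) == 2  # "more than 90%" excludes exactly 90

    def test_evalue_gate_applies(self):
        hits = hits_df([("A", "B", 99)])
        hits.loc[0, "e_value"] = 1e-5
        assert len(cluster_homologs(hits, ["A", "B"])) == 2

    def test_partition_covers_and_is_disjoint(self, default_sim, self_hits):
        genes = list(default_sim.genome_a.proteins())
        clusters = cluster_homologs(self_hits, genes)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(genes)

    def test_complete_linkage_requires_all_pairs(self):
        hits = hits_df([("A", "B", 95), ("B", "C", 92), ("A", "C", 89)])
        clusters = cluster_homologs(hits, ["A", "B", "C"], linkage="complete")
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 2]


class TestNomenclature:
    PROTS = {"A": "M" * 120, "B": "M" * 100, "C": "M" * 90, "S": "M" * 50}

    def test_singleton_gets_bare_name(self):
        clusters = cluster_homologs(hits_df([]), ["S"], family="L_LRK")
        named = assign_nomenclature(clusters, "L-LRK", self.PROTS)
        assert named[0].names == {"S": "L-LRK1"}

    def test_three_member_cluster_names(self):
        hits = hits_df([("A", "B", 95), ("B", "C", 95)])
        clusters = cluster_homologs(hits, ["A", "B", "C"], family="L_LRK")
        named = assign_nomenclature(clusters, "L-LRK", self.PROTS)
        assert named[0].representative == "A"  # longest protein
        assert named[0].names == {"A": "L-LRK1", "B": "L-LRK1.1", "C": "L-LRK1.2"}

    def test_stable_under_input_permutation(self, rng):
        hits = hits_df([("A", "B", 95), ("B", "C", 95)])
        genes = ["A", "B", "C", "S"]
        base = None
        for _ in range(5):
            perm = [genes[i] for i in rng.permutation(4)]
            clusters = cluster_homologs(hits, perm, family="L_LRK")
            named = assign_nomenclature(clusters, "L-LRK", self.PROTS)
            names = {g: n for c in named for g, n in c.names.items()}
            if base is None:
                base = names
            assert names == base


def _gene(gene_id, start, protein="MKVLWAALHE" * 8):
    cds = back_translate(protein, gene_id)
    return GeneModel.from_parts(
        gene_id, start, start + len(cds) - 1, "+",
        [(start, start + len(cds) - 1)], cds, protein,
    )


@pytest.fixture()
def placed_genes():
    gs = GenomeSet("test")
    gs.add(_gene("Traes_2AS_0001", 1_000_000))
    gs.add(_gene("Traes_2AS_0002", 3_500_000))
    gs.add(_gene("Traes_2AL_0003", 13_000_000))
    gs.add(_gene("Traes_2BS_0004", 1_000_000))
    gs.add(_gene("scaffold_99_g1", 1_000))
    return gs


class TestDuplications:
    def test_within_window_is_tandem(self, placed_genes):
        hits = hits_df([("Traes_2AS_0001", "Traes_2AS_0002", 85)])
        (e,) = find_duplications(placed_genes, hits)
        assert e.category == "TD"
        assert e.distance_bp == 2_500_000

    def test_beyond_window_is_segmental(self, placed_genes):
        hits = hits_df([("Traes_2AS_0001", "Traes_2AL_0003", 85)])
        (e,) = find_duplications(placed_genes, hits)
        assert e.category == "SD"

    def test_scaffold_member_uncategorized(self, placed_genes):
        hits = hits_df([("Traes_2AS_0001", "scaffold_99_g1", 85)])
        (e,) = find_duplications(placed_genes, hits)
        assert e.category == "uncategorized"
        assert e.distance_bp is None

    def test_different_chromosomes_are_not_events(self, placed_genes):
        hits = hits_df([("Traes_2AS_0001", "Traes_2BS_0004", 95)])
        assert find_duplications(placed_genes, hits) == []

    def test_identity_gate_is_inclusive_at_80(self, placed_genes):
        hits = hits_df([("Traes_2AS_0001", "Traes_2AS_0002", 80.0)])
        assert len(find_duplications(placed_genes, hits)) == 1
        hits = hits_df([("Traes_2AS_0001", "Traes_2AS_0002", 79.9)])
        assert find_duplications(placed_genes, hits) == []


class TestOrthologs:
    def test_single_reciprocal_pair(self):
        fwd = hits_df([("x", "y", 90, 800.0)])
        rev = hits_df([("y", "x", 90, 800.0)])
        (p,) = find_orthologs(fwd, rev)
        assert (p.gene_id_species1, p.gene_id_species2) == ("x", "y")

    def test_non_reciprocal_best_hit_yields_no_pair(self):
        fwd = hits_df([("x", "y", 90, 800.0)])
        rev = hits_df([("y", "z", 95, 900.0), ("y", "x", 90, 800.0)])
        assert find_orthologs(fwd, rev) == []

    def test_symmetric_in_species_order(self, cross_hits):
        h12, h21 = cross_hits
        fwd = {(p.gene_id_species1, p.gene_id_species2) for p in find_orthologs(h12, h21)}
        rev = {(p.gene_id_species2, p.gene_id_species1) for p in find_orthologs(h21, h12)}
        assert fwd == rev

    def test_best_hit_ranked_by_score_not_identity(self):
        fwd = hits_df([("x", "y", 95, 500.0), ("x", "z", 80, 900.0)])
        rev = hits_df([("z", "x", 80, 900.0)])
        (p,) = find_orthologs(fwd, rev)
        assert p.gene_id_species2 == "z"
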