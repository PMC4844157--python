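"""Exact-match read counting, RPKM arithmetic and fold-change rules."""

import numpy as np
import pandas as pd
import pytest

from famscan.expression import (
    ExpressionMatrix,
    ReadSet,
    TranscriptIndex,
    fold_changes,
    map_reads_exact,
    quantify,
    reverse_complement,
    rpkm,
    specificity_summary,
)

TX = {
    "g1": "ATGAAACCCGGGTTTACGTACGATCGATCGAA",
    "g2": "ATGTTTGGGCCCAAATTTACGATCAGCTAGCT",
}


class TestMapReads:
    def test_unique_read_counts_once(self):
        counts = map_reads_exact([TX["g1"][:10]], TX)
        assert counts == {"g1": 1.0, "g2": 0.0}

    def test_reverse_complement_read_maps(self):
        counts = map_reads_exact([reverse_complement(TX["g2"][5:20])], TX)
        assert counts["g2"] == 1.0

    def test_shared_read_split_fractionally(self):
        tx = {"a": "AAACCCGGGTTT", "b": "AAACCCGGGTTT"}
        counts = map_reads_exact(["AACCCGGG"], tx)
        assert counts == {"a": 0.5, "b": 0.5}

    def test_multimap_modes(self):
        tx = {"a": "AAACCCGGGTTT", "b": "AAACCCGGGTTT"}
        assert map_reads_exact(["AACCCGGG"], tx, multimap="all") == {"a": 1.0, "b": 1.0}
        assert map_reads_exact(["AACCCGGG"], tx, multimap="discard") == {"a": 0.0, "b": 0.0}

    def test_unmapped_reads_do_not_count(self):
        counts = map_reads_exact(["TTTTTTTTTT"], TX)
        assert sum(counts.values()) == 0.0

    def test_total_counts_bounded_by_reads(self, default_sim):
        rs = default_sim.read_sets[0]
        tx = default_sim.genome_a.transcripts()
        counts = map_reads_exact(rs, TranscriptIndex(tx, len(rs.reads[0])))
        assert sum(counts.values()) <= len(rs.reads) + 1e-9


class TestRpkm:
    def test_unit_instantiation(self):
        assert rpkm(10, 1000, 1_000_000) == 10.0

    def test_zero_count_is_zero(self):
        assert rpkm(0, 1000, 1_000_000) == 0.0

    def test_matches_direct_formula(self, rng):
        for _ in range(200):
            c = float(rng.integers(0, 10_000))
            L = int(rng.integers(100, 10_000))
            N = int(rng.integers(10_000, 10_000_000))
            assert rpkm(c, L, N) == pytest.approx(c * 1e9 / (L * N), rel=1e-12)

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


def _matrix(values: dict, samples: list[str]) -> ExpressionMatrix:
    rpkm_df = pd.DataFrame(values)[samples]
    meta = pd.DataFrame(
        [{"sample_id": s, "organ": "", "stage": "", "stress": "", "timepoint": "",
          "replicate": 1, "library_total": 1} for s in samples]
    )
    return ExpressionMatrix(rpkm=rpkm_df, counts=rpkm_df.copy(), samples=meta)


class TestFoldChanges:
    def test_formula_and_up_call(self):
        mat = _matrix({"t1": {"g": 4.0}, "c1": {"g": 1.0}}, ["t1", "c1"])
        (r,) = fold_changes(mat, (["t1"], ["c1"]), pseudocount=0.1)
        assert r.fold_change == pytest.approx(4.1 / 1.1)
        assert r.direction == "up"

    def test_identical_means_unaffected(self):
        mat = _matrix({"t1": {"g": 3.0}, "c1": {"g": 3.0}}, ["t1", "c1"])
        (r,) = fold_changes(mat, (["t1"], ["c1"]))
        assert r.fold_change == 1.0
        assert r.direction == "unaffected"

    def test_down_threshold_at_half(self):
        mat = _matrix({"t1": {"g": 0.9}, "c1": {"g": 1.9}}, ["t1", "c1"])
        (r,) = fold_changes(mat, (["t1"], ["c1"]), pseudocount=0.1)
        assert r.direction == "down"

    def test_self_contrast_marks_everything_unaffected(self, expr_matrix):
        cols = expr_matrix.sample_ids()[:2]
        for r in fold_changes(expr_matrix, (cols, cols)):
            assert r.direction == "unaffected"

    def test_empty_side_rejected(self, expr_matrix):
        with pytest.raises(ValueError):
            fold_changes(expr_matrix, ([], expr_matrix.sample_ids()[:1]))


class TestSpecificity:
    def test_dominant_gene_tops_its_organ(self):
        rpkm_df = pd.DataFrame(
            {"root_r1": [100.0, 1.0], "leaf_r1": [1.0, 80.0]},
            index=["gR", "gL"],
        )
        meta = pd.DataFrame(
            [{"sample_id": "root_r1", "organ": "root", "stage": "", "stress": "",
              "timepoint": "", "replicate": 1, "library_total": 1},
             {"sample_id": "leaf_r1", "organ": "leaf", "stage": "", "stress": "",
              "timepoint": "", "replicate": 1, "library_total": 1}]
        )
        mat = ExpressionMatrix(rpkm=rpkm_df, counts=rpkm_df, samples=meta)
        out = specificity_summary(mat, top_n=1)
        top = out["top_genes"]
        assert top[top["sample_id"] == "root_r1"]["gene_id"].iloc[0] == "gR"
        assert out["organ_max"] == {"gR": "root", "gL": "leaf"}

    def test_top_lists_stable_under_row_permutation(self, rng):
        vals = rng.random((10, 3))
        genes = [f"g{i}" for i in range(10)]
        meta = pd.DataFrame(
            [{"sample_id": f"s{j}", "organ": "", "stage": "", "stress": "",
              "timepoint": "", "replicate": 1, "library_total": 1} for j in range(3)]
        )
        df = pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(3)])
        base = specificity_summary(ExpressionMatrix(df, df, meta))["top_genes"]
        perm = df.iloc[list(rng.permutation(10))]
        again = specificity_summary(ExpressionMatrix(perm, perm, meta))["top_genes"]
        pd.testing.assert_frame_equal(base, again)


class TestQuantify:
    def test_library_total_fallback_is_mapped_total(self):
        rs = ReadSet(sample_id="s", reads=[TX["g1"][:10]], library_total=None)
        mat = quantify([rs], TX)
        assert mat.rpkm.loc["g1", "s"] == rpkm(1, len(TX["g1"]), 1)

    def test_rpkm_zero_iff_count_zero(self, expr_matrix):
        z_rpkm = expr_matrix.rpkm.to_numpy() == 0
        z_cnt = expr_matrix.counts.to_numpy() == 0
        assert np.array_equal(z_rpkm, z_cnt)
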