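"""Domain scanning, family classification and protein descriptors."""

import numpy as np
import pytest

from famscan.domains import (
    DomainHit,
    classify_family,
    classify_proteins,
    compute_mw_pi,
    domain_length_stats,
    hits_from_table,
    hits_to_table,
    load_packaged_models,
    load_pssm,
    net_charge,
    pssm_from_consensus,
    save_pssm,
    scan_domains,
)


@pytest.fixture(scope="module")
def models():
    return load_packaged_models()


class TestScanDomains:
    def test_consensus_self_hit_is_maximal_and_exact(self, models, rng):
        m = models["PKINASE"]
        flank = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        protein = flank + m.consensus + flank
        hits = scan_domains(protein, {"PKINASE": m})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (41, 40 + m.length)
        assert h.score == pytest.approx(m.self_score())

    def test_short_protein_yields_no_hits(self, models):
        assert scan_domains("MKVL", models) == []

    def test_shuffled_proteins_never_hit(self, models, default_sim, rng):
        """Empirical null: residue composition alone cannot pass a model."""
        protein = next(iter(default_sim.genome_a)).protein
        chars = np.array(list(protein))
        for _ in range(100):
            rng.shuffle(chars)
            assert scan_domains("".join(chars), models) == []

    def test_planted_intervals_recovered_exactly(self, small_sim, models):
        truth = {}
        for r in small_sim.truth.domain_intervals.itertuples(index=False):
            truth.setdefault(r.gene_id, set()).add((r.domain_id, r.start, r.end))
        for g in small_sim.genome_a:
            if small_sim.truth.families[g.gene_id] == "none":
                continue
            hits = scan_domains(g.protein, models, g.gene_id)
            got = {(h.domain_id, h.start, h.end) for h in hits}
            assert got == truth[g.gene_id]


def _hit(domain, score=100.0, start=1, end=50):
    return DomainHit("g", domain, start, end, score)


class TestClassifyFamily:
    @pytest.mark.parametrize(
        "domains_present, expected",
        [
            (["PKINASE", "LEC_LEGUME"], "L_LRK"),
            (["PKINASE", "LEC_BULB"], "B_LRK"),
            (["PKINASE", "LEC_C"], "C_LRK"),
            (["PKINASE"], "none"),
            (["LEC_LEGUME"], "none"),
            ([], "none"),
            (["SLG", "PAN_APPLE"], "none"),
        ],
    )
    def test_kinase_lectin_conjunction_rule(self, domains_present, expected):
        hits = [_hit(d) for d in domains_present]
        assert classify_family(hits, "g").family == expected

    def test_accessory_domains_kept_but_do_not_change_class(self):
        hits = [_hit("PKINASE", start=300, end=369), _hit("LEC_BULB"),
                _hit("SLG", start=60, end=99), _hit("PAN_APPLE", start=110, end=145)]
        a = classify_family(hits, "g")
        assert a.family == "B_LRK"
        assert len(a.evidence) == 4

    def test_dual_lectin_resolved_by_score_with_warning(self):
        hits = [_hit("PKINASE"), _hit("LEC_LEGUME", score=90),
                _hit("LEC_BULB", score=120)]
        with pytest.warns(UserWarning, match="multiple lectin"):
            a = classify_family(hits, "g")
        assert a.family == "B_LRK"
        assert a.ambiguous

    def test_pure_function_of_hit_set(self, rng):
        hits = [_hit("PKINASE"), _hit("LEC_LEGUME"), _hit("SLG")]
        base = classify_family(hits, "g").family
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            assert classify_family(perm, "g").family == base

    def test_synthetic_genome_fully_recovered(self, small_sim, models):
        assignments = classify_proteins(small_sim.genome_a.proteins(), models)
        for gid, a in assignments.items():
            assert a.family == small_sim.truth.families[gid]


class TestMwPi:
    def test_gg_is_two_glycines_plus_water(self):
        mw, _ = compute_mw_pi("GG")
        assert mw == pytest.approx(2 * 57.0519 + 18.0153, abs=0.05)

    def test_mw_additivity(self):
        a, b = "MKVLW", "HEDGY"
        mwa, _ = compute_mw_pi(a)
        mwb, _ = compute_mw_pi(b)
        mwab, _ = compute_mw_pi(a + b)
        water = 18.0153
        assert mwab == pytest.approx(mwa + mwb - water, abs=0.05)

    def test_basic_peptide_has_higher_pi_than_acidic(self):
        _, pi_k = compute_mw_pi("KKKKKKKK")
        _, pi_d = compute_mw_pi("DDDDDDDD")
        assert pi_k > 9 > 5 > pi_d

    def test_net_charge_is_zero_at_pi(self, rng):
        """Bisection result agrees with direct charge evaluation."""
        for _ in range(100):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
            _, pi = compute_mw_pi(pep)
            assert abs(net_charge(pep, pi)) < 0.05

    def test_cross_check_against_biopython(self, rng):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        for _ in range(20):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
            _, pi = compute_mw_pi(pep)
            assert pi == pytest.approx(IsoelectricPoint(pep).pi(), abs=1.0)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            compute_mw_pi("MKXL")


class TestDomainStats:
    def test_single_assignment_mean_is_hit_length(self):
        a = classify_family(
            [_hit("PKINASE", start=300, end=532), _hit("LEC_LEGUME", start=10, end=217)],
            "g",
        )
        df = domain_length_stats([a])
        row = df[df["family"] == "L_LRK"].iloc[0]
        assert row["mean_lectin_len"] == 208
        assert row["mean_kinase_len"] == 233

    def test_mean_of_two_hits(self):
        a1 = classify_family([_hit("PKINASE"), _hit("LEC_BULB", start=1, end=100)], "g1")
        a2 = classify_family([_hit("PKINASE"), _hit("LEC_BULB", start=1, end=120)], "g2")
        df = domain_length_stats([a1, a2])
        assert df[df["family"] == "B_LRK"].iloc[0]["mean_lectin_len"] == 110

    def test_empty_family_omitted(self):
        a = classify_family([_hit("PKINASE"), _hit("LEC_LEGUME", end=60)], "g")
        df = domain_length_stats([a])
        assert set(df["family"]) == {"L_LRK"}


class TestPssmIO:
    def test_save_load_round_trip(self, tmp_path):
        m = pssm_from_consensus("TESTDOM", "MKVLWAALHE")
        p = tmp_path / "t.pssm"
        save_pssm(m, p)
        back = load_pssm(p)
        assert back.domain_id == "TESTDOM"
        assert back.min_score == m.min_score
        assert np.array_equal(back.pssm, m.pssm)
        assert back.consensus == "MKVLWAALHE"

    def test_hits_table_round_trip(self):
        hits = [_hit("PKINASE"), _hit("LEC_C", start=60, end=113)]
        back = hits_from_table(hits_to_table(hits))
        assert back["g"] == hits
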