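import numpy as np
import pytest

from exprkit import NucSeq, ProtSeq, SequenceError, translate
from exprkit.solubility import (DEFAULT_SOLUBILITY_MODEL, FLEX_SCALE,
                                GRAVY_SCALE, ProteinRegion, ResidueScale,
                                SolubilityModel, compare_tags,
                                extend_region_search, flexibility_profile,
                                gravy, load_domain_table, load_tag_library,
                                p_sol, p_sol_from_swi, region_report, swi)

# explicit test configuration so expected values are self-contained
TEST_WEIGHTS = {aa: 0.5 for aa in "ACDEFGHILMNPQSTVWY"} | {"K": 0.8, "R": 0.6}
TEST_MODEL = SolubilityModel(swi_weights=TEST_WEIGHTS, logistic_a=10.0,
                             logistic_b=-6.0)


class TestSWI:
    def test_homopolymer_equals_residue_weight(self):
        assert swi(ProtSeq("KKKK"), TEST_MODEL) == pytest.approx(0.8)

    def test_two_residue_mean(self):
        assert swi(ProtSeq("KR"), TEST_MODEL) == pytest.approx(0.7)

    def test_matches_positionwise_sum_oracle(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
        expected = sum(DEFAULT_SOLUBILITY_MODEL.swi_weights[aa]
                       for aa in seq) / 50
        assert swi(ProtSeq(seq)) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant(self):
        assert swi(ProtSeq("KRDE")) == pytest.approx(swi(ProtSeq("EDRK")))

    def test_missing_weight_errors(self):
        broken = dict(TEST_WEIGHTS)
        with pytest.raises(ValueError):
            SolubilityModel(swi_weights={k: v for k, v in broken.items()
                                         if k != "W"})


class TestPSol:
    def test_logistic_midpoint(self):
        swi_mid = -TEST_MODEL.logistic_b / TEST_MODEL.logistic_a
        assert p_sol_from_swi(swi_mid, TEST_MODEL) == pytest.approx(0.5)

    def test_strictly_increasing_in_swi(self):
        grid = np.linspace(0, 1, 50)
        ps = [p_sol_from_swi(s, TEST_MODEL) for s in grid]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_steep_slope_approaches_step(self):
        steep = SolubilityModel(swi_weights=TEST_WEIGHTS, logistic_a=1e4,
                                logistic_b=-5e3)
        assert p_sol_from_swi(0.4, steep) < 1e-9
        assert p_sol_from_swi(0.6, steep) > 1 - 1e-9

    def test_nucleotide_path_equals_protein_path(self):
        cds = NucSeq("ATGAAACGTGATGAA")
        prot = translate(cds)
        assert p_sol(prot) == p_sol(ProtSeq(prot.residues))


class TestGravy:
    def test_ala_homopolymer(self):
        assert gravy(ProtSeq("AAA")) == pytest.approx(1.8)

    def test_scale_ordering(self):
        assert gravy(ProtSeq("III")) > gravy(ProtSeq("AAA")) > gravy(ProtSeq("RRR"))

    def test_single_residue(self):
        assert gravy(ProtSeq("W")) == pytest.approx(GRAVY_SCALE["W"])

    def test_matches_biopython_cross_check(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        assert gravy(ProtSeq(seq)) == pytest.approx(
            ProteinAnalysis(seq).gravy(), abs=1e-9)


class TestFlexibility:
    def test_homopolymer_profile_is_constant(self):
        prof = flexibility_profile(ProtSeq("G" * 15))
        assert np.allclose(prof, FLEX_SCALE["G"])

    def test_series_length(self):
        assert len(flexibility_profile(ProtSeq("A" * 20), window=9)) == 12

    def test_matches_window_mean_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
        prof = flexibility_profile(ProtSeq(seq), window=9)
        for k in range(len(prof)):
            expected = np.mean([FLEX_SCALE[aa] for aa in seq[k:k + 9]])
            assert prof[k] == pytest.approx(expected, abs=1e-12)

    def test_too_short_errors_with_suggestion(self):
        with pytest.raises(SequenceError, match="smaller window"):
            flexibility_profile(ProtSeq("MKV"))


def _exhaustive_best_superset(prot, region, model):
    L = len(prot)
    best = None
    for l in range(1, region.start + 1):
        for r in range(region.end, L + 1):
            if (l, r) == (region.start, region.end):
                continue
            p = p_sol(ProteinRegion(l, r).slice(prot), model)
            if best is None or p > best[0]:
                best = (p, l, r)
    return best


class TestExtendRegionSearch:
    def test_whole_protein_region_returns_empty(self):
        prot = ProtSeq("MKVLKRDDEE")
        assert extend_region_search(prot, ProteinRegion(1, 10)) == []

    def test_top_result_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            L = int(rng.integers(20, 61))
            prot = ProtSeq("".join(rng.choice(
                list("ACDEFGHIKLMNPQRSTVWY"), size=L)))
            a = int(rng.integers(5, L // 2))
            region = ProteinRegion(a, a + int(rng.integers(3, L - a)))
            reports = extend_region_search(prot, region)
            best = _exhaustive_best_superset(prot, region, DEFAULT_SOLUBILITY_MODEL)
            base = p_sol(region.slice(prot))
            if best[0] <= base:
                assert reports == []
            else:
                assert reports[0].p_sol == pytest.approx(best[0], abs=1e-12)
                assert (reports[0].region.start, reports[0].region.end) == \
                    (best[1], best[2])

    def test_all_results_strict_supersets_with_improvement(self):
        rng = np.random.default_rng(4)
        prot = ProtSeq("".join(rng.choice(
            list("ACDEFGHIKLMNPQRSTVWY"), size=200)))
        region = ProteinRegion(80, 120)
        base = p_sol(region.slice(prot))
        for rep in extend_region_search(prot, region, seed=1, max_results=20):
            assert rep.region.contains(region)
            assert rep.region != region
            assert rep.p_sol > base

    def test_annealing_path_used_on_large_proteins(self):
        # superset space > exhaustive limit: still returns valid improvements
        rng = np.random.default_rng(5)
        prot = ProtSeq("".join(rng.choice(
            list("ACDEFGHIKLMNPQRSTVWY"), size=400)))
        region = ProteinRegion(200, 210)
        reports = extend_region_search(prot, region, seed=2)
        base = p_sol(region.slice(prot))
        assert all(r.p_sol > base for r in reports)


class TestCompareTags:
    def test_untagged_baseline_present(self):
        out = compare_tags(ProtSeq("MKVLKR"), model=TEST_MODEL,
                           tags={"T1": ProtSeq("KKKK")})
        assert out["untagged"] == pytest.approx(p_sol(ProtSeq("MKVLKR"), TEST_MODEL))

    def test_high_weight_tag_raises_p_sol(self):
        region = ProtSeq("FFFF")  # weight 0.5 under test config
        out = compare_tags(region, model=TEST_MODEL,
                           tags={"K4": ProtSeq("KKKK")})  # weight 0.8
        assert out["K4"] > out["untagged"]

    def test_matches_direct_concat_oracle(self):
        region = ProtSeq("MKVDE")
        tags = load_tag_library()
        out = compare_tags(region, tags=tags)
        for name, tag in tags.items():
            assert out[name] == pytest.approx(
                p_sol(ProtSeq(tag.residues + region.residues)), abs=1e-12)

    def test_user_fusion_included(self):
        out = compare_tags(ProtSeq("MKV"), tags={}, model=TEST_MODEL,
                           extra_fusions={"mine": ProtSeq("KKKMKV")})
        assert "mine" in out

    def test_bundled_library_has_expected_tags(self):
        assert set(load_tag_library()) == {"TRX", "MBP", "SUMO", "GST"}


class TestDomainTable:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("PF00069 12 270 kinase domain\n")
        assert load_domain_table(p) == [("PF00069", 12, 270, "kinase domain")]

    def test_overlapping_domains_accepted(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A 1 50 x\nB 40 80 y\n")
        assert len(load_domain_table(p)) == 2

    def test_reversed_interval_errors(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A 50 10 x\n")
        with pytest.raises(SequenceError):
            load_domain_table(p)

    def test_out_of_protein_coordinates_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A 1 500 x\n")
        with pytest.raises(SequenceError):
            load_domain_table(p, protein_length=100)


def test_region_report_fields_consistent():
    prot = ProtSeq("MKVLKRDDEEAGHIKLMNPQ")
    rep = region_report(prot, ProteinRegion(3, 18))
    sub = ProteinRegion(3, 18).slice(prot)
    assert rep.swi == pytest.approx(swi(sub))
    assert rep.p_sol == pytest.approx(p_sol(sub))
    assert rep.gravy == pytest.approx(gravy(sub))
    assert 0 <= rep.p_sol <= 1
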