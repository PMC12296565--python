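import numpy as np
import pytest

from agarcode.alignio import SampleMetadata
from agarcode.diagnostics import (
    DiagnosticKey,
    KeyRule,
    MappingError,
    UNRESOLVED_CHINESE,
    classify_panel,
    classify_sample,
    default_key,
    load_key,
    map_to_reference,
    reference_alignment,
    reference_consensus,
    scan_diagnostic_sites,
)
from agarcode.synthgen import (
    PlantedSite,
    SpeciesSpec,
    SynthConfig,
    generate_alignment,
    make_paperlike_panel,
)

from conftest import make_alignment

_BASES = "ACGT"


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(comp[c] for c in reversed(seq))


class TestScan:
    def test_invariant_alignment_yields_nothing(self):
        aln = make_alignment(["ACGT" * 5] * 6, species=("x",) * 3 + ("y",) * 3)
        assert scan_diagnostic_sites(aln, "x") == []

    def test_planted_strict_sites_recovered_exactly(self):
        cfg = SynthConfig(
            marker="other", length=400,
            species=(SpeciesSpec("X", 4), SpeciesSpec("Y", 4), SpeciesSpec("Z", 4)),
            theta_intra=0.0, theta_inter=0.0,
            diagnostics=(
                PlantedSite(50, ("X",), "C"),
                PlantedSite(120, ("X",), "G"),
                PlantedSite(333, ("X",), "T"),
            ),
            seed=21,
        )
        aln, truth = generate_alignment(cfg)
        sites = scan_diagnostic_sites(aln, "X", mode="strict", tau=0.0)
        assert [(s.position, s.state) for s in sites] == [(50, "C"), (120, "G"), (333, "T")]
        for s in sites:
            assert s.coverage == 1.0 and s.exclusivity == 1.0

    def test_matches_brute_force_recount(self):
        """Strict scan equals the per-column disjoint-partition recount."""
        cfg = SynthConfig(
            marker="other", length=300,
            species=(SpeciesSpec("X", 5), SpeciesSpec("Y", 5)),
            theta_intra=0.004, theta_inter=0.05, seed=5,
        )
        aln, _ = generate_alignment(cfg)
        got = {s.position for s in scan_diagnostic_sites(aln, "X", mode="strict")}
        expected = set()
        xs = [s for s, sp in zip(aln.seqs, aln.species) if sp == "X"]
        ys = [s for s, sp in zip(aln.seqs, aln.species) if sp != "X"]
        for col in range(aln.length):
            colx = {s[col] for s in xs}
            coly = {s[col] for s in ys}
            if any(c not in "ACGT" for s in aln.seqs for c in s[col]):
                continue
            if len(colx) == 1 and colx.isdisjoint(coly):
                expected.add(col + 1)
        assert got == expected

    def test_near_mode_tolerates_one_off(self):
        seqs = (
            ["A" * 20] * 9 + ["A" * 10 + "G" + "A" * 9]  # one group member off
            + ["A" * 10 + "G" + "A" * 9] * 10  # complement fixed G at column 11
        )
        # group X: fixed A at col 11 except one member
        aln = make_alignment(seqs, species=("X",) * 10 + ("Y",) * 10)
        assert scan_diagnostic_sites(aln, "X", mode="strict") == []
        near = scan_diagnostic_sites(aln, "X", mode="near", tau=0.1)
        assert [(s.position, s.state) for s in near] == [(11, "A")]

    def test_reference_alignment_carries_the_chinese_origin_locus(self):
        ref = reference_alignment("matK")
        sites = scan_diagnostic_sites(ref, ("A. sinensis", "A. yunnanensis"))
        assert (249, "C") in {(s.position, s.state) for s in sites}

    def test_absent_group_is_error(self, toy_alignment):
        with pytest.raises(ValueError):
            scan_diagnostic_sites(toy_alignment, "nope")


class TestMapping:
    def test_identity_mapping(self):
        cons = reference_consensus("matK")
        colmap = map_to_reference(cons, "matK")
        assert len(colmap) == len(cons)
        assert all(colmap[i + 1] == cons[i] for i in range(len(cons)))

    def test_internal_deletion_makes_position_indeterminate(self):
        cons = reference_consensus("matK")
        query = cons[:430] + cons[440:]  # deletion spanning +435
        colmap = map_to_reference(query, "matK")
        assert 435 not in colmap
        assert colmap[100] == cons[99]

    def test_reverse_complement_auto_detected(self):
        cons = reference_consensus("matK")
        fwd = map_to_reference(cons, "matK")
        rev = map_to_reference(_revcomp(cons), "matK")
        assert fwd == rev

    def test_short_query_rejected(self):
        with pytest.raises(MappingError):
            map_to_reference("ACGT" * 10, "matK")

    def test_unrelated_query_rejected(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 600))
        with pytest.raises(MappingError, match="does not match"):
            map_to_reference(junk, "matK")


def _query_with(states: dict[int, str], marker: str = "matK") -> str:
    cons = list(reference_consensus(marker))
    for pos, st in states.items():
        cons[pos - 1] = st
    return "".join(cons)


class TestClassifySample:
    def test_full_chinese_sinensis_key(self):
        res = classify_sample(_query_with({249: "C", 435: "G", 684: "T"}))
        assert res.species_call == "A. sinensis"
        assert res.origin_call == "Chinese mainland"
        assert res.pedigree == "C1/C2"
        assert res.conflicts == ()

    def test_chinese_origin_species_unresolved(self):
        res = classify_sample(_query_with({249: "C", 435: "A", 684: "C"}))
        assert res.origin_call == "Chinese mainland"
        assert res.species_call == UNRESOLVED_CHINESE
        assert res.pedigree == "C1/C2"

    def test_one_of_two_species_rules_is_ambiguous(self):
        res = classify_sample(_query_with({249: "T", 435: "G", 684: "C"}))
        assert res.species_call == "ambiguous"
        assert res.conflicts and res.pedigree == "unassigned"

    def test_case_and_orientation_invariance(self):
        q = _query_with({249: "C", 435: "G", 684: "T"})
        r1 = classify_sample(q)
        r2 = classify_sample(q.lower())
        r3 = classify_sample(_revcomp(q))
        assert r1.species_call == r2.species_call == r3.species_call
        assert r1.origin_call == r2.origin_call == r3.origin_call

    def test_trnl_refinement_sets_origin_without_species(self):
        matk = _query_with({249: "T", 435: "A", 684: "C"})
        trnl = _query_with({173: "A", 183: "T", 200: "G"}, marker="trnL-trnF")
        res = classify_sample(matk, trnl)
        assert res.origin_call == "Indonesia"
        assert res.pedigree == "B"
        assert res.species_call == "unresolved"

    def test_trnl_never_overrides_matk_origin(self):
        matk = _query_with({249: "C", 435: "G", 684: "T"})
        trnl = _query_with({173: "A", 183: "T", 200: "G"}, marker="trnL-trnF")
        res = classify_sample(matk, trnl)
        assert res.origin_call == "Chinese mainland"
        assert any("conflict" in c for c in res.conflicts)

    def test_abstract_pedigree_map(self):
        res = classify_sample(
            _query_with({249: "C", 435: "G", 684: "T"}), pedigree_map="abstract"
        )
        assert res.pedigree == "C1"

    def test_deletion_over_all_key_loci_unclassifiable(self):
        cons = reference_consensus("matK")
        # keep only the first 200 columns: all key loci missing
        res = classify_sample(cons[:200] + "A" * 0, trnlf_query=None)
        # query shorter than reference but >=100: positions 249/435/684 absent
        assert res.species_call in ("unclassifiable", "unresolved")

    def test_key_soundness_round_trip(self):
        """Sequences synthesized from the key's expected states classify to
        the key's conclusions."""
        key = default_key()
        states = {
            r.position: r.state for r in key.rules if r.marker == "matK" and r.tier in ("species", "origin")
        }
        res = classify_sample(_query_with(states), key=key)
        assert res.species_call == "A. sinensis"
        assert res.origin_call == "Chinese mainland"


class TestKeyFile:
    def test_default_key_contents(self):
        key = default_key()
        by_pos = {(r.marker, r.position): r for r in key.rules}
        assert by_pos[("matK", 249)].state == "C"
        assert by_pos[("matK", 435)].state == "G"
        assert by_pos[("matK", 684)].state == "T"
        assert {r.position for r in key.tier("refine", "trnL-trnF")} == {173, 183, 200}
        assert {r.position for r in key.tier("cluster", "matK")} == {
            58, 124, 232, 261, 338, 373, 559,
        }

    def test_duplicate_rule_rejected(self):
        with pytest.raises(ValueError):
            DiagnosticKey(
                rules=(
                    KeyRule("matK", 249, "C", "origin", "x"),
                    KeyRule("matK", 249, "T", "origin", "y"),
                )
            )

    def test_editable_key_round_trip(self, tmp_path):
        path = tmp_path / "key.tsv"
        path.write_text(
            "marker\tposition\tstate\ttier\tlabel\nmatK\t435\tG\tspecies\tA. sinensis\nmatK\t684\tT\tspecies\tA. sinensis\n"
        )
        key = load_key(path)
        assert len(key.rules) == 2
        res = classify_sample(_query_with({435: "G", 684: "T"}), key=key)
        assert res.species_call == "A. sinensis"


class TestPanel:
    def test_synthetic_keyed_panel_fractions(self):
        samples, truth = make_paperlike_panel(3, 0, 0, seed=1)
        results, table, agg = classify_panel(samples)
        assert agg["n_chinese"] == 3 and agg["chinese_fraction"] == 1.0

    def test_paperlike_proportions(self):
        samples, truth = make_paperlike_panel(22, 6, 6, seed=0)
        results, table, agg = classify_panel(samples)
        assert agg["n_samples"] == 34
        assert agg["n_chinese"] == 22
        for r in results:
            assert r.origin_call == truth[r.sample_id]

    def test_no_chinese_when_none_keyed(self):
        samples, _ = make_paperlike_panel(0, 0, 2, seed=3)
        _, _, agg = classify_panel(samples)
        assert agg["n_chinese"] == 0

    def test_broken_sample_isolated(self):
        samples, _ = make_paperlike_panel(2, 0, 0, seed=4)
        samples.append((SampleMetadata(id="broken"), "", None))
        results, table, agg = classify_panel(samples)
        assert agg["n_samples"] == 3 and agg["n_chinese"] == 2
        broken = [r for r in results if r.sample_id == "broken"][0]
        assert broken.species_call == "unclassifiable"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            classify_panel([])
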