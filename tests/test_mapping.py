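"""Per-residue aggregation and PDB B-factor painting."""

import numpy as np
import pytest

from calascan import (GroundTruthModel, LibraryDesign, MalformedPDBError,
                      build_residue_map, call_substitutions, call_phenotypes,
                      classify, part_enrichment, read_bfactors,
                      simulate_halo_observations, simulate_library,
                      write_bfactor_pdb)
from calascan.calling import SubstitutionCall, VariantRecord
from calascan.mapping import ResidueEntry, ResidueMap
from calascan.synth import toy_pdb


def record(clone_id, positions, qc="ok"):
    subs = [SubstitutionCall(p, "A", "V", "GCT", "GTT", "Part2") for p in positions]
    return VariantRecord(clone_id, "L", dna="", dna_mutation_count=len(subs),
                         substitutions=subs, qc_status=qc)


class TestBuildResidueMap:
    def test_max_rule_over_supporting_variants(self):
        records = [record("lo", [230]), record("hi", [230])]
        calls = [classify(2, 0, clone_id="lo"), classify(4, 0, clone_id="hi")]
        rmap = build_residue_map(records, calls)
        assert rmap.entries[230].activity_short == 4
        assert rmap.entries[230].n_supporting_variants == 2

    def test_opposite_phenotypes_give_both_category(self):
        records = [record("s", [265]), record("l", [265])]
        calls = [classify(4, 0, clone_id="s"), classify(0, 4, clone_id="l")]
        rmap = build_residue_map(records, calls)
        assert rmap.entries[265].category == "both"

    def test_unmapped_residue_uses_background(self):
        rmap = build_residue_map([], [])
        assert rmap.value(123, "short") == 0.0
        assert rmap.value(123, "category") == 0.0

    def test_multi_substitution_variant_paints_every_residue(self):
        records = [record("m", [220, 300])]
        calls = [classify(4, 0, clone_id="m")]
        rmap = build_residue_map(records, calls)
        assert rmap.entries[220].category == "short"
        assert rmap.entries[300].category == "short"
        assert rmap.entries[220].n_single_sub_variants == 0

    def test_order_independence(self):
        records = [record(f"c{i}", [210 + i % 5]) for i in range(10)]
        calls = [classify((i % 5), 0, clone_id=f"c{i}") for i in range(10)]
        fwd = build_residue_map(records, calls)
        rev = build_residue_map(records[::-1], calls[::-1])
        assert {r: (e.activity_short, e.category) for r, e in fwd.entries.items()} == \
               {r: (e.activity_short, e.category) for r, e in rev.entries.items()}

    def test_adding_a_variant_never_lowers_values(self):
        base = build_residue_map([record("a", [230])], [classify(3, 0, clone_id="a")])
        more = build_residue_map(
            [record("a", [230]), record("b", [230])],
            [classify(3, 0, clone_id="a"), classify(1, 0, clone_id="b")])
        assert more.entries[230].activity_short >= base.entries[230].activity_short

    def test_missing_call_rejected_with_id(self):
        with pytest.raises(KeyError, match="orphan"):
            build_residue_map([record("orphan", [230])], [])

    def test_non_ok_record_rejected(self):
        with pytest.raises(ValueError, match="frameshift"):
            build_residue_map([record("x", [], qc="frameshift")],
                              [classify(3, 3, clone_id="x")])


class TestPartEnrichment:
    def test_empty_map_gives_zero_counts(self, gene):
        enr = part_enrichment(build_residue_map([], []), gene)
        assert all(v == 0 for counts in enr.counts.values() for v in counts.values())
        assert enr.top_windows["short"][2] == 0

    def test_distinct_positions_counted_once(self, gene):
        records = [record("a", [230]), record("b", [230]), record("c", [260])]
        calls = [classify(4, 0, clone_id=c) for c in "abc"]
        enr = part_enrichment(build_residue_map(records, calls), gene)
        assert enr.counts["Part2"]["short"] == 2   # 230 and 260, repetition excluded

    def test_synthetic_campaign_recovers_hotspot(self, gene):
        """Part 2 dominates short discrimination; top window overlaps 217-245."""
        truth = GroundTruthModel(noise_prob=0.1)
        design = LibraryDesign("Random2", ("Part2",), "random", rate_per_kb=4.1)
        rng = np.random.default_rng(2024)
        clones = simulate_library(design, gene, 384, rng)
        observations = simulate_halo_observations(clones, truth, rng)
        records = [call_substitutions(c.dna, gene, clone_id=c.clone_id,
                                      library_id="Random2") for c in clones]
        calls = call_phenotypes(observations)
        call_by_id = {c.clone_id: c for c in calls}
        ok = [r for r in records if r.qc_status == "ok"]
        rmap = build_residue_map(ok, [call_by_id[r.clone_id] for r in ok])
        enr = part_enrichment(rmap, gene)
        short_by_part = {p: c["short"] + c["both"] for p, c in enr.counts.items()}
        assert max(short_by_part, key=short_by_part.get) == "Part2"
        start, end, _ = enr.top_windows["short"]
        assert start <= 245 and end >= 217   # overlap with the true hotspot


class TestBFactorWriter:
    def _map(self, values):
        rmap = ResidueMap()
        for residue, v in values.items():
            rmap.entries[residue] = ResidueEntry(activity_short=v, activity_long=0)
        return rmap

    def test_mapped_residue_painted_others_background(self):
        pdb = toy_pdb(3)
        out = write_bfactor_pdb(pdb, self._map({2: 4}), channel="short")
        values = read_bfactors(out)
        assert values[("A", 2)] == {4.0}
        assert values[("A", 1)] == values[("A", 3)] == {0.0}

    def test_byte_diff_limited_to_bfactor_columns(self):
        pdb = toy_pdb(5, b_factor=37.25)
        out = write_bfactor_pdb(pdb, self._map({3: 2}), channel="short")
        for before, after in zip(pdb.splitlines(), out.splitlines()):
            if before.startswith(("ATOM", "HETATM")):
                assert before[:60] == after[:60]
                assert before[66:] == after[66:]
            else:
                assert before == after

    def test_write_then_parse_round_trip(self):
        pdb = toy_pdb(4)
        rmap = self._map({1: 1, 2: 3, 4: 4})
        out = write_bfactor_pdb(pdb, rmap, channel="short")
        values = read_bfactors(out)
        for residue in range(1, 5):
            assert values[("A", residue)] == {rmap.value(residue, "short")}

    def test_empty_map_sets_background_everywhere(self):
        out = write_bfactor_pdb(toy_pdb(3), ResidueMap(background_value=0.5))
        assert set().union(*read_bfactors(out).values()) == {0.5}

    def test_gemmi_oracle_agrees(self, tmp_path):
        """Independent PDB reader sees the values we wrote."""
        gemmi = pytest.importorskip("gemmi")
        out = write_bfactor_pdb(toy_pdb(3), self._map({2: 4}), channel="short")
        path = tmp_path / "toy.pdb"
        path.write_text(out)
        st = gemmi.read_structure(str(path))
        got = {res.seqid.num: {a.b_iso for a in res} for res in st[0]["A"]}
        assert got == {1: {0.0}, 2: {4.0}, 3: {0.0}}

    def test_category_channel_encoding(self):
        rmap = ResidueMap()
        rmap.entries[1] = ResidueEntry(_short=True)
        rmap.entries[2] = ResidueEntry(_long=True)
        rmap.entries[3] = ResidueEntry(_short=True, _long=True)
        out = write_bfactor_pdb(toy_pdb(4), rmap, channel="category")
        values = read_bfactors(out)
        assert [values[("A", i)] for i in range(1, 5)] == \
            [{1.0}, {2.0}, {3.0}, {0.0}]

    def test_multi_chain_requires_selector(self):
        pdb = toy_pdb(2, extra_chain="B")
        with pytest.raises(ValueError, match="chain"):
            write_bfactor_pdb(pdb, self._map({1: 2}))
        out = write_bfactor_pdb(pdb, self._map({1: 2}), chain="A")
        values = read_bfactors(out)
        assert values[("A", 1)] == {2.0}
        assert values[("B", 1)] == {0.0}

    def test_malformed_line_rejected_with_line_number(self):
        bad = "ATOM      1  CA  ALA A   1\n"
        with pytest.raises(MalformedPDBError, match="line 1"):
            write_bfactor_pdb(bad, ResidueMap())

    def test_insertion_codes_rejected(self):
        line = toy_pdb(1).splitlines()[1]
        bad = line[:26] + "A" + line[27:] + "\n"
        with pytest.raises(MalformedPDBError, match="insertion"):
            write_bfactor_pdb(bad, ResidueMap())
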