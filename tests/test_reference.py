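"""Reference gene model: codon expansion, assembly, load arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from calascan import (AssemblyError, FrameError, LibraryDesign, PartSequence,
                      additivity_check, assemble_parts, cal_a_reference,
                      expand_degenerate_codon, expected_mutations_per_gene,
                      round_half_up)
from calascan.reference import IUPAC_NUCLEOTIDES

NDT_AA = set("FLIVYHNDCRSG")  # the 12 amino acids of the NDT reduced alphabet


class TestDegenerateCodons:
    def test_ndt_expands_to_12_codons_12_amino_acids_no_stops(self):
        exp = expand_degenerate_codon("NDT")
        assert exp.n_codons == 12
        assert exp.amino_acids == frozenset(NDT_AA)
        assert exp.stop_codons == ()

    @pytest.mark.parametrize("triplet, n_codons, n_aa, n_stops", [
        ("TTT", 1, 1, 0),       # no ambiguity
        ("NNN", 64, 20, 3),     # full genetic code
        ("NNK", 32, 20, 1),     # common saturation alphabet
    ])
    def test_expansion_counts(self, triplet, n_codons, n_aa, n_stops):
        exp = expand_degenerate_codon(triplet)
        assert (exp.n_codons, exp.n_amino_acids, len(exp.stop_codons)) == \
            (n_codons, n_aa, n_stops)

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            expand_degenerate_codon("NXT")
        with pytest.raises(ValueError):
            expand_degenerate_codon("ND")

    @given(st.text(alphabet=sorted(IUPAC_NUCLEOTIDES), min_size=3, max_size=3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_expansion_size_is_product_of_cardinalities(self, triplet):
        exp = expand_degenerate_codon(triplet)
        expected = 1
        for letter in triplet:
            expected *= len(IUPAC_NUCLEOTIDES[letter])
        assert exp.n_codons == expected
        assert len(set(exp.codons)) == exp.n_codons


class TestAssembly:
    def _tagged_parts(self, lengths=(605, 420, 286)):
        import numpy as np
        rng = np.random.default_rng(5)
        tags = ["AATG", "CCTA", "GGAT", "TTCG"]
        return [
            PartSequence(f"P{i+1}", "".join(rng.choice(list("ACGT"), size=n)),
                         tags[i], tags[i + 1])
            for i, n in enumerate(lengths)
        ]

    def test_reported_part_lengths_assemble_to_1311_bp(self):
        parts = self._tagged_parts()
        cds = assemble_parts(parts)
        assert len(cds) == 1311
        # each part's interior is byte-identical in the product
        offset = 0
        for part in parts:
            assert cds[offset:offset + len(part.seq)] == part.seq
            offset += len(part.seq)

    def test_single_part_is_identity(self):
        part = PartSequence("solo", "ATGGCT", "AATG", "TTCG")
        assert assemble_parts([part]) == "ATGGCT"

    def test_mutated_part_changes_only_its_own_range(self, gene):
        parts = gene.part_sequences()
        mutated = parts[1].seq[:100] + "A" + parts[1].seq[101:]
        if mutated == parts[1].seq:
            mutated = parts[1].seq[:100] + "C" + parts[1].seq[101:]
        parts[1] = PartSequence(parts[1].part_id, mutated,
                                parts[1].junction_5, parts[1].junction_3)
        cds = assemble_parts(parts)
        lo, hi = gene.cds_span("Part2")
        diff = [i for i, (a, b) in enumerate(zip(gene.cds, cds)) if a != b]
        assert diff and all(lo <= i < hi for i in diff)

    def test_junction_mismatch_names_offender(self):
        parts = self._tagged_parts()
        bad = PartSequence(parts[1].part_id, parts[1].seq, "TTTT", parts[1].junction_3)
        with pytest.raises(AssemblyError, match="P1.*P2"):
            assemble_parts([parts[0], bad, parts[2]])

    def test_out_of_frame_product_rejected(self):
        a = PartSequence("a", "ATGG", "AATG", "CCTA")
        b = PartSequence("b", "CTTT", "CCTA", "GGAT")
        with pytest.raises(FrameError):
            assemble_parts([a, b])

    def test_assembly_is_associative_over_adjacent_merges(self):
        parts = self._tagged_parts((99, 150, 51))
        whole = assemble_parts(parts)
        left = assemble_parts(parts[:2])
        merged = PartSequence("P12", left, parts[0].junction_5, parts[1].junction_3)
        assert assemble_parts([merged, parts[2]]) == whole


class TestMutationalLoad:
    @pytest.mark.parametrize("library, rate, bp, expected", [
        ("Random1", 2.1, 605, 1.3),
        ("Random2", 4.1, 420, 1.7),
        ("RandomTot", 4.2, 1311, 5.5),
        ("RandomRec", 3.0, 1311, 3.9),
    ])
    def test_per_gene_load_from_per_kb_rate(self, gene, library, rate, bp, expected):
        from calascan import CAL_A_LIBRARY_DESIGNS
        design = CAL_A_LIBRARY_DESIGNS[library]
        assert design.mutated_load_bp(gene) == bp
        assert expected_mutations_per_gene(design, gene) == pytest.approx(expected)

    def test_zero_rate_gives_zero_load(self, gene):
        design = LibraryDesign("null", ("Part1",), "random", rate_per_kb=0.0)
        assert expected_mutations_per_gene(design, gene) == 0.0

    def test_recombined_load_is_additive_over_parts(self):
        # recombining independently mutagenized parts sums their loads
        assert additivity_check([1.3, 1.7, 1.0]) == pytest.approx(4.0)

    @given(rate=st.floats(0.0, 20.0, allow_nan=False),)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_load_additivity_property(self, rate):
        gene = cal_a_reference()
        parts = ("Part1", "Part2", "Part3")
        whole = LibraryDesign("w", parts, "random", rate_per_kb=rate)
        total = expected_mutations_per_gene(whole, gene, rounded=False)
        summed = sum(
            expected_mutations_per_gene(
                LibraryDesign(p, (p,), "random", rate_per_kb=rate), gene, rounded=False)
            for p in parts
        )
        assert total == pytest.approx(summed)

    def test_ndt_mode_rejected(self, gene):
        design = LibraryDesign("sat", ("Part1",), "ndt_saturation",
                               target_positions=(93,))
        with pytest.raises(ValueError, match="random"):
            expected_mutations_per_gene(design, gene)


class TestGeneGeometry:
    def test_parts_tile_residues_1_to_446(self, gene):
        covered = []
        for part in gene.parts:
            covered.extend(range(part.residue_range[0], part.residue_range[1] + 1))
        assert covered == list(range(1, 447))
        assert [p.n_residues for p in gene.parts] == [210, 140, 96]

    def test_translated_length_matches_cds(self, gene):
        assert len(gene.protein) * 3 == len(gene.cds)
        assert "*" not in gene.protein

    def test_annotated_residue_identities(self, gene):
        protein = gene.protein
        assert protein[92] == "Y" and protein[182] == "Y" and protein[430] == "F"
        assert (protein[183], protein[333], protein[365]) == ("S", "D", "H")
        assert protein[236] == "G"  # position 237

    def test_part_bp_discrepancy_is_flagged(self, gene):
        notes = gene.geometry_warnings()
        assert any("Part1" in n and "605" in n for n in notes)
        assert any("Part3" in n and "286" in n for n in notes)

    def test_config_round_trip(self, gene, tmp_path):
        from calascan import load_reference, write_reference_config
        cfg, fasta = tmp_path / "gene.cfg", tmp_path / "gene.fasta"
        write_reference_config(gene, cfg, fasta)
        loaded = load_reference(fasta, cfg)
        assert loaded.cds == gene.cds
        assert loaded.parts == gene.parts
        assert loaded.catalytic_triad == gene.catalytic_triad


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(1.25, 1) == 1.3
    assert round_half_up(1.27, 1) == 1.3
    assert round_half_up(0.94, 1) == 0.9
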