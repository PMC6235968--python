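import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmquantkit import assay_design as ad
from prmquantkit.masses import (
    HEAVY_K_DELTA,
    HEAVY_R_DELTA,
    PROTON,
    RESIDUE_MASSES,
    WATER,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# digest_protein
# ---------------------------------------------------------------------------


class TestDigestProtein:
    def test_tryptic_example(self):
        entry = ad.ProteinEntry("X", "MKDSSFNSAYNLPIPRVLPESVSRK")
        peptides = [c.sequence for c in ad.digest_protein(entry, 0)]
        assert peptides == ["MK", "DSSFNSAYNLPIPR", "VLPESVSR", "K"]

    def test_proline_blocks_cleavage(self):
        entry = ad.ProteinEntry("X", "AAAKPGGGR")
        peptides = [c.sequence for c in ad.digest_protein(entry, 0)]
        assert peptides == ["AAAKPGGGR"]

    def test_no_internal_site_with_missed_cleavage(self):
        entry = ad.ProteinEntry("X", "GGGGGGR")
        peptides = [c.sequence for c in ad.digest_protein(entry, 1)]
        assert peptides == ["GGGGGGR"]

    def test_missed_cleavage_products(self):
        entry = ad.ProteinEntry("X", "AAKGGRDD")
        got = {(c.sequence, c.missed_cleavages)
               for c in ad.digest_protein(entry, 1)}
        assert got == {("AAK", 0), ("GGR", 0), ("DD", 0),
                       ("AAKGGR", 1), ("GGRDD", 1)}

    def test_positions_are_one_based_inclusive(self):
        entry = ad.ProteinEntry("X", "MKDSSFNSAYNLPIPRVLPESVSRK")
        first = ad.digest_protein(entry, 0)[0]
        assert (first.start, first.end) == (1, 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ad.ProteinEntry("X", "")

    def test_negative_missed_cleavages_rejected(self):
        with pytest.raises(ValueError):
            ad.digest_protein(ad.ProteinEntry("X", "GGR"), -1)

    @given(sequences)
    @settings(max_examples=200, deadline=None)
    def test_digestion_partitions_sequence(self, seq):
        entry = ad.ProteinEntry("X", seq)
        peptides = [c.sequence for c in ad.digest_protein(entry, 0)]
        assert "".join(peptides) == seq

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_internal_cleavage_sites_respected(self, seq):
        for cand in ad.digest_protein(ad.ProteinEntry("X", seq), 0):
            internal = cand.sequence[:-1]
            for i, aa in enumerate(internal):
                if aa in "KR":
                    assert cand.sequence[i + 1] == "P"


# ---------------------------------------------------------------------------
# filter_candidates / check_uniqueness
# ---------------------------------------------------------------------------


class TestFilterCandidates:
    def _candidate(self, seq, mc=0):
        return ad.PeptideCandidate(seq, "P0", 1, len(seq), mc,
                                   ad.compute_peptide_mass(seq))

    def test_good_peptide_kept(self, toy_proteome):
        kept, rejected = ad.filter_candidates(
            [self._candidate("ISPNSPVAR")], toy_proteome)
        assert len(kept) == 1 and not rejected

    def test_short_met_peptide_rejected_with_both_reasons(self, toy_proteome):
        kept, rejected = ad.filter_candidates(
            [self._candidate("MKAAAA")], toy_proteome)
        assert not kept
        reasons = set(rejected[0].rejection_reasons)
        assert "length<7" in reasons and "contains-M" in reasons

    def test_histidine_peptide_rejected(self, toy_proteome):
        _, rejected = ad.filter_candidates(
            [self._candidate("ASASAASAETLSHR")], toy_proteome)
        assert "contains-H" in rejected[0].rejection_reasons

    def test_missed_cleavage_rejected(self, toy_proteome):
        _, rejected = ad.filter_candidates(
            [self._candidate("DSSFNSAYNLPIPRK", mc=1)], toy_proteome)
        assert "missed-cleavage" in rejected[0].rejection_reasons

    def test_partition_and_idempotence(self, toy_proteome):
        cands = [self._candidate(s) for s in
                 ("ISPNSPVAR", "MKAAAA", "DSSFNSAYNLPIPR", "GGGGGGR")]
        kept, rejected = ad.filter_candidates(cands, toy_proteome)
        assert len(kept) + len(rejected) == len(cands)
        kept2, rejected2 = ad.filter_candidates(kept + rejected, toy_proteome)
        assert {c.sequence for c in kept2} == {c.sequence for c in kept}


class TestCheckUniqueness:
    def test_unique_peptide(self, toy_proteome):
        res = ad.check_uniqueness("ISPNSPVAR", toy_proteome)
        assert res == {"unique": True, "matches": ["P2"]}

    def test_shared_peptide(self):
        proteome = [ad.ProteinEntry("A", "GGPEPTIDEKGG"),
                    ad.ProteinEntry("B", "AAPEPTIDEKAA")]
        res = ad.check_uniqueness("PEPTIDEK", proteome)
        assert res["unique"] is False and len(res["matches"]) == 2

    def test_absent_peptide_distinct_from_shared(self, toy_proteome):
        res = ad.check_uniqueness("WWWWWWW", toy_proteome)
        assert res["unique"] is False and res["matches"] == []

    def test_empty_peptide_rejected(self, toy_proteome):
        with pytest.raises(ValueError):
            ad.check_uniqueness("", toy_proteome)

    def test_il_equivalence_mode(self):
        proteome = [ad.ProteinEntry("A", "GGPEPTLDEKGG")]
        assert not ad.check_uniqueness("PEPTIDEK", proteome)["matches"]
        assert ad.check_uniqueness("PEPTIDEK", proteome,
                                   il_equivalent=True)["matches"] == ["A"]

    def test_agrees_with_substring_enumeration_oracle(self, toy_proteome, rng):
        # oracle: membership in the set of all fixed-length substrings
        for _ in range(100):
            k = int(rng.integers(2, 9))
            pep = "".join(rng.choice(list(AA), k))
            oracle_matches = [
                e.accession for e in toy_proteome
                if pep in {e.sequence[i:i + k]
                           for i in range(len(e.sequence) - k + 1)}
            ]
            res = ad.check_uniqueness(pep, toy_proteome)
            assert res["matches"] == oracle_matches
            assert res["unique"] == (len(oracle_matches) == 1)


# ---------------------------------------------------------------------------
# mass / m/z arithmetic
# ---------------------------------------------------------------------------


class TestPeptideMass:
    def test_known_nonapeptide(self):
        assert ad.compute_peptide_mass("ISPNSPVAR") == pytest.approx(
            939.5138, abs=1e-3)

    def test_single_glycine(self):
        assert ad.compute_peptide_mass("G") == pytest.approx(75.0320, abs=1e-3)

    def test_heavy_lysine_shift(self):
        light = ad.compute_peptide_mass("EGNVSISAFVAK")
        heavy = ad.compute_peptide_mass("EGNVSISAFVAK", heavy=ad.HEAVY_K)
        assert heavy - light == pytest.approx(8.0142, abs=1e-4)

    def test_modification_deltas_add(self):
        base = ad.compute_peptide_mass("ACDK")
        cam = ad.compute_peptide_mass(
            "ACDK", modifications=[ad.ModificationSpec("carbamidomethyl-C")])
        assert cam - base == pytest.approx(57.021464, abs=1e-5)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            ad.compute_peptide_mass("ABZ")

    def test_heavy_label_residue_mismatch(self):
        with pytest.raises(ValueError):
            ad.compute_peptide_mass("ISPNSPVAR", heavy=ad.HEAVY_K)

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_mass_is_sum_of_residues_plus_water(self, seq):
        expected = sum(RESIDUE_MASSES[a] for a in seq) + WATER
        assert ad.compute_peptide_mass(seq) == pytest.approx(expected)


class TestPrecursorMz:
    def test_doubly_charged_reference(self):
        mass = ad.compute_peptide_mass("ISPNSPVAR")
        assert ad.compute_precursor_mz(mass, 2) == pytest.approx(470.7642,
                                                                 abs=1e-3)

    def test_triply_charged_reference(self):
        mass = ad.compute_peptide_mass("VPLLHLSNFTNDWAELSTR")
        assert ad.compute_precursor_mz(mass, 3) == pytest.approx(738.3832,
                                                                 abs=1e-3)

    def test_zero_mass_gives_proton(self):
        assert ad.compute_precursor_mz(0.0, 2) == pytest.approx(PROTON,
                                                                abs=1e-4)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            ad.compute_precursor_mz(500.0, 0)


class TestFragmentMz:
    def test_y1_of_arginine_peptide(self):
        assert ad.compute_fragment_mz("ISPNSPVAR", "y", 1) == pytest.approx(
            175.1190, abs=1e-3)

    def test_b2_of_glycines(self):
        assert ad.compute_fragment_mz("GGGGK", "b", 2) == pytest.approx(
            115.0502, abs=1e-3)

    def test_heavy_label_shifts_y_ions_only(self):
        y5_light = ad.compute_fragment_mz("ISPNSPVAR", "y", 5)
        y5_heavy = ad.compute_fragment_mz("ISPNSPVAR", "y", 5, heavy=ad.HEAVY_R)
        assert y5_heavy - y5_light == pytest.approx(10.0083, abs=1e-3)
        b5_light = ad.compute_fragment_mz("ISPNSPVAR", "b", 5)
        b5_heavy = ad.compute_fragment_mz("ISPNSPVAR", "b", 5, heavy=ad.HEAVY_R)
        assert b5_heavy == b5_light

    def test_ordinal_out_of_range(self):
        with pytest.raises(ValueError):
            ad.compute_fragment_mz("GGR", "y", 3)

    def test_doubly_charged_fragment(self):
        y7_1 = ad.compute_fragment_mz("ISPNSPVAR", "y", 7, 1)
        y7_2 = ad.compute_fragment_mz("ISPNSPVAR", "y", 7, 2)
        assert y7_2 == pytest.approx((y7_1 + PROTON) / 2, abs=1e-3)


# ---------------------------------------------------------------------------
# the reference panel fixture
# ---------------------------------------------------------------------------


class TestReferencePanel:
    def test_cardinality(self, reference_panel):
        assert len(reference_panel) == 21
        assert len(reference_panel.proteins) == 11
        assert reference_panel.n_precursors == 42

    def test_all_precursor_mz_recomputed(self, reference_panel):
        for row in reference_panel:
            mass = ad.compute_peptide_mass(row.peptide)
            delta = ad.heavy_label_for(row.peptide).mass_delta
            assert ad.compute_precursor_mz(mass, row.charge) == pytest.approx(
                row.light_mz, abs=1e-3), row.peptide
            assert ad.compute_precursor_mz(mass + delta, row.charge) == \
                pytest.approx(row.heavy_mz, abs=1e-3), row.peptide

    def test_heavy_light_difference_matches_label(self, reference_panel):
        for row in reference_panel:
            delta = (HEAVY_K_DELTA if row.peptide.endswith("K")
                     else HEAVY_R_DELTA)
            assert row.heavy_mz - row.light_mz == pytest.approx(
                delta / row.charge, abs=1e-4), row.peptide

    def test_spike_amounts_positive(self, reference_panel):
        assert all(row.spike_fmol > 0 for row in reference_panel)

    def test_round_trip_io(self, reference_panel, tmp_path):
        path = tmp_path / "panel.csv"
        ad.save_panel(reference_panel, path)
        loaded = ad.load_panel(path)
        assert [r.peptide for r in loaded] == [r.peptide for r in reference_panel]
        assert [t.label for t in loaded.rows[0].transitions] == \
            [t.label for t in reference_panel.rows[0].transitions]

    def test_transition_list_export(self, reference_panel, tmp_path):
        path = tmp_path / "transitions.csv"
        ad.export_transition_list(reference_panel, path)
        lines = path.read_text().splitlines()
        n_transitions = sum(len(r.transitions) for r in reference_panel)
        assert len(lines) == 1 + 2 * n_transitions  # light + heavy


class TestParseIonLabel:
    @pytest.mark.parametrize("label,ion_type,ordinal,charge", [
        ("y7+", "y", 7, 1),
        ("y8++", "y", 8, 2),
        ("b12++", "b", 12, 2),
        ("p+", "p", None, 1),
        ("Y8+", "y", 8, 1),
    ])
    def test_valid(self, label, ion_type, ordinal, charge):
        t = ad.parse_ion_label(label)
        assert (t.ion_type, t.ordinal, t.product_charge) == \
            (ion_type, ordinal, charge)

    @pytest.mark.parametrize("label", ["x3+", "y+", "y7", "y7-H2O+"])
    def test_invalid(self, label):
        with pytest.raises(ValueError):
            ad.parse_ion_label(label)


# ---------------------------------------------------------------------------
# build_assay_panel
# ---------------------------------------------------------------------------


class TestBuildAssayPanel:
    def test_empty_targets_empty_panel(self, toy_proteome):
        panel = ad.build_assay_panel([], toy_proteome, {"AAAAAAK": 10.0})
        assert len(panel) == 0

    def test_two_peptides_four_precursors(self, toy_proteome):
        target = toy_proteome[0]  # contains DSSFNSAYNLPIPR and VLPESVSR
        panel = ad.build_assay_panel(
            [target], toy_proteome,
            {"DSSFNSAYNLPIPR": 15.0, "VLPESVSR": 10.0})
        assert len(panel) == 2
        assert panel.n_precursors == 4
        row = panel.row_for("VLPESVSR")
        mass = ad.compute_peptide_mass("VLPESVSR")
        assert row.light_mz == pytest.approx(
            ad.compute_precursor_mz(mass, 2), abs=1e-4)
        assert row.heavy_mz - row.light_mz == pytest.approx(
            HEAVY_R_DELTA / 2, abs=1e-4)

    def test_unknown_extra_peptide_errors(self, toy_proteome):
        with pytest.raises(ValueError, match="WWWWWWK"):
            ad.build_assay_panel([toy_proteome[0]], toy_proteome,
                                 {"WWWWWWK": 5.0}, extra_peptides=["WWWWWWK"])

    def test_nonpositive_spike_rejected(self, toy_proteome):
        with pytest.raises(ValueError):
            ad.build_assay_panel([toy_proteome[0]], toy_proteome,
                                 {"VLPESVSR": 0.0})

    def test_extra_peptide_bypasses_filters(self, toy_proteome):
        # ASASAASAETLSHR carries a histidine yet can enter via extras
        proteome = toy_proteome + [
            ad.ProteinEntry("P4", "GGKASASAASAETLSHRGG")]
        panel = ad.build_assay_panel(
            [proteome[-1]], proteome, {"ASASAASAETLSHR": 5.0},
            extra_peptides=["ASASAASAETLSHR"])
        assert panel.peptides == ["ASASAASAETLSHR"]


def test_read_fasta(tmp_path):
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(
        ">sp|Q1|ETR1 some receptor\nMKDSSFNSAY\nNLPIPR\n>Q2\nGGGGGGR\n")
    entries = ad.read_fasta(fasta)
    assert [e.accession for e in entries] == ["sp|Q1|ETR1", "Q2"]
    assert entries[0].sequence == "MKDSSFNSAYNLPIPR"
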