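"""Fragment enumeration conventions and the sulfo-linkage diagnostic logic."""

import pytest

from sulfoglyco.fragments import (
    B_END,
    NA_MINUS_H,
    SULFO_GAL_RESIDUE,
    FragmentError,
    FragmentKind,
    SulfoLinkage,
    SulfoPosition,
    annotate_msms,
    assign_sulfo_linkage,
    diagnostic_ions,
    enumerate_glycosidic_fragments,
)
from sulfoglyco.masses import (
    H,
    NA,
    O,
    PROTON,
    RESIDUE_MASSES,
    S,
    Polarity,
    ion_mz,
)
from sulfoglyco.topology import parse_topology

# Negative-mode MS/MS peak list of the mono-sulfated core-fucosylated
# biantennary precursor (its printed fragment labels).
NEGATIVE_MSMS_PEAKS = [97.0, 153.0, 181.1, 253.1, 283.0, 528.2,
                       1834.8, 2067.9, 1822.8]


class TestPrintedFragmentIons:
    """The frozen end-group conventions reproduce the printed MS/MS ions."""

    @pytest.fixture(autouse=True)
    def _fragments(self, sulfo_biantennary):
        self.topology = sulfo_biantennary
        self.negative = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.NEGATIVE, max_cleavages=1
        )
        self.positive = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.POSITIVE, max_cleavages=1
        )

    def _has(self, fragments, printed, kind=None):
        return any(
            abs(f.mz - printed) <= 1.0 and (kind is None or f.kind is kind)
            for f in fragments
        )

    @pytest.mark.parametrize("printed", [2067, 1822])
    def test_sequential_antenna_y_ions(self, printed):
        assert self._has(self.negative, printed, FragmentKind.Y)

    def test_core_fucosylation_b_ion(self):
        # B ion after loss of the reducing GlcNAc + core fucose.
        assert self._has(self.negative, 1834, FragmentKind.B)

    @pytest.mark.parametrize("printed", [283, 528])
    def test_terminal_sulfo_b_ions(self, printed):
        assert self._has(self.negative, printed, FragmentKind.B)

    @pytest.mark.parametrize("printed", [474, 486, 574, 1781, 2026])
    def test_positive_mode_complementary_ions(self, printed):
        assert self._has(self.positive, printed)


class TestEnumerationInvariants:
    def test_four_ions_per_bond_in_positive_mode(self, sulfo_biantennary):
        fragments = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.POSITIVE, max_cleavages=1
        )
        assert len(fragments) == 4 * sulfo_biantennary.n_bonds

    def test_b_y_complementarity(self, sulfo_biantennary):
        """For each single cleavage, sodiated B + Y minus one Na rebuilds
        the precursor."""
        precursor = ion_mz(sulfo_biantennary.composition(), Polarity.POSITIVE)
        fragments = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.POSITIVE, max_cleavages=1
        )
        by_edge = {}
        for f in fragments:
            if f.kind in (FragmentKind.B, FragmentKind.Y):
                by_edge.setdefault(f.cleaved_edges[0], {})[f.kind] = f
        assert by_edge
        for pair in by_edge.values():
            total = pair[FragmentKind.B].mz + pair[FragmentKind.Y].mz - NA
            assert total == pytest.approx(precursor, abs=1e-2)

    def test_negative_mode_keeps_only_sulfate_retaining_ions(
        self, sulfo_biantennary
    ):
        fragments = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.NEGATIVE, max_cleavages=1
        )
        for f in fragments:
            if f.kind in (FragmentKind.B, FragmentKind.C):
                assert f.composition.sulfo >= 1
            else:  # Y/Z retain the root side, which keeps the sulfate
                assert f.composition.sulfo >= 1

    def test_negative_mode_requires_sulfated_topology(self):
        plain = parse_topology("GlcNAc(GlcNAc(Man(Man)(Man)))")
        with pytest.raises(FragmentError):
            enumerate_glycosidic_fragments(plain, Polarity.NEGATIVE)

    def test_double_cleavages_add_internal_fragments(self, sulfo_biantennary):
        singles = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.POSITIVE, max_cleavages=1
        )
        doubles = enumerate_glycosidic_fragments(
            sulfo_biantennary, Polarity.POSITIVE, max_cleavages=2
        )
        extra_kinds = {f.kind for f in doubles} - {f.kind for f in singles}
        assert extra_kinds <= {FragmentKind.BY, FragmentKind.YY}
        assert len(doubles) > len(singles)


class TestDiagnosticTable:
    def test_curated_nominal_masses(self):
        table = {round(e.mz): e for e in diagnostic_ions().entries}
        assert set(table) == {97, 153, 181, 253, 283, 528}

    def test_sulfate_anion_recomputed_from_atoms(self):
        entry = next(e for e in diagnostic_ions().entries
                     if e.name == "sulfate_anion")
        assert entry.mz == pytest.approx(H + S + 4 * O, abs=0.05)
        assert round(entry.mz) == 97

    def test_sulfo_gal_b_ion_recomputed_from_residues(self):
        entry = next(e for e in diagnostic_ions().entries
                     if e.name == "B_sulfo_gal")
        expected = SULFO_GAL_RESIDUE + B_END - 2 * PROTON
        assert entry.mz == pytest.approx(expected, abs=0.05)
        assert entry.mz == pytest.approx(283.05, abs=1.0)

    def test_sulfo_lacnac_b_ion_adds_one_hexnac(self):
        table = {e.name: e for e in diagnostic_ions().entries}
        assert table["B2_sulfo_lacnac"].mz == pytest.approx(
            table["B_sulfo_gal"].mz + RESIDUE_MASSES["hexnac"], abs=0.05
        )
        assert table["B2_sulfo_lacnac"].mz == pytest.approx(528.17, abs=1.0)

    def test_every_entry_carries_a_citation(self):
        assert all(e.citation for e in diagnostic_ions().entries)


class TestAssignSulfoLinkage:
    def test_full_diagnostic_set_yields_3_o_gal_verdict(self):
        verdict = assign_sulfo_linkage(
            [96.96, 528.2, 283.0, 153.0, 253.1, 181.1], Polarity.NEGATIVE
        )
        assert verdict.sulfate_present
        assert verdict.sulfo_on_lacnac
        assert verdict.sulfo_position is SulfoPosition.TERMINAL_GAL
        assert verdict.linkage is SulfoLinkage.THREE_O_GAL

    def test_sulfate_alone_leaves_linkage_indeterminate(self):
        verdict = assign_sulfo_linkage([96.96], Polarity.NEGATIVE)
        assert verdict.sulfate_present
        assert not verdict.sulfo_on_lacnac
        assert verdict.linkage is SulfoLinkage.INDETERMINATE
        assert verdict.sulfo_position is SulfoPosition.INDETERMINATE

    def test_empty_peak_list_all_indeterminate(self):
        verdict = assign_sulfo_linkage([], Polarity.NEGATIVE)
        assert not verdict.sulfate_present
        assert verdict.linkage is SulfoLinkage.INDETERMINATE
        assert verdict.matched_diagnostics == ()

    def test_cross_ring_ions_without_sulfate_anion_insufficient(self):
        verdict = assign_sulfo_linkage([153.0, 181.0], Polarity.NEGATIVE)
        assert verdict.linkage is SulfoLinkage.INDETERMINATE

    def test_positive_mode_contributes_no_linkage_call(self):
        verdict = assign_sulfo_linkage(NEGATIVE_MSMS_PEAKS, Polarity.POSITIVE)
        assert verdict.linkage is SulfoLinkage.INDETERMINATE
        assert not verdict.sulfate_present


class TestAnnotateMsms:
    def test_printed_peak_set_fully_matched(self, sulfo_biantennary):
        result = annotate_msms(
            sulfo_biantennary, NEGATIVE_MSMS_PEAKS, Polarity.NEGATIVE
        )
        explained = [m.observed_mz for m in result.matches] + list(
            result.diagnostics
        )
        # Every printed glycosidic ion and diagnostic is accounted for.
        for printed in (1834, 2067, 1822, 283, 528, 97, 153, 181, 253):
            assert any(abs(e - printed) <= 1.0 for e in explained)
        assert result.verdict.linkage is SulfoLinkage.THREE_O_GAL
        assert result.coverage > 0

    def test_positive_lacnac_b_ion_matched(self, sulfo_biantennary):
        result = annotate_msms(
            sulfo_biantennary, [486.2], Polarity.POSITIVE
        )
        assert len(result.matches) == 1
        assert result.matches[0].fragment.kind is FragmentKind.B

    def test_each_peak_matches_at_most_one_fragment(self, sulfo_biantennary):
        result = annotate_msms(
            sulfo_biantennary, NEGATIVE_MSMS_PEAKS, Polarity.NEGATIVE
        )
        observed = [m.observed_mz for m in result.matches]
        assert len(observed) == len(set(observed))

    def test_no_peaks_gives_zero_coverage(self, sulfo_biantennary):
        result = annotate_msms(sulfo_biantennary, [], Polarity.NEGATIVE)
        assert result.coverage == 0.0
        assert result.matches == ()

    def test_precursor_mismatch_rejected(self, sulfo_biantennary):
        with pytest.raises(FragmentError):
            annotate_msms(
                sulfo_biantennary, NEGATIVE_MSMS_PEAKS, Polarity.NEGATIVE,
                precursor_mz=2500.0,
            )

    def test_matching_sodiation_increment(self):
        assert NA_MINUS_H == pytest.approx(21.9819, abs=1e-3)
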