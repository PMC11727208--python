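"""Peak-list ingestion, filtering, composition enumeration and annotation."""

import itertools
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sulfoglyco.annotate import (
    CompositionBounds,
    Fraction,
    Peak,
    PeaklistError,
    Spectrum,
    annotate_spectrum,
    annotations_to_table,
    enumerate_compositions,
    filter_peaks,
    flag_satellites,
    read_peaklist,
)
from sulfoglyco.composition import GlycanComposition, parse_composition
from sulfoglyco.masses import IonSpecies, Polarity, ion_mz


def _write(tmp_path, text, name="peaks.csv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestReadPeaklist:
    def test_reads_and_sorts(self, tmp_path):
        path = _write(tmp_path, """\
            mz,intensity,snr
            2605.3,500,12
            1579.8,1000,30
            2966.5,250,8
        """)
        spec = read_peaklist(path, "positive", "neutral_sialylated")
        assert len(spec) == 3
        assert [round(p.mz, 1) for p in spec.peaks] == [1579.8, 2605.3, 2966.5]

    def test_unparseable_row_reports_line(self, tmp_path):
        path = _write(tmp_path, """\
            mz,intensity
            1579.8,1000
            abc,1.0
        """)
        with pytest.raises(PeaklistError, match="line 2"):
            read_peaklist(path, "positive", "neutral_sialylated")

    def test_empty_file_rejected(self, tmp_path):
        path = _write(tmp_path, "mz,intensity,snr\n")
        with pytest.raises(PeaklistError):
            read_peaklist(path, "positive", "neutral_sialylated")

    def test_missing_snr_imputed_from_median_intensity(self, tmp_path, caplog):
        path = _write(tmp_path, """\
            mz,intensity
            1579.8,1000
            2605.3,500
            2966.5,250
        """)
        with caplog.at_level("WARNING"):
            spec = read_peaklist(path, "positive", "neutral_sialylated")
        assert "imputed" in caplog.text
        snrs = {round(p.mz, 1): p.snr for p in spec.peaks}
        assert snrs[1579.8] == pytest.approx(2.0)   # 1000 / median 500
        assert snrs[2966.5] == pytest.approx(0.5)

    def test_tab_delimited_accepted(self, tmp_path):
        path = _write(tmp_path, "mz\tintensity\tsnr\n2286.1\t100\t5\n")
        spec = read_peaklist(path, "negative", "sulfated")
        assert spec.peaks[0].intensity == 100


class TestFilterPeaks:
    def make(self, *snrs, mz=2000.0):
        return Spectrum(
            peaks=tuple(
                Peak(mz=mz + i, intensity=1.0, snr=s)
                for i, s in enumerate(snrs)
            ),
            polarity=Polarity.POSITIVE,
            fraction=Fraction.NEUTRAL_SIALYLATED,
        )

    def test_threshold_is_inclusive_at_two(self):
        spec = filter_peaks(self.make(2.0, 1.99, 5.0))
        assert [p.snr for p in spec.peaks] == [2.0, 5.0]

    def test_out_of_range_peaks_removed(self):
        spec = Spectrum(
            peaks=(Peak(999.0, 1.0, 10.0), Peak(1500.0, 1.0, 10.0),
                   Peak(6001.0, 1.0, 10.0)),
            polarity=Polarity.POSITIVE,
            fraction=Fraction.NEUTRAL_SIALYLATED,
        )
        assert [p.mz for p in filter_peaks(spec).peaks] == [1500.0]

    def test_empty_spectrum_allowed(self):
        assert len(filter_peaks(self.make())) == 0


def brute_force_enumeration(target_mz, polarity, tolerance, bounds, fraction):
    """Independent oracle: exhaustive nested-loop scan of the bounds."""
    if polarity is Polarity.NEGATIVE:
        sulfos = range(1, bounds.max_sulfo + 1)
    elif fraction is Fraction.NEUTRAL_SIALYLATED:
        sulfos = [0]
    else:
        sulfos = range(0, bounds.max_sulfo + 1)
    found = set()
    for h, n, d, s, u in itertools.product(
        range(bounds.max_hex + 1), range(bounds.max_hexnac + 1),
        range(bounds.max_dhex + 1), range(bounds.max_neuac + 1), sulfos,
    ):
        if h + n + d + s == 0:
            continue
        comp = GlycanComposition(hex=h, hexnac=n, dhex=d, neuac=s, sulfo=u)
        if not bounds.admits(comp):
            continue
        try:
            mz = ion_mz(comp, polarity)
        except ValueError:
            continue
        if abs(mz - target_mz) <= tolerance:
            found.add(comp)
    return found


class TestEnumerateCompositions:
    def test_oligomannose_peak_is_found(self):
        cands = enumerate_compositions(
            1579.8, Polarity.POSITIVE, 0.5,
            fraction=Fraction.NEUTRAL_SIALYLATED,
        )
        assert parse_composition("Hex5HexNAc2") in {
            c.composition for c in cands
        }

    def test_disialylated_biantennary_found(self):
        cands = enumerate_compositions(
            2966.5, Polarity.POSITIVE, 0.5,
            fraction=Fraction.NEUTRAL_SIALYLATED,
        )
        assert parse_composition("Hex5HexNAc4Fuc1NeuAc2") in {
            c.composition for c in cands
        }

    def test_results_sorted_by_abs_error_with_ranks(self):
        cands = enumerate_compositions(
            2286.1, Polarity.NEGATIVE, 0.5, fraction=Fraction.SULFATED
        )
        errors = [abs(c.error_da) for c in cands]
        assert errors == sorted(errors)
        assert [c.rank for c in cands] == list(range(1, len(cands) + 1))

    def test_fixed_species_restricts_sulfo_count(self):
        species = IonSpecies(Polarity.NEGATIVE, n_sulfo=2)
        cands = enumerate_compositions(2374.0, species, 0.5)
        assert cands and all(c.composition.sulfo == 2 for c in cands)

    def test_rejects_non_positive_tolerance(self):
        with pytest.raises(ValueError):
            enumerate_compositions(2000.0, Polarity.POSITIVE, 0.0)

    @given(
        hst.floats(min_value=1000.0, max_value=6000.0),
        hst.sampled_from([
            (Polarity.POSITIVE, Fraction.NEUTRAL_SIALYLATED),
            (Polarity.NEGATIVE, Fraction.SULFATED),
        ]),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, target, setup):
        polarity, fraction = setup
        bounds = CompositionBounds(
            max_hex=8, max_hexnac=7, max_dhex=3, max_neuac=4, max_sulfo=3
        )
        ours = {
            c.composition
            for c in enumerate_compositions(
                target, polarity, 0.5, bounds, fraction=fraction
            )
        }
        assert ours == brute_force_enumeration(
            target, polarity, 0.5, bounds, fraction
        )


def _spectrum_from_compositions(comps, polarity, fraction, snr=10.0):
    peaks = tuple(
        Peak(mz=ion_mz(c, polarity), intensity=100.0, snr=snr) for c in comps
    )
    return Spectrum(peaks=peaks, polarity=polarity, fraction=Fraction(fraction))


class TestAnnotateSpectrum:
    def test_oligomannose_series_rank1(self, oligomannose_series):
        spec = _spectrum_from_compositions(
            oligomannose_series, Polarity.POSITIVE, "neutral_sialylated"
        )
        annotations = annotate_spectrum(spec)
        assert len(annotations) == 5
        assigned = [a.top.composition for a in annotations]
        assert assigned == oligomannose_series

    def test_peak_without_candidates_is_unassigned(self):
        spec = Spectrum(
            peaks=(Peak(1001.0, 50.0, 10.0),),
            polarity=Polarity.POSITIVE,
            fraction=Fraction.NEUTRAL_SIALYLATED,
        )
        annotations = annotate_spectrum(spec)
        assert len(annotations) == 1 and not annotations[0].assigned

    def test_polarity_fraction_mismatch_raises(self, oligomannose_series):
        spec = _spectrum_from_compositions(
            oligomannose_series, Polarity.POSITIVE, "neutral_sialylated"
        )
        bad = Spectrum(peaks=spec.peaks, polarity=Polarity.NEGATIVE,
                       fraction=Fraction.NEUTRAL_SIALYLATED)
        with pytest.raises(ValueError):
            annotate_spectrum(bad)

    def test_no_annotation_error_exceeds_tolerance(self, oligomannose_series):
        spec = _spectrum_from_compositions(
            oligomannose_series, Polarity.POSITIVE, "neutral_sialylated"
        )
        for a in annotate_spectrum(spec, tolerance_da=0.5):
            assert all(abs(c.error_da) <= 0.5 for c in a.candidates)

    def test_report_is_deterministic(self, oligomannose_series):
        spec = _spectrum_from_compositions(
            oligomannose_series, Polarity.POSITIVE, "neutral_sialylated"
        )
        first = annotations_to_table(annotate_spectrum(spec)).to_csv(sep="\t")
        second = annotations_to_table(annotate_spectrum(spec)).to_csv(sep="\t")
        assert first == second


class TestFlagSatellites:
    def _annotations(self, mzs, fraction=Fraction.SULFATED):
        spec = Spectrum(
            peaks=tuple(Peak(m, 100.0, 10.0) for m in mzs),
            polarity=(Polarity.NEGATIVE if fraction is Fraction.SULFATED
                      else Polarity.POSITIVE),
            fraction=fraction,
        )
        return annotate_spectrum(spec)

    def test_under_permethylation_pair_linked(self):
        annotations = self._annotations([2272.05, 2286.07])
        labels = [s.label for s in annotations[0].satellites]
        assert "under_permethylation" in labels

    def test_di_sulfation_pair_linked_in_sulfated_pool(self):
        annotations = self._annotations([2286.07, 2373.99])
        labels = [s.label for s in annotations[1].satellites]
        assert "di_sulfation_candidate" in labels

    def test_di_sulfation_spacing_not_linked_in_neutral_pool(self):
        annotations = self._annotations(
            [2286.07, 2373.99], fraction=Fraction.NEUTRAL_SIALYLATED
        )
        assert all(not a.satellites for a in annotations)

    def test_isolated_peak_has_no_links(self):
        annotations = self._annotations([2286.07])
        assert annotations[0].satellites == []

    def test_links_do_not_change_rank1(self):
        mzs = [2286.07, 2373.99]
        with_links = self._annotations(mzs)
        bare = flag_satellites(self._annotations(mzs), tolerance_da=1e-9)
        for a, b in zip(with_links, bare):
            assert (a.top is None) == (b.top is None)
            if a.top:
                assert a.top.composition == b.top.composition


def test_annotation_table_columns(oligomannose_series):
    spec = _spectrum_from_compositions(
        oligomannose_series, Polarity.POSITIVE, "neutral_sialylated"
    )
    table = annotations_to_table(annotate_spectrum(spec))
    assert {"mz", "composition", "ion_species", "error_mda",
            "category", "candidates_json"} <= set(table.columns)
    assert (table["category"] == "oligomannose").all()
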