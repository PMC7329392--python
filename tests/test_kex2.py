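import numpy as np
import pytest

from kepmine.io_formats import ProteinRecord, SignalPrediction
from kepmine.kex2 import (
    KEPRecord,
    RejectionReason,
    call_kep,
    classify_repeat_units,
    find_kex2_sites,
    split_fragments,
)
from kepmine.params import PipelineParams
from kepmine.repeat_detector import repeat_position_scores
from tests.conftest import toy_kep


class TestSites:
    @pytest.mark.parametrize(
        "mature,sites",
        [
            ("AAAKRGGGKKCCC", [(3, 5), (8, 10)]),
            ("AKRRG", [(1, 3)]),  # greedy takes KR; trailing RG starts mid-pair
            ("ACDEFG", []),
            ("KRKR", [(0, 2), (2, 4)]),
            ("AKKKA", [(1, 3)]),  # non-overlapping: scan resumes after KK
        ],
    )
    def test_leftmost_greedy_scan(self, mature, sites):
        assert find_kex2_sites(mature) == sites


class TestFragments:
    @pytest.mark.parametrize(
        "mature,frags",
        [
            ("AAAKRGGGKKCCC", ["AAA", "GGG", "CCC"]),
            ("AKRRG", ["A", "RG"]),
            ("ACDEFG", ["ACDEFG"]),  # no sites: whole mature
            ("KRKR", []),            # all fragments empty, dropped
            ("KRAAAKR", ["AAA"]),    # terminal sites give no empty fragments
        ],
    )
    def test_splitting(self, mature, frags):
        assert [f.sequence for f in split_fragments(mature)] == frags

    def test_site_plus_fragment_residues_reconstruct_mature(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            mature = "".join(aa[i] for i in rng.integers(0, 20, size=60))
            frags = split_fragments(mature)
            sites = find_kex2_sites(mature)
            n = sum(len(f) for f in frags) + 2 * len(sites)
            assert n == len(mature)
            for f in frags:
                assert mature[f.start : f.end] == f.sequence

    def test_motif_content_flags(self):
        (f,) = split_fragments("YWHHA")
        assert f.contains_y and f.contains_w and f.contains_hh
        (g,) = split_fragments("AAAA")
        assert not (g.contains_y or g.contains_w or g.contains_hh)


class TestRepeatUnits:
    def test_boundary_length_eight_is_a_unit(self):
        track = repeat_position_scores("YAIGSTVNKR" * 4)
        frags = split_fragments("YAIGSTVNKR" * 4)
        classify_repeat_units(frags, track)
        assert all(f.is_repeat_unit for f in frags if len(f) == 8)

    def test_min_length_excludes_seven(self, params):
        track = repeat_position_scores("YAIGSTVKR" * 5)  # 9-aa period, units of 7
        frags = split_fragments("YAIGSTVKR" * 5)
        classify_repeat_units(frags, track)
        assert all(not f.is_repeat_unit for f in frags if len(f) == 7)

    def test_unmasked_fragment_is_not_a_unit(self):
        signal, mature = toy_kep()
        track = repeat_position_scores(mature)
        frags = split_fragments(mature)
        classify_repeat_units(frags, track)
        tail = frags[-1]
        assert tail.sequence == "GD" and not tail.is_repeat_unit

    def test_track_length_mismatch_is_error(self):
        track = repeat_position_scores("YAIGSTVNKR" * 2)
        frags = split_fragments("YAIGSTVNKR" * 5)
        with pytest.raises(ValueError):
            classify_repeat_units(frags, track)


class TestCallKep:
    def _protein(self, mature: str) -> tuple[ProteinRecord, SignalPrediction]:
        signal = "MKLLVVLLLAFSDA"
        rec = ProteinRecord("p", signal + mature)
        return rec, SignalPrediction("p", True, len(signal))

    def test_toy_kep_accepted_with_four_units(self, toy_kep_protein):
        rec, pred = toy_kep_protein
        result = call_kep(rec, pred)
        assert isinstance(result, KEPRecord)
        units = result.repeat_units
        assert len(units) == 4
        assert all(u.sequence == "YAIGSTVN" for u in units)
        assert [u.start for u in units] == [10, 20, 30, 40]

    def test_no_signal_is_first_reason(self):
        rec = ProteinRecord("p", "YAIGSTVNKR" * 6)
        pred = SignalPrediction("p", False, None)
        assert call_kep(rec, pred) is RejectionReason.NO_SIGNAL

    def test_short_mature_rejected(self):
        rec, pred = self._protein("YAIGKRYAIG")
        assert call_kep(rec, pred) is RejectionReason.TOO_SHORT

    def test_random_mature_not_repetitive(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHILMNPQSTVWY"
        rec, pred = self._protein("".join(aa[i] for i in rng.integers(0, 18, 80)))
        assert call_kep(rec, pred) is RejectionReason.NOT_REPETITIVE

    def test_repeats_without_sites_fail_on_kex2(self):
        # repetitive (unit x 5 flanked by random) but no dibasic pair anywhere
        rec, pred = self._protein("DGEANQHW" + "YAIGSTVN" * 5 + "EDQGHA")
        assert call_kep(rec, pred) is RejectionReason.NO_KEX2_SITE

    def test_oversized_fragment_rejected_even_outside_units(self):
        _, mature = toy_kep(k=6)
        long_frag = "ADEFGHINQSTVWYELMNPQ" * 6  # 120 aa, no dibasic
        rec, pred = self._protein(mature + long_frag)
        assert call_kep(rec, pred) is RejectionReason.FRAGMENT_TOO_LONG

    def test_two_copies_are_too_few(self):
        _, mature = toy_kep(unit="YAIGSTVNDEQW", k=2, tail="GDHNEA")
        rec, pred = self._protein(mature)
        assert call_kep(rec, pred) is RejectionReason.TOO_FEW_UNITS

    def test_short_units_reason(self):
        _, mature = toy_kep(unit="YAIGS", k=6, tail="GDHNEA")
        rec, pred = self._protein(mature)
        assert call_kep(rec, pred) is RejectionReason.UNITS_TOO_SHORT

    def test_deterministic_and_order_independent(self, toy_kep_protein):
        rec, pred = toy_kep_protein
        first = call_kep(rec, pred)
        second = call_kep(rec, pred)
        assert [f.sequence for f in first.fragments] == [
            f.sequence for f in second.fragments
        ]

    def test_custom_min_units_parameter(self, toy_kep_protein):
        rec, pred = toy_kep_protein
        strict = PipelineParams(min_units=5)
        assert call_kep(rec, pred, strict) is RejectionReason.TOO_FEW_UNITS
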