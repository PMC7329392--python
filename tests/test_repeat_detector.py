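import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kepmine.repeat_detector import (
    RepeatScoreTrack,
    effective_seed_length,
    is_tandem_repetitive,
    repeat_position_scores,
    tandem_repeat_parts,
)
from tests.conftest import AA20, random_protein_sequence
from tests.oracles import brute_force_repeat_votes


class TestScoring:
    def test_exact_tandem_array_fully_masked(self):
        # six exact copies of a 10-aa unit of distinct residues
        mature = "ACDEFGHIKL" * 6
        track = repeat_position_scores(mature)
        assert track.n_seeds == 21
        assert (track.scores > 0.6).all()
        assert track.mask.all()

    def test_random_sequences_score_zero(self):
        rng = np.random.default_rng(11)
        masked = []
        for _ in range(50):
            track = repeat_position_scores(random_protein_sequence(rng, 60))
            masked.append(track.mask.mean())
            assert track.scores.max() <= 0.6
        assert float(np.mean(masked)) < 0.05

    def test_all_distinct_residues_score_zero(self):
        track = repeat_position_scores(AA20)
        assert (track.scores == 0).all()
        assert track.seed_length == 10 and track.seed_reduced

    def test_short_mature_is_degenerate_not_an_error(self):
        track = repeat_position_scores("ACDEFGHIKLMNPQR")  # 15 aa
        assert track.n_seeds == 0
        assert not track.mask.any()
        assert not is_tandem_repetitive(track)

    def test_x_never_matches_even_itself(self):
        track = repeat_position_scores("X" * 60)
        assert (track.votes == 0).all()

    def test_mask_is_exactly_scores_above_threshold(self):
        track = repeat_position_scores("YAIGSTVNKR" * 5)
        assert np.array_equal(track.mask, track.scores > track.threshold)

    def test_effective_seed_length_reduction(self):
        assert effective_seed_length(100) == 40
        assert effective_seed_length(41) == 40
        assert effective_seed_length(40) == 20
        assert effective_seed_length(17) == 8


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_votes_match_direct_enumeration_on_random_strings(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            length = int(rng.integers(16, 90))
            mature = random_protein_sequence(rng, length)
            track = repeat_position_scores(mature)
            assert track.votes.tolist() == brute_force_repeat_votes(mature)

    def test_votes_match_direct_enumeration_on_tandem_arrays(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            unit = random_protein_sequence(rng, int(rng.integers(5, 12)))
            k = int(rng.integers(3, 7))
            mature = random_protein_sequence(rng, 8) + unit * k
            track = repeat_position_scores(mature)
            assert track.votes.tolist() == brute_force_repeat_votes(mature)


class TestProperties:
    def test_scores_invariant_under_alphabet_permutation(self):
        rng = np.random.default_rng(7)
        mature = ("YAIGSTVNKR" * 4) + random_protein_sequence(rng, 12)
        perm = dict(zip(AA20, np.random.default_rng(1).permutation(list(AA20))))
        relabeled = "".join(perm[c] for c in mature)
        a = repeat_position_scores(mature)
        b = repeat_position_scores(relabeled)
        assert np.allclose(a.scores, b.scores)

    def test_distinct_rare_suffix_receives_zero_votes(self):
        # suffix residues occur nowhere else, so they can never match
        base = "YAIGSNVD" * 5
        suffix = "WCHMPQRT"
        assert not set(suffix) & set(base)
        track = repeat_position_scores(base + suffix)
        assert (track.votes[-len(suffix):] == 0).all()
        assert not track.mask[-len(suffix):].any()

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_votes_bounded_by_total_placements(self, seed):
        rng = np.random.default_rng(seed)
        mature = random_protein_sequence(rng, int(rng.integers(16, 70)))
        track = repeat_position_scores(mature)
        # each of the n_seeds seeds covers a position in at most K placements
        assert track.votes.max() <= track.n_seeds * track.seed_length
        assert (track.votes >= 0).all()


class TestParts:
    def _track(self, mask):
        mask = np.asarray(mask, dtype=bool)
        return RepeatScoreTrack(
            mature_length=len(mask),
            scores=mask.astype(float),
            mask=mask,
            seed_length=8,
            threshold=0.6,
            n_seeds=max(len(mask) - 7, 1),
            votes=mask.astype(np.int64),
        )

    @pytest.mark.parametrize(
        "mask,parts",
        [
            ([False] * 12, 1),
            ([False] * 4 + [True] * 4 + [False] * 4, 3),
            ([False, True, False, True, False], 5),
            ([True] * 6, 1),
            ([True] * 3 + [False] * 3, 2),
        ],
    )
    def test_block_counting(self, mask, parts):
        assert tandem_repeat_parts(self._track(mask)) == parts

    @pytest.mark.parametrize(
        "mask,repetitive",
        [
            ([False] * 4 + [True] * 4 + [False] * 4, True),   # 3 parts
            ([True] * 6 + [False] * 6, False),                # 2 parts
            ([True] * 12, False),                              # 1 part
        ],
    )
    def test_more_than_two_parts_rule(self, mask, repetitive):
        assert is_tandem_repetitive(self._track(mask)) is repetitive

    def test_track_tsv_dump(self, tmp_path):
        track = repeat_position_scores("YAIGSTVNKR" * 5)
        out = tmp_path / "track.tsv"
        track.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "position\tscore\tmask"
        assert len(lines) == track.mature_length + 1
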