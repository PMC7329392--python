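"""Seed-sliding identity voting: mark repeated positions in a mature sequence.

The detector slides every length-``seed_length`` window ("seed") of the
mature sequence over the sequence itself at every gapless offset (partial
end-overlap allowed; the seed's own source placement is excluded). Under a
placement, each overlap position whose residue is identical to the seed
residue overlaid on it receives one vote, *provided the match is coherent*:
at that placement's shift, at least ``min_local_identity`` (default 2/3)
of the ``coherence_window`` (default 12) shifted-comparison columns around
the position must also match, i.e. the match must sit in a locally
conserved copied segment rather than be a residue coincidence, and it must
extend to at least one adjacent column (an isolated single-residue match
never votes). X never matches anything, including another X. The per-position score is the vote
count divided by the number of seeds, and positions scoring above
``threshold`` (default 0.6) are masked as repeated.

The coherence requirement is what separates tandem arrays from composition
bias: without it, every residue coincidence between a seed and the sequence
votes and a uniform-random sequence reaches an expected score of
``seed_length / 20`` = 2 at every position. With it, random sequences score
zero almost surely (8 of 12 chance matches at 1/20 each has probability
~2e-8 per site) while tandem arrays - where period-multiple offsets align
copy onto copy - accumulate several votes per seed, and a few percent of
point substitutions between copies leave the local identity above the 2/3
bar.

A sequence is *tandem repetitive* when cutting it at every mask flip yields
more than 2 alternating repeated/non-repeated blocks: a real repeat region
is flanked by non-repeated sequence (pro-region, tail), giving >= 3 blocks,
while an unbroken mask (1 block) or a single boundary (2 blocks) is not
evidence of internal tandem structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_X = ord("X")

#: Mature sequences shorter than this cannot be scored and are reported as
#: non-repetitive with an empty mask.
MIN_SCORABLE_LENGTH = 16


@dataclass
class RepeatScoreTrack:
    """Per-position repeat scores for one mature sequence.

    ``mask[i]`` is exactly ``scores[i] > threshold``; ``n_seeds`` equals
    ``mature_length - seed_length + 1`` (0 for degenerate short inputs).
    ``votes`` keeps the raw integer vote counts for exact cross-checks.
    """

    mature_length: int
    scores: np.ndarray
    mask: np.ndarray
    seed_length: int
    threshold: float
    n_seeds: int
    votes: np.ndarray
    seed_reduced: bool = False

    def to_tsv(self, path: str | Path) -> None:
        """Dump (position, score, mask) rows for debugging."""
        with open(path, "w") as fh:
            fh.write("position\tscore\tmask\n")
            for i in range(self.mature_length):
                fh.write(f"{i}\t{self.scores[i]:.6f}\t{int(self.mask[i])}\n")


def effective_seed_length(length: int, seed_length: int = 40) -> int:
    """Seed length actually used for a mature sequence of ``length`` residues.

    Sequences shorter than ``seed_length + 1`` would admit fewer than two
    seeds, so the seed shrinks to ``max(8, length // 2)``; the shortest legal
    KEP mature sequences (around 30 aa) thus remain scorable. Tracks with a
    reduced seed are flagged via ``RepeatScoreTrack.seed_reduced``.
    """
    if length >= seed_length + 1:
        return seed_length
    return max(8, length // 2)


def seed_coverage_count(m: int, length: int, seed_length: int) -> int:
    """Number of seeds (windows at stride 1) containing position ``m``."""
    n_seeds = length - seed_length + 1
    return min(m, n_seeds - 1) - max(0, m - seed_length + 1) + 1


#: Shifted comparisons spanning fewer columns than this carry too little
#: context for the coherence test and are skipped.
MIN_COHERENCE_COLS = 6


def coherent_matches(
    eq: np.ndarray, coherence_window: int, min_local_identity: float
) -> np.ndarray:
    """Matches of one shifted self-comparison that pass the coherence test.

    ``eq`` is the boolean match vector of a single shift. Around each
    position a window of ``coherence_window`` columns (slid inward at the
    vector's edges so it keeps full width whenever possible) must reach
    ``min_local_identity`` matched fraction for the position's own match to
    count.
    """
    Lc = eq.shape[0]
    if Lc < MIN_COHERENCE_COLS:
        return np.zeros(Lc, dtype=bool)
    w = min(coherence_window, Lc)
    half = coherence_window // 2
    pref = np.concatenate(([0], np.cumsum(eq)))
    idx = np.arange(Lc)
    lo = np.clip(idx - half, 0, Lc - w)
    cnt = pref[lo + w] - pref[lo]
    window_ok = cnt >= min_local_identity * w - 1e-9
    # an isolated single-residue coincidence is never evidence of copying:
    # the match must extend to at least one adjacent column
    neighbor = np.zeros(Lc, dtype=bool)
    neighbor[:-1] |= eq[1:]
    neighbor[1:] |= eq[:-1]
    return eq & window_ok & neighbor


def repeat_position_scores(
    mature: str,
    seed_length: int = 40,
    threshold: float = 0.6,
    coherence_window: int = 12,
    min_local_identity: float = 2 / 3,
) -> RepeatScoreTrack:
    """Score every position of ``mature`` for membership in a tandem repeat.

    Implements the seed/placement vote definition above in O(L^2) by
    grouping placements by their source-to-placement shift d: under shift d
    a position i is compared with its partner i + d, so the coherent
    matches of all placements at that shift are read off the single shifted
    self-comparison ``mature[i] == mature[i + d]``; the number of (seed,
    placement) pairs aligning i with partner m is the number of seeds whose
    window contains m. The result is vote-for-vote identical to the direct
    (seed, placement, position) enumeration.
    """
    L = len(mature)
    if L < MIN_SCORABLE_LENGTH:
        zeros = np.zeros(L)
        return RepeatScoreTrack(
            mature_length=L,
            scores=zeros,
            mask=zeros.astype(bool),
            seed_length=seed_length,
            threshold=threshold,
            n_seeds=0,
            votes=np.zeros(L, dtype=np.int64),
        )
    K = effective_seed_length(L, seed_length)
    n_seeds = L - K + 1

    arr = np.frombuffer(mature.encode("ascii"), dtype=np.uint8)
    not_x = arr != _X
    # C[m]: number of seeds whose window contains position m
    m_idx = np.arange(L)
    C = (
        np.minimum(m_idx, n_seeds - 1) - np.maximum(0, m_idx - K + 1) + 1
    ).astype(np.int64)

    votes = np.zeros(L, dtype=np.int64)
    for d in range(1, L):
        # shifted self-comparison: positions i in [0, L-d) vs partners i+d
        eq = (arr[: L - d] == arr[d:]) & not_x[: L - d] & not_x[d:]
        valid = coherent_matches(eq, coherence_window, min_local_identity)
        if not valid.any():
            continue
        # shift +d: i gains C[i + d] votes; shift -d: the partner side
        votes[: L - d] += valid * C[d:]
        votes[d:] += valid * C[: L - d]

    scores = votes / n_seeds
    return RepeatScoreTrack(
        mature_length=L,
        scores=scores,
        mask=scores > threshold,
        seed_length=K,
        threshold=threshold,
        n_seeds=n_seeds,
        votes=votes,
        seed_reduced=K != seed_length,
    )


def tandem_repeat_parts(track: RepeatScoreTrack) -> int:
    """Number of maximal constant-mask blocks (alternating repeated /
    non-repeated runs each count as one part)."""
    if track.mature_length == 0:
        return 0
    mask = track.mask
    return int(1 + np.count_nonzero(mask[1:] != mask[:-1]))


def is_tandem_repetitive(track: RepeatScoreTrack) -> bool:
    """True iff the mask partitions the sequence into more than 2 parts."""
    return tandem_repeat_parts(track) > 2
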