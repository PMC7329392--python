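"""Kex2 dibasic-site processing and the KEP acceptance filter.

Kex2 is a Golgi protease cleaving after dibasic motifs (KR, KK, RK, RR). The
mature sequence is cut at those sites into fragments; fragments that fall in
the repeat-masked region and are 8-100 aa long are repeat units. A protein is
accepted as a KEP when it has an ER signal peptide, is tandem repetitive, and
carries >= 3 repeat units between its Kex2 sites, with no fragment longer
than 100 aa. Rejected proteins carry the first failing stage as their single
rejection reason, so the detection funnel can be audited.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from kepmine.io_formats import ProteinRecord, SignalPrediction
from kepmine.params import PipelineParams
from kepmine.repeat_detector import (
    MIN_SCORABLE_LENGTH,
    RepeatScoreTrack,
    is_tandem_repetitive,
    repeat_position_scores,
)
from kepmine.signal_filter import mature_sequence


class RejectionReason(enum.Enum):
    """First failing stage of the detection funnel, in pipeline order."""

    NO_SIGNAL = "NO_SIGNAL"
    TOO_SHORT = "TOO_SHORT"
    NOT_REPETITIVE = "NOT_REPETITIVE"
    NO_KEX2_SITE = "NO_KEX2_SITE"
    FRAGMENT_TOO_LONG = "FRAGMENT_TOO_LONG"
    UNITS_TOO_SHORT = "UNITS_TOO_SHORT"
    TOO_FEW_UNITS = "TOO_FEW_UNITS"


@dataclass
class Kex2Fragment:
    """One inter-site fragment: ``sequence == mature[start:end]`` (0-based,
    half-open); the cleaved dibasic residues are excluded from fragments."""

    start: int
    end: int
    sequence: str
    is_repeat_unit: bool = False

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def contains_y(self) -> bool:
        return "Y" in self.sequence

    @property
    def contains_hh(self) -> bool:
        return "HH" in self.sequence

    @property
    def contains_w(self) -> bool:
        return "W" in self.sequence


@dataclass
class KEPRecord:
    """An accepted KEP with its processing products and downstream labels."""

    protein: ProteinRecord
    mature: str
    fragments: list[Kex2Fragment]
    track: RepeatScoreTrack
    type_label: str = "0"
    subtype_labels: dict[int, str] = field(default_factory=dict)
    annotation: "object | None" = None  # AnnotationFlags, set by annotation stage
    duf3328_within_radius: bool | None = None
    nearest_duf3328_distance: int | None = None

    @property
    def protein_id(self) -> str:
        return self.protein.protein_id

    @property
    def repeat_units(self) -> list[Kex2Fragment]:
        return [f for f in self.fragments if f.is_repeat_unit]


def find_kex2_sites(
    mature: str, motifs: tuple[str, ...] = ("KR", "KK", "RK", "RR")
) -> list[tuple[int, int]]:
    """Non-overlapping, leftmost-greedy scan for dibasic sites.

    Scanning resumes *after* a recorded site, matching cleavage after the
    dibasic motif: in ``AKRRB`` only KR at [1, 3) is a site and the trailing
    ``RB`` starts mid-pair.
    """
    motif_set = set(motifs)
    sites: list[tuple[int, int]] = []
    i = 0
    while i < len(mature) - 1:
        if mature[i : i + 2] in motif_set:
            sites.append((i, i + 2))
            i += 2
        else:
            i += 1
    return sites


def split_fragments(
    mature: str, motifs: tuple[str, ...] = ("KR", "KK", "RK", "RR")
) -> list[Kex2Fragment]:
    """Cut the mature sequence at its Kex2 sites.

    Fragments are the maximal intervals between consecutive sites and the
    sequence ends, with site residues excluded; zero-length fragments
    (adjacent sites, or a site at a terminus) are dropped. Site residues plus
    fragment residues reconstruct the mature sequence exactly.
    """
    sites = find_kex2_sites(mature, motifs)
    fragments: list[Kex2Fragment] = []
    prev_end = 0
    for s_start, s_end in sites:
        if s_start > prev_end:
            fragments.append(
                Kex2Fragment(prev_end, s_start, mature[prev_end:s_start])
            )
        prev_end = s_end
    if prev_end < len(mature):
        fragments.append(Kex2Fragment(prev_end, len(mature), mature[prev_end:]))
    return fragments


def classify_repeat_units(
    fragments: list[Kex2Fragment],
    track: RepeatScoreTrack,
    min_masked_fraction: float = 0.5,
    min_unit_len: int = 8,
    max_unit_len: int = 100,
) -> list[Kex2Fragment]:
    """Set ``is_repeat_unit`` on fragments lying in the repeat-masked region.

    A fragment is a repeat unit when at least ``min_masked_fraction`` of its
    positions are masked as repeated and its length is within
    ``[min_unit_len, max_unit_len]``. The masked-fraction rule is the bridge
    between the per-position mask and the inter-site fragments.
    """
    if fragments and max(f.end for f in fragments) > track.mature_length:
        raise ValueError(
            "fragment coordinates exceed the score track length "
            f"({track.mature_length})"
        )
    for frag in fragments:
        n = len(frag)
        frac = float(track.mask[frag.start : frag.end].mean()) if n else 0.0
        frag.is_repeat_unit = (
            frac >= min_masked_fraction and min_unit_len <= n <= max_unit_len
        )
    return fragments


def call_kep(
    protein: ProteinRecord,
    prediction: SignalPrediction,
    params: PipelineParams | None = None,
) -> KEPRecord | RejectionReason:
    """Run the full acceptance funnel on one protein.

    Stage order (the first failure is the rejection reason): signal peptide
    -> mature long enough to score -> tandem repetitive -> has Kex2 sites ->
    no fragment over ``max_fragment_len`` -> >= ``min_units`` repeat units of
    at least ``min_unit_len`` aa. Deterministic and independent across
    proteins.
    """
    params = params or PipelineParams()

    if not prediction.has_signal:
        return RejectionReason.NO_SIGNAL
    mature = mature_sequence(protein, prediction)
    assert mature is not None

    if len(mature) < max(params.min_mature_length, MIN_SCORABLE_LENGTH):
        return RejectionReason.TOO_SHORT

    track = repeat_position_scores(
        mature,
        seed_length=params.seed_length,
        threshold=params.repeat_threshold,
        coherence_window=params.coherence_window,
        min_local_identity=params.min_local_identity,
    )
    if not is_tandem_repetitive(track):
        return RejectionReason.NOT_REPETITIVE

    sites = find_kex2_sites(mature, params.kex2_motifs)
    if not sites:
        return RejectionReason.NO_KEX2_SITE

    fragments = split_fragments(mature, params.kex2_motifs)
    if any(len(f) > params.max_fragment_len for f in fragments):
        return RejectionReason.FRAGMENT_TOO_LONG

    classify_repeat_units(
        fragments,
        track,
        min_masked_fraction=params.masked_fraction,
        min_unit_len=params.min_unit_len,
        max_unit_len=params.max_fragment_len,
    )
    n_units = sum(f.is_repeat_unit for f in fragments)
    if n_units < params.min_units:
        # label the dominant failure mode: when most of the repeat-masked
        # fragments are below the minimum unit length, the repeats are real
        # but too short; otherwise there simply are not enough of them
        n_masked_short = sum(
            1
            for f in fragments
            if not f.is_repeat_unit
            and len(f) < params.min_unit_len
            and len(f) > 0
            and float(track.mask[f.start : f.end].mean()) >= params.masked_fraction
        )
        if n_masked_short > n_units:
            return RejectionReason.UNITS_TOO_SHORT
        return RejectionReason.TOO_FEW_UNITS

    return KEPRecord(protein=protein, mature=mature, fragments=fragments, track=track)
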