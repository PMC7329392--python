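"""Stage orchestration: detection funnel, typing, vicinity and annotation.

The functions here are what the CLI subcommands and the reproduction script
call; they operate purely on the domain types and return plain containers,
so library users can compose stages without touching files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from kepmine.io_formats import DomainHit, GeneRecord, ProteinRecord, SignalPrediction
from kepmine.kex2 import KEPRecord, RejectionReason, call_kep
from kepmine.families import KEPType, RepeatSubtype, kep_type_clustering, subtype_repeat_units
from kepmine.neighborhood import DUF3328, GeneNeighborhood
from kepmine.params import PipelineParams
from kepmine.signal_filter import heuristic_signal_predict

log = logging.getLogger("kepmine")


@dataclass
class DetectionResult:
    """Accepted KEPs plus the per-protein audit trail of the funnel."""

    keps: list[KEPRecord]
    rejections: dict[str, RejectionReason]

    @property
    def funnel_counts(self) -> dict[str, int]:
        """Monotone funnel: proteins -> with signal -> tandem repetitive ->
        KEPs (each count includes everything that survived that stage)."""
        n = len(self.keps) + len(self.rejections)
        reasons = Counter(r.name for r in self.rejections.values())
        with_signal = n - reasons["NO_SIGNAL"]
        repetitive = with_signal - reasons["TOO_SHORT"] - reasons["NOT_REPETITIVE"]
        return {
            "proteins": n,
            "with_signal": with_signal,
            "tandem_repetitive": repetitive,
            "keps": len(self.keps),
        }


def detect_keps(
    proteins: list[ProteinRecord],
    predictions: dict[str, SignalPrediction] | None = None,
    params: PipelineParams | None = None,
    use_heuristic: bool = False,
) -> DetectionResult:
    """Run the acceptance funnel over a proteome.

    ``predictions`` holds precomputed signal-peptide calls (e.g. from a
    SignalP short-format table); with ``use_heuristic`` the built-in
    heuristic fills in for proteins missing from it. A protein with neither
    a prediction nor the heuristic enabled is an error - silent drops would
    corrupt the funnel counts.
    """
    params = params or PipelineParams()
    predictions = predictions or {}
    keps: list[KEPRecord] = []
    rejections: dict[str, RejectionReason] = {}
    for protein in proteins:
        pred = predictions.get(protein.protein_id)
        if pred is None:
            if not use_heuristic:
                raise ValueError(
                    f"no signal prediction for {protein.protein_id!r} and the "
                    "heuristic is disabled"
                )
            pred = heuristic_signal_predict(protein)
        result = call_kep(protein, pred, params)
        if isinstance(result, RejectionReason):
            rejections[protein.protein_id] = result
        else:
            keps.append(result)
    counts = DetectionResult(keps, rejections).funnel_counts
    log.info(
        "funnel: %d proteins -> %d with signal -> %d repetitive -> %d KEPs",
        counts["proteins"], counts["with_signal"],
        counts["tandem_repetitive"], counts["keps"],
    )
    return DetectionResult(keps, rejections)


@dataclass
class ClassificationResult:
    labels: dict[str, str]
    types: list[KEPType]
    subtypes: list[RepeatSubtype] = field(default_factory=list)


def classify_keps(
    keps: list[KEPRecord],
    params: PipelineParams | None = None,
    with_subtypes: bool = True,
    build_profiles: bool = False,
) -> ClassificationResult:
    """Type the KEPs and (optionally) sub-type their repeat units; labels
    are written back onto the KEP records."""
    params = params or PipelineParams()
    labels, types = kep_type_clustering(keps, params)
    for kep in keps:
        kep.type_label = labels[kep.protein_id]
    subtypes: list[RepeatSubtype] = []
    if with_subtypes:
        by_label: dict[str, list[KEPRecord]] = {}
        for kep in keps:
            by_label.setdefault(kep.type_label, []).append(kep)
        for label, members in sorted(by_label.items()):
            if label == "0":
                # stand-alone KEPs are sub-typed per KEP
                for m in members:
                    subtypes.extend(
                        subtype_repeat_units(label, [m], params, build_profiles)
                    )
            else:
                subtypes.extend(
                    subtype_repeat_units(label, members, params, build_profiles)
                )
        for st in subtypes:
            for kep_id, frag_idx in st.member_ids:
                for kep in keps:
                    if kep.protein_id == kep_id:
                        kep.subtype_labels[frag_idx] = st.label
    return ClassificationResult(labels, types, subtypes)


def attach_vicinity(
    keps: list[KEPRecord],
    genes: list[GeneRecord],
    domain_hits: list[DomainHit],
    params: PipelineParams | None = None,
) -> GeneNeighborhood:
    """Build the gene neighborhood and write per-KEP DUF3328 accompaniment
    (flag + nearest distance) back onto the KEP records."""
    params = params or PipelineParams()
    hood = GeneNeighborhood(
        genes, domain_hits, kep_protein_ids=[k.protein_id for k in keps]
    )
    stats = hood.domain_vicinity_stats(
        [k.protein_id for k in keps if hood.rank_of(k.protein_id) is not None],
        DUF3328,
        radius=params.vicinity_radius,
        allhits_max_dist=params.allhits_max_dist,
    )
    for kep in keps:
        if hood.rank_of(kep.protein_id) is None:
            continue
        nearest = stats.nearest_by_kep.get(kep.protein_id)
        kep.duf3328_within_radius = nearest is not None
        kep.nearest_duf3328_distance = nearest
    return hood


def kep_table(result: DetectionResult, audit: bool = False) -> pd.DataFrame:
    """The KEP table: one row per accepted KEP (plus, in audit mode, one row
    per rejection with its reason)."""
    rows = []
    for k in result.keps:
        units = [f for f in k.fragments if f.is_repeat_unit]
        rows.append(
            {
                "protein_id": k.protein_id,
                "strain": k.protein.strain_id,
                "type_label": k.type_label,
                "n_fragments": len(k.fragments),
                "n_repeat_units": len(units),
                "unit_coords": ",".join(f"{u.start}-{u.end}" for u in units),
                "duf3328_within_radius": k.duf3328_within_radius,
                "nearest_duf3328_distance": k.nearest_duf3328_distance,
                "rejection_reason": "",
            }
        )
    if audit:
        for pid, reason in sorted(result.rejections.items()):
            rows.append(
                {
                    "protein_id": pid,
                    "strain": "",
                    "type_label": "",
                    "n_fragments": 0,
                    "n_repeat_units": 0,
                    "unit_coords": "",
                    "duf3328_within_radius": None,
                    "nearest_duf3328_distance": None,
                    "rejection_reason": reason.name,
                }
            )
    return pd.DataFrame(rows)
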