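"""Descriptive reports on individual precursors.

:func:`kex2_convention_report` reproduces, for any supplied precursor
sequences, the per-protein numbers used to discuss pheromone precursors:
how many Kex2 fragments the mature sequence yields, which of them contain a
tyrosine (the residue required for ustiloxin-type cyclization), and the
lengths of those Y-containing fragments. Run it on real accessions (e.g.
the Neurospora crassa Ccg-4 pheromone precursor and its Rutstroemia
homolog) to check the fragment-splitting conventions against published
fragment counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from kepmine.io_formats import ProteinRecord, SignalPrediction
from kepmine.kex2 import split_fragments
from kepmine.params import PipelineParams
from kepmine.signal_filter import heuristic_signal_predict, mature_sequence


@dataclass
class ConventionReport:
    protein_id: str
    mature_length: int
    n_fragments: int
    n_y_fragments: int
    y_fragment_lengths: list[int]
    fragment_lengths: list[int]


def kex2_convention_report(
    protein: ProteinRecord,
    prediction: SignalPrediction | None = None,
    assume_mature: bool = False,
    params: PipelineParams | None = None,
) -> ConventionReport:
    """Fragment census for one precursor.

    With ``assume_mature`` the sequence is taken as already signal-trimmed;
    otherwise the supplied prediction (or the built-in heuristic) strips the
    signal peptide first.
    """
    params = params or PipelineParams()
    if assume_mature:
        mature = protein.sequence
    else:
        pred = prediction or heuristic_signal_predict(protein)
        mature = mature_sequence(protein, pred) if pred.has_signal else protein.sequence
    fragments = split_fragments(mature, params.kex2_motifs)
    y_frags = [f for f in fragments if f.contains_y]
    return ConventionReport(
        protein_id=protein.protein_id,
        mature_length=len(mature),
        n_fragments=len(fragments),
        n_y_fragments=len(y_frags),
        y_fragment_lengths=[len(f) for f in y_frags],
        fragment_lengths=[len(f) for f in fragments],
    )
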