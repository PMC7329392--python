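"""Gate proteins on possession of an ER signal peptide.

Two routes exist: real runs consume a SignalP 4.1 short-format table
(:func:`kepmine.io_formats.read_signalp_short`); test and simulation runs use
the built-in heuristic below, whose rules the synthetic generator mirrors
exactly. The heuristic caricatures the canonical signal-peptide architecture
(positively charged n-region, hydrophobic h-region, small-residue c-region
ending at an A-X-A-like cleavage site); it is not a SignalP reimplementation.
"""

from __future__ import annotations

from kepmine.io_formats import ProteinRecord, SignalPrediction

#: Residues counted as hydrophobic for the h-region run.
HYDROPHOBIC = frozenset("ACFILMVW")
#: Small residues allowed at the -3/-1 positions of the cleavage motif.
SMALL = frozenset("AGSTC")

_WINDOW = 45      # the decision looks only at this N-terminal stretch
_MIN_LENGTH = 25  # shorter proteins are never called signal-positive
_CHARGE_SPAN = 6  # K/R must occur within positions 1..6
_RUN_MIN = 8      # minimum h-region run length
_RUN_START_RANGE = (2, 15)  # allowed 1-based start of the run
_MAX_CLEAVAGE = 40


def heuristic_signal_predict(protein: ProteinRecord) -> SignalPrediction:
    """Decide signal-peptide presence from the N-terminal 45 residues.

    A protein is signal-positive iff (i) a K or R occurs at positions 1-6,
    (ii) a run of >= 8 consecutive hydrophobic residues starts at a position
    in 2-15, and (iii) a motif [AGSTC]-x-[AGSTC] ends at a position p with
    hEnd + 2 <= p <= 40, where hEnd is the end of the (maximally extended)
    hydrophobic run. The smallest such p is the cleavage position (last
    signal residue; the mature sequence starts at p + 1).
    """
    seq = protein.sequence
    if len(seq) < _MIN_LENGTH:
        return SignalPrediction(protein.protein_id, False, None, source="heuristic")
    w = seq[:_WINDOW]

    if not any(c in "KR" for c in w[:_CHARGE_SPAN]):
        return SignalPrediction(protein.protein_id, False, None, source="heuristic")

    h_end = None  # 1-based end of the hydrophobic run
    lo, hi = _RUN_START_RANGE
    for p1 in range(lo, hi + 1):
        window = w[p1 - 1 : p1 - 1 + _RUN_MIN]
        if len(window) == _RUN_MIN and all(c in HYDROPHOBIC for c in window):
            end = p1 + _RUN_MIN - 1
            while end < len(w) and w[end] in HYDROPHOBIC:
                end += 1
            h_end = end
            break
    if h_end is None:
        return SignalPrediction(protein.protein_id, False, None, source="heuristic")

    p_max = min(_MAX_CLEAVAGE, len(w), len(seq) - 1)
    for p in range(h_end + 2, p_max + 1):
        if p < 3:
            continue
        if w[p - 3] in SMALL and w[p - 1] in SMALL:
            return SignalPrediction(protein.protein_id, True, p, source="heuristic")
    return SignalPrediction(protein.protein_id, False, None, source="heuristic")


def mature_sequence(protein: ProteinRecord, prediction: SignalPrediction) -> str | None:
    """Strip the signal peptide; ``None`` when the protein has no signal.

    The returned string is always a suffix of the input sequence:
    ``signal + mature == sequence``.
    """
    if prediction.protein_id != protein.protein_id:
        raise ValueError(
            f"prediction for {prediction.protein_id!r} applied to "
            f"{protein.protein_id!r}"
        )
    if not prediction.has_signal:
        return None
    pos = prediction.cleavage_pos
    if pos is None or pos < 1 or pos >= len(protein.sequence):
        raise ValueError(
            f"{protein.protein_id}: cleavage_pos {pos} outside 1..{len(protein.sequence) - 1}"
        )
    return protein.sequence[pos:]
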