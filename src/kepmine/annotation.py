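"""Functional annotation of KEPs and census summary tables.

Mating-factor annotation is by Pfam domain content (MF_alpha PF04648 and/or
MF_alpha_N PF05436); pheromone annotation is by local-alignment similarity
(E < 1e-10, database mode over the query set) to experimentally validated
pheromone precursor peptides supplied as FASTA. Motif-content rates report
the fraction of repeat units (8-100 aa) containing a residue motif such as
Y, HH or W - the Y rate tracks the cyclization chemistry of ustiloxin-type
compounds, which form an ether bond on a tyrosine ring.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from kepmine.io_formats import DomainHit, ProteinRecord
from kepmine.kex2 import KEPRecord, Kex2Fragment
from kepmine.families import KEPType, STANDALONE_LABEL
from kepmine.params import PipelineParams
from kepmine.similarity import AlignmentParams, local_align

MF_ALPHA = "PF04648"
MF_ALPHA_N = "PF05436"


@dataclass
class AnnotationFlags:
    """Independent functional flags; a KEP may carry several."""

    is_yeast_alpha_mating_factor: bool = False
    is_fungal_pheromone: bool = False
    is_basidiomycota_pheromone: bool = False


def flag_mating_factor(
    kep: KEPRecord | str,
    domain_hits: Iterable[DomainHit],
    evalue_threshold: float = 1e-5,
) -> bool:
    """True iff the KEP carries an MF_alpha (PF04648) and/or MF_alpha_N
    (PF05436) domain hit at E <= ``evalue_threshold``."""
    pid = kep if isinstance(kep, str) else kep.protein_id
    return any(
        h.protein_id == pid
        and h.accession_base in (MF_ALPHA, MF_ALPHA_N)
        and h.evalue <= evalue_threshold
        for h in domain_hits
    )


def flag_pheromone(
    kep: KEPRecord | ProteinRecord,
    queries: Sequence[ProteinRecord],
    params: PipelineParams | None = None,
) -> bool:
    """True iff the best local alignment against any query peptide reaches
    E < ``pheromone_evalue`` (database mode over the query set)."""
    params = params or PipelineParams()
    if not queries:
        return False
    protein = kep.protein if isinstance(kep, KEPRecord) else kep
    db_size = sum(len(q.sequence) for q in queries)
    aln_params = AlignmentParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        ka_lambda=params.ka_lambda,
        ka_k=params.ka_k,
        search_space_mode="database",
        db_size=db_size,
    )
    best = min(
        local_align(protein.sequence, q.sequence, params=aln_params).evalue
        for q in queries
    )
    return best < params.pheromone_evalue


def annotate_keps(
    keps: Sequence[KEPRecord],
    domain_hits: Iterable[DomainHit] = (),
    pheromone_queries: Sequence[ProteinRecord] = (),
    basidiomycota_queries: Sequence[ProteinRecord] = (),
    params: PipelineParams | None = None,
) -> None:
    """Attach :class:`AnnotationFlags` to every KEP in place."""
    params = params or PipelineParams()
    hits_by_pid: dict[str, list[DomainHit]] = defaultdict(list)
    for h in domain_hits:
        hits_by_pid[h.protein_id].append(h)
    for kep in keps:
        kep.annotation = AnnotationFlags(
            is_yeast_alpha_mating_factor=flag_mating_factor(
                kep, hits_by_pid.get(kep.protein_id, ()), params.domain_evalue
            ),
            is_fungal_pheromone=flag_pheromone(kep, pheromone_queries, params),
            is_basidiomycota_pheromone=flag_pheromone(
                kep, basidiomycota_queries, params
            ),
        )


def motif_content_rate(
    repeat_units: Iterable[Kex2Fragment | str],
    motif: str,
    min_len: int = 8,
    max_len: int = 100,
) -> float:
    """Fraction of repeat units (restricted to ``min_len``..``max_len`` aa)
    containing at least one occurrence of ``motif`` as a plain substring.
    Returns 0.0 for an empty unit list."""
    seqs = [
        u.sequence if isinstance(u, Kex2Fragment) else u for u in repeat_units
    ]
    seqs = [s for s in seqs if min_len <= len(s) <= max_len]
    if not seqs:
        return 0.0
    return sum(motif in s for s in seqs) / len(seqs)


# ---------------------------------------------------------------------------
# census tables

def phylum_summary(
    keps: Sequence[KEPRecord],
    strain_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-phylum census: strains surveyed / with >= 1 KEP ("found"),
    genera, total KEPs (with the DUF3328-accompanied count), mean and SD of
    per-strain KEP counts.

    ``strain_table`` must carry one row per surveyed strain with columns
    ``strain_id``, ``genus``, ``phylum``. The mean is total KEPs divided by
    found strains, and the SD is the sample (n-1) SD over found strains'
    counts (0.0 for a single strain): two strains with counts {5, 7} print
    mean 6.00 and SD 1.41.
    """
    required = {"strain_id", "genus", "phylum"}
    if not required <= set(strain_table.columns):
        raise ValueError(f"strain_table needs columns {sorted(required)}")

    per_strain: dict[str, int] = defaultdict(int)
    duf_by_phylum: dict[str, int] = defaultdict(int)
    for kep in keps:
        per_strain[kep.protein.strain_id] += 1
        if kep.duf3328_within_radius:
            duf_by_phylum[kep.protein.phylum] += 1

    rows = []
    for phylum, sub in strain_table.groupby("phylum", sort=True):
        counts = np.array(
            [per_strain.get(s, 0) for s in sub["strain_id"]], dtype=float
        )
        found = counts[counts > 0]
        total = int(counts.sum())
        mean = total / len(found) if len(found) else 0.0
        sd = float(np.std(found, ddof=1)) if len(found) > 1 else 0.0
        rows.append(
            {
                "phylum": phylum,
                "strains_surveyed": len(sub),
                "strains_found": int(len(found)),
                "genera": sub["genus"].nunique(),
                "keps_total": total,
                "keps_with_duf3328": duf_by_phylum.get(phylum, 0),
                "keps_per_found_strain": round(mean, 2),
                "sd": round(sd, 2),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        all_counts = np.array(
            [per_strain.get(s, 0) for s in strain_table["strain_id"]], dtype=float
        )
        found = all_counts[all_counts > 0]
        total_row = {
            "phylum": "Total",
            "strains_surveyed": int(df["strains_surveyed"].sum()),
            "strains_found": int(df["strains_found"].sum()),
            "genera": int(strain_table["genus"].nunique()),
            "keps_total": int(df["keps_total"].sum()),
            "keps_with_duf3328": int(df["keps_with_duf3328"].sum()),
            "keps_per_found_strain": round(
                float(all_counts.sum() / len(found)) if len(found) else 0.0, 2
            ),
            "sd": round(float(np.std(found, ddof=1)) if len(found) > 1 else 0.0, 2),
        }
        df = pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
    return df


def type_summary(
    types: Sequence[KEPType],
    keps: Sequence[KEPRecord],
) -> pd.DataFrame:
    """One row per KEP type: count, strains, KEPs/strain, genera, phyla,
    annotation-flag counts and DUF3328-accompaniment split."""
    kep_by_id = {k.protein_id: k for k in keps}
    rows = []
    for t in types:
        members = [kep_by_id[m] for m in t.member_ids if m in kep_by_id]
        n_mating = sum(
            1
            for m in members
            if m.annotation is not None and m.annotation.is_yeast_alpha_mating_factor
        )
        n_pher = sum(
            1
            for m in members
            if m.annotation is not None and m.annotation.is_fungal_pheromone
        )
        n_basidio = sum(
            1
            for m in members
            if m.annotation is not None and m.annotation.is_basidiomycota_pheromone
        )
        with_duf = sum(1 for m in members if m.duf3328_within_radius)
        known_duf = sum(1 for m in members if m.duf3328_within_radius is not None)
        rows.append(
            {
                "label": t.label,
                "count": t.size,
                "strains": len(t.strain_counts),
                "keps_per_strain": round(t.keps_per_strain, 2),
                "genera": len(t.genus_counts),
                "phyla": len(t.phylum_counts),
                "yeast_alpha_mating_factors": n_mating,
                "fungal_pheromones": n_pher,
                "basidiomycota_pheromones": n_basidio,
                "with_duf3328": with_duf,
                "without_duf3328": known_duf - with_duf,
            }
        )
    return pd.DataFrame(rows)
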