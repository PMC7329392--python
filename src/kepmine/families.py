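"""Typing of KEPs and sub-typing of their repeat units.

KEPs are clustered into *types* by single linkage over reciprocal similarity
links (E < 1e-30 and query coverage > 70% in both directions, over a database
of all KEP sequences); singletons are *stand-alone* (type "0"). Within each
type, repeat units are grouped into *sub-types* (identity > 65% and coverage
> 70%, reciprocal). Per sub-type, a center-star multiple alignment and a
per-column residue frequency profile summarize the repeat motif.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np

from kepmine.io_formats import AMINO_ACIDS
from kepmine.kex2 import KEPRecord
from kepmine.params import PipelineParams
from kepmine.similarity import AlignmentParams, _aligner, reciprocal_link

STANDALONE_LABEL = "0"


@dataclass
class KEPType:
    """One KEP type: label "#k" by descending member count, or "0"."""

    label: str
    member_ids: list[str]
    strain_counts: Counter = field(default_factory=Counter)
    genus_counts: Counter = field(default_factory=Counter)
    phylum_counts: Counter = field(default_factory=Counter)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def keps_per_strain(self) -> float:
        n_strains = len(self.strain_counts)
        return self.size / n_strains if n_strains else float(self.size)


@dataclass
class RepeatSubtype:
    """A group of mutually similar repeat units within one KEP type."""

    parent_type: str
    label: str
    member_ids: list[tuple[str, int]]  # (kep protein_id, fragment index)
    sequences: list[str]
    alignment: list[str] = field(default_factory=list)
    profile: np.ndarray | None = None  # columns x 20, rows sum to 1

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def is_small(self) -> bool:
        """Sub-types with 1 or 2 members are excluded from profile reporting."""
        return self.size <= 2


# ---------------------------------------------------------------------------
# single-linkage clustering

def cluster_single_linkage(
    ids: Sequence[Hashable], link: Callable[[Hashable, Hashable], bool]
) -> list[list[Hashable]]:
    """Connected components of the pairwise link graph (single linkage:
    components are merged whenever they share one linked pair).

    ``link`` must be symmetric; it is evaluated once per unordered pair.
    Components preserve first-seen member order; singletons are components
    of size 1.
    """
    parent = {i: i for i in range(len(ids))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if find(i) != find(j) and link(ids[i], ids[j]):
                parent[find(j)] = find(i)

    # note: union-find with the link predicate evaluated lazily would skip
    # pairs already merged transitively; the predicate here is a pure
    # function of the two sequences, so skipping is sound.
    groups: dict[int, list[Hashable]] = defaultdict(list)
    for i, item in enumerate(ids):
        groups[find(i)].append(item)
    return list(groups.values())


def assign_type_labels(
    partition: Iterable[Sequence[Hashable]],
) -> dict[Hashable, str]:
    """Label components "#1", "#2", ... by (size desc, smallest member id);
    singletons get the stand-alone label "0".

    The labeling is a permutation-stable function of the partition: shuffling
    the input order changes neither component membership keys nor labels.
    """
    components = [sorted(c, key=str) for c in partition]
    multi = sorted(
        (c for c in components if len(c) > 1), key=lambda c: (-len(c), str(c[0]))
    )
    labels: dict[Hashable, str] = {}
    for rank, comp in enumerate(multi, start=1):
        for item in comp:
            labels[item] = f"#{rank}"
    for comp in components:
        if len(comp) == 1:
            labels[comp[0]] = STANDALONE_LABEL
    return labels


# ---------------------------------------------------------------------------
# KEP typing

def kep_type_clustering(
    keps: Sequence[KEPRecord], params: PipelineParams | None = None
) -> tuple[dict[str, str], list[KEPType]]:
    """Cluster KEPs into types by reciprocal database-mode hits.

    Link rule: E < ``type_evalue`` in both directions (database = all KEP
    full sequences) and each query's coverage > ``type_coverage``. Returns
    (protein_id -> label, KEPType list sorted stand-alone last).
    """
    params = params or PipelineParams()
    seqs = {k.protein_id: k.protein.sequence for k in keps}
    db_size = sum(len(s) for s in seqs.values())
    aln_params = AlignmentParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        ka_lambda=params.ka_lambda,
        ka_k=params.ka_k,
        search_space_mode="database",
        db_size=db_size,
    )

    def link(a: str, b: str) -> bool:
        return reciprocal_link(
            seqs[a],
            seqs[b],
            e_threshold=params.type_evalue,
            coverage_threshold=params.type_coverage,
            params=aln_params,
        )

    ids = sorted(seqs)
    partition = cluster_single_linkage(ids, link)
    labels = assign_type_labels(partition)

    by_label: dict[str, KEPType] = {}
    kep_by_id = {k.protein_id: k for k in keps}
    for comp in partition:
        for pid in comp:
            label = labels[pid]
            key = label if label != STANDALONE_LABEL else f"0:{pid}"
            ktype = by_label.setdefault(key, KEPType(label=label, member_ids=[]))
            ktype.member_ids.append(pid)
            prot = kep_by_id[pid].protein
            ktype.strain_counts[prot.strain_id] += 1
            ktype.genus_counts[prot.genus] += 1
            ktype.phylum_counts[prot.phylum] += 1
    types = sorted(
        by_label.values(),
        key=lambda t: (t.label == STANDALONE_LABEL, -t.size, t.member_ids[0]),
    )
    return labels, types


# ---------------------------------------------------------------------------
# repeat-unit sub-typing

def subtype_repeat_units(
    type_label: str,
    members: Sequence[KEPRecord],
    params: PipelineParams | None = None,
    build_profiles: bool = True,
) -> list[RepeatSubtype]:
    """Group the repeat units of one type's members into sub-types.

    Link rule: identity > ``subtype_identity`` and each query's coverage >
    ``subtype_coverage`` in reciprocal alignments; no E-value threshold.
    Every repeat unit of every member belongs to exactly one sub-type.
    """
    params = params or PipelineParams()
    aln_params = AlignmentParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        ka_lambda=params.ka_lambda,
        ka_k=params.ka_k,
    )
    unit_ids: list[tuple[str, int]] = []
    unit_seqs: dict[tuple[str, int], str] = {}
    for kep in members:
        for idx, frag in enumerate(kep.fragments):
            if frag.is_repeat_unit:
                uid = (kep.protein_id, idx)
                unit_ids.append(uid)
                unit_seqs[uid] = frag.sequence

    def link(u: tuple[str, int], v: tuple[str, int]) -> bool:
        return reciprocal_link(
            unit_seqs[u],
            unit_seqs[v],
            coverage_threshold=params.subtype_coverage,
            identity_threshold=params.subtype_identity,
            params=aln_params,
        )

    partition = cluster_single_linkage(sorted(unit_ids), link)
    ordered = sorted(partition, key=lambda c: (-len(c), str(sorted(c, key=str)[0])))
    subtypes = []
    for k, comp in enumerate(ordered, start=1):
        comp = sorted(comp)
        st = RepeatSubtype(
            parent_type=type_label,
            label=f"{type_label}.{k}",
            member_ids=comp,
            sequences=[unit_seqs[u] for u in comp],
        )
        if build_profiles and st.size >= 2:
            st.alignment, st.profile = build_profile(st.sequences, params=params)
        subtypes.append(st)
    return subtypes


# ---------------------------------------------------------------------------
# center-star alignment + frequency profile

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def build_profile(
    sequences: Sequence[str],
    pseudocount: float = 0.05,
    params: PipelineParams | None = None,
) -> tuple[list[str], np.ndarray]:
    """Center-star multiple alignment and per-column residue frequencies.

    The center is the member maximizing its summed pairwise alignment scores;
    the others are aligned to it globally and merged on center coordinates
    ("once a gap, always a gap"). Frequencies per column are residue counts
    plus a total pseudocount mass of ``pseudocount`` split uniformly over the
    20 residues, normalized to sum to 1; gap characters carry no mass. A
    single member yields a degenerate profile of near-point masses.
    """
    params = params or PipelineParams()
    if not sequences:
        raise ValueError("cannot build a profile from zero sequences")
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend, "global")

    n = len(sequences)
    if n == 1:
        rows = [sequences[0]]
    else:
        scores = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                s = aligner.score(sequences[i], sequences[j])
                scores[i] += s
                scores[j] += s
        center = int(np.argmax(scores))
        center_seq = sequences[center]
        Lc = len(center_seq)

        # per member: residues at each center position, insertions between
        aligned: list[tuple[list[str], list[str]]] = []
        max_ins = [0] * (Lc + 1)
        order = [center] + [i for i in range(n) if i != center]
        for i in order:
            if i == center:
                cols = list(center_seq)
                ins = [""] * (Lc + 1)
            else:
                aln = next(iter(aligner.align(center_seq, sequences[i])))
                cols = ["-"] * Lc
                ins = [""] * (Lc + 1)
                ca, cb = aln.indices  # per-column indices into center/member
                cpos = 0
                for col in range(ca.shape[0]):
                    ia, ib = ca[col], cb[col]
                    if ia >= 0 and ib >= 0:
                        cols[ia] = sequences[i][ib]
                        cpos = ia + 1
                    elif ia >= 0:
                        cpos = ia + 1
                    elif ib >= 0:
                        ins[cpos] += sequences[i][ib]
            aligned.append((cols, ins))
            for g in range(Lc + 1):
                max_ins[g] = max(max_ins[g], len(ins[g]))

        rows = []
        for cols, ins in aligned:
            row = []
            for g in range(Lc):
                row.append(ins[g].ljust(max_ins[g], "-"))
                row.append(cols[g])
            row.append(ins[Lc].ljust(max_ins[Lc], "-"))
            rows.append("".join(row))
        # restore input order (center was moved to the front)
        rows = [rows[order.index(i)] for i in range(n)]

    width = len(rows[0])
    assert all(len(r) == width for r in rows)
    counts = np.zeros((width, len(AMINO_ACIDS)))
    for row in rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[c, idx] += 1.0
    counts += pseudocount / len(AMINO_ACIDS)
    profile = counts / counts.sum(axis=1, keepdims=True)
    return rows, profile


# ---------------------------------------------------------------------------
# cross-study set comparison

@dataclass
class SetOverlapReport:
    """Reciprocal >95%/95% matching between two KEP sets."""

    matched_a: int
    unmatched_a: int
    matched_b: int
    unmatched_b: int
    pairs: list[tuple[str, str]]

    @property
    def fraction_a_matched(self) -> float:
        total = self.matched_a + self.unmatched_a
        return self.matched_a / total if total else 0.0

    @property
    def fraction_b_matched(self) -> float:
        total = self.matched_b + self.unmatched_b
        return self.matched_b / total if total else 0.0


def compare_kep_sets(
    set_a: dict[str, str],
    set_b: dict[str, str],
    params: PipelineParams | None = None,
) -> SetOverlapReport:
    """Count sequences considered identical across two sets (reciprocal
    identity and coverage both > ``setcompare_identity``/``setcompare_coverage``,
    default 95%/95%)."""
    params = params or PipelineParams()
    aln_params = AlignmentParams(
        matrix_name=params.matrix_name,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    pairs = []
    hit_a, hit_b = set(), set()
    for ida, sa in sorted(set_a.items()):
        for idb, sb in sorted(set_b.items()):
            if reciprocal_link(
                sa,
                sb,
                coverage_threshold=params.setcompare_coverage,
                identity_threshold=params.setcompare_identity,
                params=aln_params,
            ):
                pairs.append((ida, idb))
                hit_a.add(ida)
                hit_b.add(idb)
    return SetOverlapReport(
        matched_a=len(hit_a),
        unmatched_a=len(set_a) - len(hit_a),
        matched_b=len(hit_b),
        unmatched_b=len(set_b) - len(hit_b),
        pairs=pairs,
    )
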