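"""Gene-rank vicinity analysis around KEP-encoding genes.

Genes on each contig are ranked by start coordinate; the distance between
two genes on the same contig is the absolute rank difference (adjacent = 1,
strand ignored), and genes on different contigs have no defined distance.
The statistics mirror a domain co-occurrence survey: how often a domain
(e.g. the DUF3328 cyclization factor, Pfam PF11807) occurs among the genes
within ``radius`` (default 15) on each side of a KEP gene, at what nearest
distance, and how that changes conditional on another domain's presence.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from kepmine.io_formats import DomainHit, GeneRecord

#: Synthetic domain label marking a gene as KEP-encoding.
KEP_LABEL = "KEP"
DUF3328 = "PF11807"
TYROSINASE = "PF00264"
MFS_1 = "PF07690"


@dataclass
class VicinityStats:
    """Per-distance hit histogram for one domain label around KEP genes.

    ``counts[d]`` sums hits at rank distance d over both sides and all KEPs;
    ``nearest_mean`` averages, over KEPs with at least one hit in the radius,
    the distance of each KEP's nearest hit; ``allhits_mean`` averages the
    distance of every hit at distance <= ``allhits_max_dist``. Means are
    ``None`` when there are no contributing hits.
    """

    domain_label: str
    radius: int
    counts: dict[int, int]
    n_keps: int
    n_keps_with_hit: int
    nearest_mean: float | None
    allhits_mean: float | None
    allhits_max_dist: int
    nearest_by_kep: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fraction_of_keps_with_hit(self) -> float:
        return self.n_keps_with_hit / self.n_keps if self.n_keps else 0.0


class GeneNeighborhood:
    """Ranked gene order with per-gene domain labels."""

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        domain_hits: Iterable[DomainHit] = (),
        kep_protein_ids: Iterable[str] = (),
        extra_labels: dict[str, set[str]] | None = None,
    ) -> None:
        by_contig: dict[str, list[GeneRecord]] = defaultdict(list)
        for g in genes:
            by_contig[g.contig_id].append(g)
        self._order: dict[str, list[GeneRecord]] = {}
        self._rank: dict[str, tuple[str, int]] = {}  # protein_id -> (contig, rank)
        for contig, glist in by_contig.items():
            glist.sort(key=lambda g: (g.start, g.gene_id))
            self._order[contig] = glist
            for rank, g in enumerate(glist, start=1):
                if g.protein_id:
                    self._rank[g.protein_id] = (contig, rank)

        self._labels: dict[str, set[str]] = defaultdict(set)  # gene_id -> labels
        pid_to_gene = {g.protein_id: g.gene_id for g in genes if g.protein_id}
        for hit in domain_hits:
            gid = pid_to_gene.get(hit.protein_id)
            if gid is not None:
                self._labels[gid].add(hit.accession_base)
        for pid in kep_protein_ids:
            gid = pid_to_gene.get(pid)
            if gid is not None:
                self._labels[gid].add(KEP_LABEL)
        if extra_labels:
            for gid, labels in extra_labels.items():
                self._labels[gid] |= labels

    def rank_of(self, protein_id: str) -> tuple[str, int] | None:
        return self._rank.get(protein_id)

    def labels_of(self, gene: GeneRecord) -> set[str]:
        return self._labels.get(gene.gene_id, set())

    def vicinity_genes(
        self, kep_protein_id: str, radius: int = 15
    ) -> list[tuple[GeneRecord, int]]:
        """Genes within rank distance 1..radius on each side of the KEP gene
        (signed distance: negative = upstream in rank order), truncated at
        contig ends; the KEP gene itself is excluded."""
        loc = self.rank_of(kep_protein_id)
        if loc is None:
            raise KeyError(f"protein {kep_protein_id!r} is not mapped to a gene")
        contig, rank = loc
        glist = self._order[contig]
        out = []
        for d in range(-radius, radius + 1):
            if d == 0:
                continue
            r = rank + d
            if 1 <= r <= len(glist):
                out.append((glist[r - 1], d))
        return out

    # -- statistics --------------------------------------------------------

    def domain_vicinity_stats(
        self,
        kep_protein_ids: Sequence[str],
        domain_label: str,
        radius: int = 15,
        allhits_max_dist: int = 10,
    ) -> VicinityStats:
        """Histogram of ``domain_label`` hits around each KEP gene.

        KEPs without a mapped gene are excluded (with a warning). The KEP's
        own gene never counts, and for the KEP label each *other* KEP gene
        in the window does.
        """
        counts: dict[int, int] = {d: 0 for d in range(1, radius + 1)}
        nearest_by_kep: dict[str, int] = {}
        allhit_dists: list[int] = []
        n_keps = 0
        for pid in kep_protein_ids:
            if self.rank_of(pid) is None:
                warnings.warn(
                    f"KEP {pid!r} has no gene in the neighborhood; excluded",
                    stacklevel=2,
                )
                continue
            n_keps += 1
            nearest = None
            for gene, d in self.vicinity_genes(pid, radius):
                if domain_label in self.labels_of(gene):
                    dist = abs(d)
                    counts[dist] += 1
                    if dist <= allhits_max_dist:
                        allhit_dists.append(dist)
                    if nearest is None or dist < nearest:
                        nearest = dist
            if nearest is not None:
                nearest_by_kep[pid] = nearest
        nearest_vals = list(nearest_by_kep.values())
        return VicinityStats(
            domain_label=domain_label,
            radius=radius,
            counts=counts,
            n_keps=n_keps,
            n_keps_with_hit=len(nearest_vals),
            nearest_mean=(sum(nearest_vals) / len(nearest_vals)) if nearest_vals else None,
            allhits_mean=(sum(allhit_dists) / len(allhit_dists)) if allhit_dists else None,
            allhits_max_dist=allhits_max_dist,
            nearest_by_kep=nearest_by_kep,
        )

    def conditional_histogram(
        self,
        kep_protein_ids: Sequence[str],
        domain_label: str,
        condition_label: str,
        radius: int = 15,
        allhits_max_dist: int = 10,
    ) -> tuple[VicinityStats, VicinityStats]:
        """Stats for ``domain_label`` computed separately for KEPs with and
        without a ``condition_label`` gene within the radius (e.g. Tyrosinase
        conditioned on DUF3328 presence). The two strata partition the KEPs,
        so their counts sum to the unconditional counts."""
        with_cond, without_cond = [], []
        for pid in kep_protein_ids:
            if self.rank_of(pid) is None:
                continue
            present = any(
                condition_label in self.labels_of(g)
                for g, _ in self.vicinity_genes(pid, radius)
            )
            (with_cond if present else without_cond).append(pid)
        return (
            self.domain_vicinity_stats(with_cond, domain_label, radius, allhits_max_dist),
            self.domain_vicinity_stats(without_cond, domain_label, radius, allhits_max_dist),
        )

    def cooccurring_keps(
        self, kep_protein_ids: Sequence[str], radius: int = 15,
        allhits_max_dist: int = 10,
    ) -> VicinityStats:
        """How often another KEP-encoding gene lies within the radius."""
        return self.domain_vicinity_stats(
            kep_protein_ids, KEP_LABEL, radius, allhits_max_dist
        )
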