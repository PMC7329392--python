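"""Synthetic proteomes, signal predictions, gene orders and domain tables
with planted KEP structure and exact ground truth.

The generator emulates the statistical structure the mining pipeline
assumes: secretory precursors built as signal peptide + leading pro-region
(spacer) + k mutated copies of an ancestral repeat unit separated by Kex2
dibasic sites + short tail; per-rejection-mode decoy proteins; and
per-contig gene orders where cyclization-factor (DUF3328) genes are planted
at controlled rank distances from KEP genes, with Tyrosinase genes enriched
near DUF3328-positive KEPs and background transporter-like labels scattered
uniformly. Everything is driven by one seed; the emitted files and the
ground truth are consistent byte for byte.

What it does *not* emulate: real signal-peptide sequence statistics (the
planted signals satisfy the built-in heuristic's rules exactly), domain
architecture beyond single labels, codon/DNA level structure, and the
taxonomic correlation structure of real strain collections.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from kepmine.io_formats import (
    AMINO_ACIDS,
    DomainHit,
    GeneRecord,
    ProteinRecord,
    SignalPrediction,
    write_domtblout,
    write_fasta,
    write_gene_order_tsv,
    write_signalp_short,
)
from kepmine.neighborhood import DUF3328, MFS_1, TYROSINASE
from kepmine.similarity import local_align

#: Decoy classes, one per intended rejection mode.
DECOY_CLASSES = (
    "no_signal",
    "no_repeat",
    "no_kex2",
    "long_fragment",
    "short_units",
    "few_units",
)

KEX2_MOTIFS = ("KR", "KK", "RK", "RR")
_AA = AMINO_ACIDS  # 20 letters
_AA_NO_KR = "".join(c for c in _AA if c not in "KR")
_HYDRO_RUN = "FILMVW"  # h-region alphabet for planted signals


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset. ``rng_seed`` is mandatory:
    there is no implicit randomness."""

    rng_seed: int
    n_strains: int = 20
    keps_per_strain: int = 5
    decoys_per_class: int = 6
    n_families: int = 6
    ancestor_len_range: tuple[int, int] = (8, 30)
    units_range: tuple[int, int] = (3, 12)
    mutation_rate: float = 0.05
    spacer_len_range: tuple[int, int] = (10, 16)
    tail_len_range: tuple[int, int] = (4, 8)

    genes_per_strain: int = 400
    min_kep_gene_separation: int = 32  # keeps 15-gene vicinities disjoint
    duf3328_fraction: float = 0.22
    duf3328_distance_mean: float = 3.09
    tyrosinase_given_duf3328: float = 0.5
    tyrosinase_distance: int = 2
    background_label_fraction: float = 0.05
    kex2_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    #: "per_protein": one motif drawn per precursor and reused at every
    #: junction (real precursors conserve the processing motif across their
    #: repeats); "per_site": drawn independently at every junction.
    kex2_sampling: str = "per_protein"

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "duf3328_fraction", "tyrosinase_given_duf3328",
                     "background_label_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mutation_rate >= 1.0:
            raise ValueError("mutation_rate must be < 1")
        needed = 16 + self.keps_per_strain * self.min_kep_gene_separation + 16
        if self.genes_per_strain < needed:
            raise ValueError(
                f"genes_per_strain={self.genes_per_strain} too small for "
                f"{self.keps_per_strain} KEP genes at separation "
                f"{self.min_kep_gene_separation} (need >= {needed})"
            )


@dataclass
class ProteinTruth:
    is_kep: bool
    decoy_class: str | None = None
    family_id: int | None = None
    cleavage_pos: int | None = None  # 1-based last signal residue
    unit_intervals: list[tuple[int, int]] = field(default_factory=list)  # on mature


@dataclass
class GeneTruth:
    contig: str
    rank: int
    labels: list[str] = field(default_factory=list)
    kep_protein_id: str | None = None  # the KEP this planted gene belongs to
    planted_distance: int | None = None


@dataclass
class GroundTruth:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    def family_labels(self) -> dict[str, int]:
        return {
            pid: t.family_id
            for pid, t in self.proteins.items()
            if t.is_kep and t.family_id is not None
        }


# ---------------------------------------------------------------------------
# sequence construction primitives

def _random_peptide(
    rng: np.random.Generator, length: int, alphabet: str = _AA
) -> str:
    """Random peptide with no dibasic (K/R-K/R) adjacency and no K/R at
    either boundary, so concatenation with Kex2 sites cannot create or
    destroy cleavage sites."""
    chars = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    for i, c in enumerate(chars):
        if c not in "KR":
            continue
        boundary = i == 0 or i == length - 1
        neighbor = (i > 0 and chars[i - 1] in "KR") or (
            i < length - 1 and chars[i + 1] in "KR"
        )
        while boundary or (chars[i] in "KR" and neighbor):
            chars[i] = alphabet[int(rng.integers(0, len(alphabet)))]
            if chars[i] not in "KR":
                break
    return "".join(chars)


def _positional_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(a[i] == b[i] for i in range(n)) / n if n else 0.0


def make_family_ancestors(
    rng: np.random.Generator, config: SyntheticConfig
) -> list[str]:
    """Ancestral repeat units, pairwise < 30% identical (by local-alignment
    identity), rejection-sampled so type recovery is unambiguous."""
    lo, hi = config.ancestor_len_range
    ancestors: list[str] = []
    attempts = 0
    while len(ancestors) < config.n_families:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not sample dissimilar family ancestors")
        length = int(rng.integers(max(lo, 8), hi + 1))
        cand = _random_peptide(rng, length)
        if _has_dibasic(cand):
            continue
        ok = True
        for anc in ancestors:
            hit = local_align(cand, anc)
            if hit.identity >= 0.30 and hit.score > 0:
                # identity over aligned columns; short random peptides rarely
                # collide, but reject to keep families cleanly separated
                span = min(hit.query_interval[1] - hit.query_interval[0], len(cand))
                if span >= 5 or _positional_identity(cand, anc) >= 0.30:
                    ok = False
                    break
        if ok:
            ancestors.append(cand)
    return ancestors


def _has_dibasic(seq: str) -> bool:
    return any(seq[i : i + 2] in KEX2_MOTIFS for i in range(len(seq) - 1))


def mutate_unit(rng: np.random.Generator, ancestor: str, rate: float) -> str:
    """Ancestor copy with i.i.d. substitutions; a substitution that would
    put K/R at a boundary or next to K/R is resampled, so planted unit
    intervals stay exact."""
    if _has_dibasic(ancestor):
        raise ValueError("ancestor unit must not contain a dibasic pair")
    chars = list(ancestor)
    for i in range(len(chars)):
        if rng.random() >= rate:
            continue
        while True:
            new = _AA[int(rng.integers(0, len(_AA)))]
            if new == chars[i]:
                continue
            if new in "KR":
                boundary = i == 0 or i == len(chars) - 1
                neighbor = (i > 0 and chars[i - 1] in "KR") or (
                    i < len(chars) - 1 and chars[i + 1] in "KR"
                )
                if boundary or neighbor:
                    continue
            chars[i] = new
            break
    return "".join(chars)


def _sample_site(rng: np.random.Generator, config: SyntheticConfig) -> str:
    return KEX2_MOTIFS[
        int(rng.choice(len(KEX2_MOTIFS), p=np.asarray(config.kex2_weights)))
    ]


def make_signal(rng: np.random.Generator) -> tuple[str, int]:
    """A signal peptide satisfying the detection heuristic's three rules
    exactly: M + K/R + hydrophobic run (8-12) + S-D-A. The heuristic's
    smallest valid cleavage position is the end of that S-D-A motif, i.e.
    the planted signal length."""
    run_len = int(rng.integers(8, 13))
    run = "".join(
        _HYDRO_RUN[i] for i in rng.integers(0, len(_HYDRO_RUN), size=run_len)
    )
    charge = "K" if rng.random() < 0.5 else "R"
    signal = "M" + charge + run + "SDA"
    return signal, len(signal)


# ---------------------------------------------------------------------------
# proteins

def make_kep_protein(
    ancestor: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    protein_id: str,
    strain_id: str = "",
    genus: str = "",
    phylum: str = "",
    family_id: int | None = None,
    n_units: int | None = None,
    spacer: str | None = None,
    tail: str | None = None,
) -> tuple[ProteinRecord, SignalPrediction, ProteinTruth]:
    """Precursor = signal + spacer + site + (unit + site) x k + tail.

    The leading spacer (pro-region) and trailing tail flank the repeat
    region with non-repeated sequence; the extra site after the spacer makes
    the detector's fragments coincide exactly with the planted units. A
    family of homologs sharing their whole precursor by descent can pass an
    ancestral ``spacer``/``tail``, which are then mutated at the same rate
    as the units; by default both are drawn fresh per protein.
    """
    signal, cleavage = make_signal(rng)
    lo, hi = config.units_range
    k = n_units if n_units is not None else int(rng.integers(lo, hi + 1))
    if spacer is None:
        spacer = _random_peptide(rng, int(rng.integers(*_incl(config.spacer_len_range))))
    else:
        spacer = mutate_unit(rng, spacer, config.mutation_rate)
    if tail is None:
        tail = _random_peptide(rng, int(rng.integers(*_incl(config.tail_len_range))))
    else:
        tail = mutate_unit(rng, tail, config.mutation_rate)

    protein_site = _sample_site(rng, config)

    def next_site() -> str:
        if config.kex2_sampling == "per_protein":
            return protein_site
        return _sample_site(rng, config)

    parts = [spacer, next_site()]
    pos = len(spacer) + 2
    intervals = []
    for _ in range(k):
        unit = mutate_unit(rng, ancestor, config.mutation_rate)
        parts.append(unit)
        intervals.append((pos, pos + len(unit)))
        pos += len(unit)
        parts.append(next_site())
        pos += 2
    parts.append(tail)
    mature = "".join(parts)

    record = ProteinRecord(
        protein_id=protein_id,
        sequence=signal + mature,
        strain_id=strain_id,
        genus=genus,
        phylum=phylum,
    )
    prediction = SignalPrediction(protein_id, True, cleavage, source="file")
    truth = ProteinTruth(
        is_kep=True,
        family_id=family_id,
        cleavage_pos=cleavage,
        unit_intervals=intervals,
    )
    return record, prediction, truth


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def make_decoy(
    decoy_class: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    protein_id: str,
    strain_id: str = "",
    genus: str = "",
    phylum: str = "",
) -> tuple[ProteinRecord, SignalPrediction, ProteinTruth]:
    """A protein constructed to fail exactly one acceptance stage.

    no_signal: KEP-like body behind an N-terminus violating the signal rules.
    no_repeat: valid signal + uniform-random mature sequence.
    no_kex2: valid signal + spacer + repeat units concatenated with no
        dibasic separators (the whole mature is K/R-free).
    long_fragment: a KEP with one extra 101-150 aa inter-site fragment.
    short_units: repeat units of 5-7 aa (below the 8-aa minimum).
    few_units: only 2 repeat units (below the 3-unit minimum).

    Decoy repeat units are exact copies (mutation rate 0): each class
    isolates a single rejection mode, so its repeat signal is kept
    unambiguous rather than inheriting the KEP mutation rate.
    """
    if decoy_class not in DECOY_CLASSES:
        raise ValueError(f"unknown decoy class {decoy_class!r}")
    from dataclasses import replace

    config = replace(config, mutation_rate=0.0)

    def fresh_ancestor(lo: int, hi: int, alphabet: str = _AA) -> str:
        return _random_peptide(rng, int(rng.integers(lo, hi + 1)), alphabet)

    if decoy_class == "no_signal":
        anc = fresh_ancestor(10, 20)
        rec, _, _ = make_kep_protein(
            anc, config, rng, protein_id, strain_id, genus, phylum
        )
        body = rec.sequence[rec.sequence.index("SDA") + 3 :]
        seq = "MDEQNG" + body
        record = ProteinRecord(protein_id, seq, strain_id, genus, phylum)
        pred = SignalPrediction(protein_id, False, None, source="file")
        return record, pred, ProteinTruth(is_kep=False, decoy_class=decoy_class)

    signal, cleavage = make_signal(rng)
    if decoy_class == "no_repeat":
        mature = _random_peptide(rng, int(rng.integers(60, 121)))
    elif decoy_class == "no_kex2":
        anc = fresh_ancestor(10, 20, _AA_NO_KR)
        k = int(rng.integers(4, 7))
        spacer = _random_peptide(rng, 12, _AA_NO_KR)
        tail = _random_peptide(rng, 6, _AA_NO_KR)
        mature = spacer + "".join(
            mutate_no_kr(rng, anc, config.mutation_rate) for _ in range(k)
        ) + tail
    elif decoy_class == "long_fragment":
        anc = fresh_ancestor(12, 20)
        long_frag = _random_peptide(rng, int(rng.integers(101, 151)), _AA_NO_KR)
        rec, pred, truth = make_kep_protein(
            anc, config, rng, protein_id, strain_id, genus, phylum, n_units=6
        )
        mature = rec.sequence[pred.cleavage_pos :]
        # insert the oversized fragment just before the tail, delimited by a site
        mature = mature + _sample_site(rng, config) + long_frag
        signal = rec.sequence[: pred.cleavage_pos]
        cleavage = pred.cleavage_pos
    elif decoy_class == "short_units":
        anc = fresh_ancestor(5, 7)
        rec, pred, _ = make_kep_protein(
            anc, config, rng, protein_id, strain_id, genus, phylum, n_units=6
        )
        record = ProteinRecord(protein_id, rec.sequence, strain_id, genus, phylum)
        return record, pred, ProteinTruth(
            is_kep=False, decoy_class=decoy_class, cleavage_pos=pred.cleavage_pos
        )
    elif decoy_class == "few_units":
        anc = fresh_ancestor(10, 14)
        rec, pred, _ = make_kep_protein(
            anc, config, rng, protein_id, strain_id, genus, phylum, n_units=2
        )
        record = ProteinRecord(protein_id, rec.sequence, strain_id, genus, phylum)
        return record, pred, ProteinTruth(
            is_kep=False, decoy_class=decoy_class, cleavage_pos=pred.cleavage_pos
        )

    record = ProteinRecord(protein_id, signal + mature, strain_id, genus, phylum)
    pred = SignalPrediction(protein_id, True, cleavage, source="file")
    return record, pred, ProteinTruth(
        is_kep=False, decoy_class=decoy_class, cleavage_pos=cleavage
    )


def mutate_no_kr(rng: np.random.Generator, ancestor: str, rate: float) -> str:
    """Mutated copy that stays K/R-free (for the no_kex2 decoy class)."""
    chars = list(ancestor)
    for i in range(len(chars)):
        if rng.random() < rate:
            new = chars[i]
            while new == chars[i]:
                new = _AA_NO_KR[int(rng.integers(0, len(_AA_NO_KR)))]
            chars[i] = new
    return "".join(chars)


# ---------------------------------------------------------------------------
# gene orders

def geometric_distance_probs(mean: float, dmax: int = 15) -> np.ndarray:
    """Truncated-geometric distance distribution over 1..dmax with the given
    mean, solved by bisection on the decay ratio. Emulates the sharp rise of
    cyclization-factor gene counts toward the KEP gene."""
    if not 1.0 < mean < (dmax + 1) / 2:
        raise ValueError(f"mean must be in (1, {(dmax + 1) / 2})")
    d = np.arange(1, dmax + 1, dtype=float)

    def mean_for(r: float) -> float:
        w = r ** (d - 1)
        return float((d * w).sum() / w.sum())

    lo, hi = 1e-9, 1.0 - 1e-9
    for _ in range(200):
        mid = (lo + hi) / 2
        if mean_for(mid) < mean:
            lo = mid
        else:
            hi = mid
    w = ((lo + hi) / 2) ** (d - 1)
    return w / w.sum()


def make_gene_order(
    strain_id: str,
    kep_protein_ids: Sequence[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneRecord], list[DomainHit], dict[str, GeneTruth]]:
    """One contig of ``genes_per_strain`` genes with KEP genes at controlled
    ranks and planted domain labels.

    KEP genes are placed >= ``min_kep_gene_separation`` ranks apart and >= 16
    ranks from the contig ends, so the 15-gene vicinities of distinct KEPs
    never overlap and planted distances are recovered exactly. Each KEP gets
    a DUF3328 (PF11807) gene at a truncated-geometric distance with
    probability ``duf3328_fraction``; DUF3328-positive KEPs additionally get
    a Tyrosinase (PF00264) gene with probability ``tyrosinase_given_duf3328``.
    Background transporter-like labels (MFS_1) are scattered uniformly over
    unlabeled non-KEP genes.
    """
    n = config.genes_per_strain
    contig = f"{strain_id}_ctg1"
    k = len(kep_protein_ids)
    sep = config.min_kep_gene_separation

    # ranks: 16 + i*sep + jitter, jitter bounded so separation holds
    slack = n - 32 - (k - 1) * sep if k else 0
    if k and slack < 0:
        raise ValueError("genes_per_strain too small for the KEP count")
    jitter = np.sort(rng.integers(0, max(slack, 1), size=k)) if k else np.array([], int)
    kep_ranks = [16 + i * sep + int(jitter[i]) for i in range(k)]

    probs = geometric_distance_probs(config.duf3328_distance_mean)
    labels: dict[int, set[str]] = {}
    truth: dict[str, GeneTruth] = {}

    kep_rank_set = set(kep_ranks)
    for pid, rank in zip(kep_protein_ids, kep_ranks):
        if rng.random() < config.duf3328_fraction:
            dist = int(rng.choice(np.arange(1, 16), p=probs))
            side = 1 if rng.random() < 0.5 else -1
            target = rank + side * dist
            if not (1 <= target <= n) or target in kep_rank_set:
                target = rank - side * dist
            labels.setdefault(target, set()).add(DUF3328)
            truth[f"{contig}_r{target}"] = GeneTruth(
                contig=contig,
                rank=target,
                labels=[DUF3328],
                kep_protein_id=pid,
                planted_distance=dist,
            )
            if rng.random() < config.tyrosinase_given_duf3328:
                t_side = -side
                t_target = rank + t_side * config.tyrosinase_distance
                if not (1 <= t_target <= n) or t_target in kep_rank_set:
                    t_target = rank + side * config.tyrosinase_distance
                if t_target != target and t_target not in kep_rank_set:
                    labels.setdefault(t_target, set()).add(TYROSINASE)
                    truth[f"{contig}_r{t_target}"] = GeneTruth(
                        contig=contig,
                        rank=t_target,
                        labels=[TYROSINASE],
                        kep_protein_id=pid,
                        planted_distance=config.tyrosinase_distance,
                    )

    # background labels on untouched, non-KEP genes
    free = [
        r
        for r in range(1, n + 1)
        if r not in kep_rank_set and r not in labels
    ]
    n_bg = int(round(config.background_label_fraction * len(free)))
    if n_bg:
        for r in rng.choice(free, size=n_bg, replace=False):
            labels.setdefault(int(r), set()).add(MFS_1)

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    rank_to_pid = dict(zip(kep_ranks, kep_protein_ids))
    for rank in range(1, n + 1):
        pid = rank_to_pid.get(rank, f"{strain_id}_p{rank:04d}")
        gid = f"{strain_id}_g{rank:04d}"
        genes.append(GeneRecord(gid, pid, contig, rank, rank))
        for acc in sorted(labels.get(rank, ())):
            name = {DUF3328: "DUF3328", TYROSINASE: "Tyrosinase", MFS_1: "MFS_1"}[acc]
            hits.append(
                DomainHit(
                    protein_id=pid,
                    domain_accession=acc,
                    domain_name=name,
                    evalue=1e-10,
                    env_start=1,
                    env_end=50,
                )
            )
        for t in truth.values():
            if t.rank == rank:
                t.labels = sorted(labels.get(rank, ()))
    for rank, pid in rank_to_pid.items():
        truth[f"{contig}_r{rank}"] = GeneTruth(
            contig=contig, rank=rank, labels=["KEP"], kep_protein_id=pid
        )
    return genes, hits, truth


# ---------------------------------------------------------------------------
# whole datasets

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    proteins: list[ProteinRecord]
    predictions: dict[str, SignalPrediction]
    genes: list[GeneRecord]
    domain_hits: list[DomainHit]
    truth: GroundTruth
    ancestors: list[str]
    strain_table: "object" = None  # pandas DataFrame, filled by generate

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA, SignalP short table, gene-order TSV, domtblout and
        truth JSON into ``outdir``; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "signalp": outdir / "signalp_short.tsv",
            "genes": outdir / "gene_order.tsv",
            "domains": outdir / "domains.domtblout",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.proteins, paths["proteome"])
        write_signalp_short(self.predictions.values(), paths["signalp"])
        write_gene_order_tsv(self.genes, paths["genes"])
        write_domtblout(self.domain_hits, paths["domains"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "ancestors": self.ancestors,
                    "proteins": {k: asdict(v) for k, v in self.truth.proteins.items()},
                    "genes": {k: asdict(v) for k, v in self.truth.genes.items()},
                },
                fh,
                indent=1,
            )
        return paths

    def self_check(self) -> None:
        """Validate the ground truth against the in-memory records."""
        by_id = {p.protein_id: p for p in self.proteins}
        for pid, t in self.truth.proteins.items():
            rec = by_id[pid]
            if t.is_kep:
                assert t.cleavage_pos is not None
                mature = rec.sequence[t.cleavage_pos :]
                for start, end in t.unit_intervals:
                    assert 0 <= start < end <= len(mature)
                    assert not _has_dibasic(mature[start:end])
        rank_seen: dict[str, set[int]] = {}
        for g in self.genes:
            rank_seen.setdefault(g.contig_id, set()).add(g.start)
        for gt in self.truth.genes.values():
            assert gt.rank in rank_seen[gt.contig]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full study: per-strain proteomes with planted KEPs and
    decoys, plus gene orders with planted domain labels. Deterministic under
    ``config.rng_seed``."""
    import pandas as pd

    rng = np.random.default_rng(config.rng_seed)
    ancestors = make_family_ancestors(rng, config)

    proteins: list[ProteinRecord] = []
    predictions: dict[str, SignalPrediction] = {}
    genes: list[GeneRecord] = []
    domain_hits: list[DomainHit] = []
    truth = GroundTruth()
    strain_rows = []

    phyla = ("Ascomycota", "Basidiomycota")
    for s in range(config.n_strains):
        strain = f"strain{s:03d}"
        genus = f"Genus{s // 3:02d}"
        phylum = phyla[s % 2]
        strain_rows.append({"strain_id": strain, "genus": genus, "phylum": phylum})

        kep_ids = []
        for i in range(config.keps_per_strain):
            fam = int(rng.integers(0, config.n_families))
            pid = f"{strain}_KEP{i:02d}"
            rec, pred, pt = make_kep_protein(
                ancestors[fam], config, rng, pid, strain, genus, phylum, family_id=fam
            )
            proteins.append(rec)
            predictions[pid] = pred
            truth.proteins[pid] = pt
            kep_ids.append(pid)

        for cls in DECOY_CLASSES:
            for j in range(config.decoys_per_class):
                pid = f"{strain}_{cls}{j:02d}"
                rec, pred, pt = make_decoy(cls, config, rng, pid, strain, genus, phylum)
                proteins.append(rec)
                predictions[pid] = pred
                truth.proteins[pid] = pt

        g, h, gt = make_gene_order(strain, kep_ids, config, rng)
        genes.extend(g)
        domain_hits.extend(h)
        truth.genes.update(gt)

    ds = SyntheticDataset(
        config=config,
        proteins=proteins,
        predictions=predictions,
        genes=genes,
        domain_hits=domain_hits,
        truth=truth,
        ancestors=ancestors,
        strain_table=pd.DataFrame(strain_rows),
    )
    ds.self_check()
    return ds
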