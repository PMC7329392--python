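"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`SignalPrediction`, :class:`DomainHit` and
:class:`GeneRecord`. Supported formats: FASTA (via Bio.SeqIO), the SignalP
4.1 short-format table, HMMER3 ``--domtblout`` tables, GFF3 and a simple
4-column gene-order TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from Bio import SeqIO

#: The 20 proteinogenic residues plus X for unknown. X never matches any
#: residue (including another X) anywhere in the pipeline.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


class ParseError(ValueError):
    """A file violated its format contract; message carries the line number."""


@dataclass
class ProteinRecord:
    """One protein sequence with its identifiers.

    ``sequence`` is an uppercase string over the 20-letter alphabet plus X;
    residues outside that alphabet are mapped to X by :func:`read_fasta`.
    """

    protein_id: str
    sequence: str
    strain_id: str = ""
    genus: str = ""
    phylum: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: invalid residue(s) {sorted(bad)!r}; "
                "sequences must be uppercase, gap- and whitespace-free"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SignalPrediction:
    """Signal-peptide decision for one protein.

    ``cleavage_pos`` is the 1-based index of the *last* signal residue, so
    the mature sequence begins at ``cleavage_pos + 1`` (1-based), i.e.
    ``sequence[cleavage_pos:]`` in 0-based slicing. It is ``None`` when
    ``has_signal`` is false.
    """

    protein_id: str
    has_signal: bool
    cleavage_pos: int | None = None
    source: str = "file"  # "file" | "heuristic"

    def __post_init__(self) -> None:
        if self.has_signal:
            if self.cleavage_pos is None or self.cleavage_pos < 1:
                raise ValueError(
                    f"{self.protein_id}: cleavage_pos must be >= 1 when has_signal"
                )
        elif self.cleavage_pos is not None:
            raise ValueError(
                f"{self.protein_id}: cleavage_pos must be absent without a signal"
            )


@dataclass
class DomainHit:
    """One domain annotation (e.g. a Pfam hit from hmmscan)."""

    protein_id: str
    domain_accession: str
    domain_name: str
    evalue: float
    env_start: int  # 1-based inclusive
    env_end: int

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"{self.protein_id}: evalue must be > 0")
        if self.env_start < 1 or self.env_end < self.env_start:
            raise ValueError(
                f"{self.protein_id}: invalid envelope "
                f"[{self.env_start}, {self.env_end}]"
            )

    @property
    def accession_base(self) -> str:
        """Accession without its version suffix (``PF11807.8`` -> ``PF11807``)."""
        return self.domain_accession.split(".")[0]


@dataclass
class GeneRecord:
    """One gene with its genomic location and linked protein."""

    gene_id: str
    protein_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "unknown"  # "+" | "-" | "unknown"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )


# ---------------------------------------------------------------------------
# FASTA

def _default_metadata(record_id: str, description: str):
    """Pull ``strain= genus= phylum=`` tokens out of a FASTA description.

    Plain FASTA without those tokens yields empty metadata, so any input
    works; headers produced by :func:`write_fasta` round-trip.
    """
    meta = {"strain": "", "genus": "", "phylum": ""}
    for token in description.split():
        key, _, value = token.partition("=")
        if value and key in meta:
            meta[key] = value
    return meta["strain"], meta["genus"], meta["phylum"]


def read_fasta(
    path: str | Path,
    metadata_fn: Callable[[str, str], tuple[str, str, str]] = _default_metadata,
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Multi-line sequences are concatenated and uppercased; residues outside
    the 20-letter alphabet (B, Z, U, *, ...) are mapped to X. An empty file
    yields an empty list. Duplicate ids and empty headers raise
    :class:`ParseError` naming the offender and its line number.
    """
    path = Path(path)
    header_lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[idx] if idx < len(header_lines) else -1
        if not rec.id:
            raise ParseError(f"{path}:{lineno}: FASTA header without an identifier")
        if rec.id in seen:
            raise ParseError(
                f"{path}:{lineno}: duplicate protein id {rec.id!r} "
                f"(first seen at line {seen[rec.id]})"
            )
        seen[rec.id] = lineno
        seq = str(rec.seq).upper().replace("*", "")
        seq = "".join(c if c in ALPHABET else "X" for c in seq)
        if not seq:
            raise ParseError(f"{path}:{lineno}: record {rec.id!r} has an empty sequence")
        strain, genus, phylum = metadata_fn(rec.id, rec.description)
        records.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=seq,
                strain_id=strain,
                genus=genus,
                phylum=phylum,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, embedding strain/genus/phylum as header tokens."""
    with open(path, "w") as fh:
        for rec in records:
            meta = []
            if rec.strain_id:
                meta.append(f"strain={rec.strain_id}")
            if rec.genus:
                meta.append(f"genus={rec.genus}")
            if rec.phylum:
                meta.append(f"phylum={rec.phylum}")
            header = " ".join([rec.protein_id] + meta)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SignalP 4.1 short format
#
# Columns: name Cmax pos Ymax pos Smax pos Smean D ? Dmaxcut Networks-used
# The Ymax "pos" column reports the first mature residue; by the convention
# fixed here, cleavage_pos = pos - 1 (last signal residue).

def read_signalp_short(path: str | Path) -> dict[str, SignalPrediction]:
    path = Path(path)
    out: dict[str, SignalPrediction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 10 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            name = fields[0]
            try:
                ypos = int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer cleavage position {fields[4]!r}"
                ) from exc
            decision = fields[9]
            if decision not in ("Y", "N"):
                raise ParseError(
                    f"{path}:{lineno}: decision column must be Y or N, got "
                    f"{decision!r}"
                )
            if decision == "Y":
                out[name] = SignalPrediction(name, True, ypos - 1, source="file")
            else:
                out[name] = SignalPrediction(name, False, None, source="file")
    return out


def write_signalp_short(
    predictions: Iterable[SignalPrediction], path: str | Path
) -> None:
    """Emit a SignalP-4.1 short-format table (synthetic scores)."""
    with open(path, "w") as fh:
        fh.write("# SignalP-4.1 euk predictions\n")
        fh.write(
            "# name                     Cmax  pos  Ymax  pos  Smax  pos  Smean   D     ?  Dmaxcut    Networks-used\n"
        )
        for p in predictions:
            if p.has_signal:
                pos = p.cleavage_pos + 1
                fh.write(
                    f"{p.protein_id:<25s} 0.800 {pos:>4d} 0.800 {pos:>4d} 0.900 "
                    f"{max(pos - 1, 1):>4d} 0.850  0.820 Y 0.450     SignalP-noTM\n"
                )
            else:
                fh.write(
                    f"{p.protein_id:<25s} 0.100    5 0.100    5 0.120    "
                    f"4 0.110  0.105 N 0.450     SignalP-noTM\n"
                )


# ---------------------------------------------------------------------------
# HMMER3 --domtblout

_DOMTBL_NCOLS = 23  # fixed columns before the free-text description


def read_domtblout(path: str | Path, evalue_threshold: float = 1e-5) -> list[DomainHit]:
    """Read a hmmscan ``--domtblout`` table, keeping rows whose full-sequence
    E-value is <= ``evalue_threshold``.

    In hmmscan output the *target* is the profile (Pfam domain) and the
    *query* is the protein. Envelope coordinates are preserved.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, _DOMTBL_NCOLS - 1)
            if len(fields) < _DOMTBL_NCOLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_DOMTBL_NCOLS} columns in "
                    f"domtblout row, got {len(fields)}"
                )
            try:
                evalue = float(fields[6])
                env_start = int(fields[19])
                env_end = int(fields[20])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if evalue > evalue_threshold:
                continue
            hits.append(
                DomainHit(
                    protein_id=fields[3],
                    domain_accession=fields[1],
                    domain_name=fields[0],
                    evalue=max(evalue, 1e-300),
                    env_start=env_start,
                    env_end=env_end,
                )
            )
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Emit domain hits in hmmscan ``--domtblout`` column layout."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        for h in hits:
            tlen = h.env_end - h.env_start + 1
            fh.write(
                f"{h.domain_name:<20s} {h.domain_accession:<11s} {tlen:4d} "
                f"{h.protein_id:<20s} -           {h.env_end + 10:4d} "
                f"{h.evalue:9.2g} {50.0:6.1f} {0.1:5.1f} {1:3d} {1:3d} "
                f"{h.evalue:9.2g} {h.evalue:9.2g} {49.0:6.1f} {0.1:5.1f} "
                f"{1:5d} {tlen:5d} {h.env_start:5d} {h.env_end:5d} "
                f"{h.env_start:5d} {h.env_end:5d} 0.95 -\n"
            )


# ---------------------------------------------------------------------------
# Gene order: GFF3 or 4-column TSV (contig, rank-or-start, gene_id, protein_id)

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.strip().partition("=")
        attrs[key] = value
    return attrs


def read_gene_order(
    path: str | Path,
    dialect: str = "tsv",
    protein_id_attr: str = "protein_id",
) -> list[GeneRecord]:
    """Read gene order from a GFF3 file or a 4-column TSV.

    The TSV dialect is ``contig <tab> rank-or-start <tab> gene_id <tab>
    protein_id``; rank/start is used directly as both start and end so that
    per-contig gene rank is the ordering by that number. For GFF3, ``gene``
    features are used and the protein link is resolved from the configured
    attribute key on the gene or any of its ``mRNA``/``CDS`` children. A gene
    without a resolvable protein id is kept with an empty ``protein_id`` and
    a warning.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_gene_order_tsv(path)
    if dialect == "gff3":
        return _read_gene_order_gff3(path, protein_id_attr)
    raise ValueError(f"unknown gene-order dialect {dialect!r}")


def _read_gene_order_tsv(path: Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got "
                    f"{len(fields)}"
                )
            contig, pos_s, gene_id, protein_id = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer rank/start {pos_s!r}"
                ) from exc
            records.append(GeneRecord(gene_id, protein_id, contig, pos, pos))
    return records


def _read_gene_order_gff3(path: Path, protein_id_attr: str) -> list[GeneRecord]:
    # One linear pass: gene rows become records; mRNA/CDS rows may carry the
    # protein link of their (grand)parent gene via Parent= chains.
    genes: list[GeneRecord] = []
    gene_index: dict[str, int] = {}
    parent_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                )
            contig, _, ftype, start_s, end_s, _, strand, _, attr_s = fields
            if ftype not in ("gene", "mRNA", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(
                    f"{path}:{lineno}: feature end {end} < start {start}"
                )
            attrs = _parse_gff3_attributes(attr_s)
            fid = attrs.get("ID", "")
            if ftype == "gene":
                if not fid:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                gene_index[fid] = len(genes)
                genes.append(
                    GeneRecord(
                        gene_id=fid,
                        protein_id=attrs.get(protein_id_attr, ""),
                        contig_id=contig,
                        start=start,
                        end=end,
                        strand=strand if strand in "+-" else "unknown",
                    )
                )
            else:
                parent = attrs.get("Parent", "")
                if fid and parent:
                    parent_of[fid] = parent
                pid = attrs.get(protein_id_attr, "")
                if pid and parent:
                    root = parent
                    while root not in gene_index and root in parent_of:
                        root = parent_of[root]
                    if root in gene_index and not genes[gene_index[root]].protein_id:
                        genes[gene_index[root]].protein_id = pid
    for g in genes:
        if not g.protein_id:
            warnings.warn(
                f"gene {g.gene_id} has no resolvable {protein_id_attr}; kept with "
                "empty protein_id",
                stacklevel=2,
            )
    return genes


def write_gene_order_tsv(records: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig_id}\t{r.start}\t{r.gene_id}\t{r.protein_id}\n")
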