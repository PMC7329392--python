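"""Pipeline parameters. Defaults are the published thresholds of the method."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineParams:
    """Every numeric constant of the mining pipeline in one place.

    Defaults: 40-aa seeds with a 0.6 repeated-position score threshold; Kex2
    dibasic motifs KR/KK/RK/RR; a KEP needs >= 3 repeat units of 8-100 aa and
    no Kex2 fragment longer than 100 aa; typing uses reciprocal hits with
    E < 1e-30 and query coverage > 70%; repeat-unit sub-typing uses identity
    > 65% and coverage > 70%; cross-study set comparison uses 95%/95%;
    pheromone annotation uses E < 1e-10; domain tables are filtered at
    E <= 1e-5; the gene-neighborhood radius is 15 genes on each side.
    """

    seed_length: int = 40
    repeat_threshold: float = 0.6
    coherence_window: int = 12
    min_local_identity: float = 2 / 3
    min_mature_length: int = 16
    min_unit_len: int = 8
    max_fragment_len: int = 100
    min_units: int = 3
    masked_fraction: float = 0.5
    kex2_motifs: tuple[str, ...] = ("KR", "KK", "RK", "RR")

    type_evalue: float = 1e-30
    type_coverage: float = 0.70
    subtype_identity: float = 0.65
    subtype_coverage: float = 0.70
    setcompare_identity: float = 0.95
    setcompare_coverage: float = 0.95
    pheromone_evalue: float = 1e-10
    domain_evalue: float = 1e-5

    vicinity_radius: int = 15
    allhits_max_dist: int = 10

    # local-alignment scoring (see similarity.AlignmentParams)
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self) -> None:
        for name in (
            "seed_length", "repeat_threshold", "min_unit_len", "max_fragment_len",
            "min_units", "type_evalue", "type_coverage", "subtype_identity",
            "subtype_coverage", "pheromone_evalue", "domain_evalue",
            "vicinity_radius", "gap_open", "gap_extend", "ka_lambda", "ka_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
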