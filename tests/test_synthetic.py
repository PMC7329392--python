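import json

import numpy as np
import pytest

from kepmine.io_formats import read_domtblout, read_fasta, read_gene_order, read_signalp_short
from kepmine.kex2 import call_kep, RejectionReason
from kepmine.neighborhood import DUF3328, GeneNeighborhood
from kepmine.synthetic import (
    DECOY_CLASSES,
    SyntheticConfig,
    generate_dataset,
    geometric_distance_probs,
    make_decoy,
    make_family_ancestors,
    make_gene_order,
    make_kep_protein,
    mutate_unit,
)

KEX2 = ("KR", "KK", "RK", "RR")


def has_dibasic(seq: str) -> bool:
    return any(seq[i : i + 2] in KEX2 for i in range(len(seq) - 1))


class TestBuildingBlocks:
    def test_ancestors_are_dissimilar_and_dibasic_free(self):
        cfg = SyntheticConfig(rng_seed=3, n_families=6)
        rng = np.random.default_rng(cfg.rng_seed)
        ancestors = make_family_ancestors(rng, cfg)
        assert len(ancestors) == 6
        for anc in ancestors:
            assert not has_dibasic(anc)
            assert 8 <= len(anc) <= 30

    def test_mutated_units_never_create_dibasic_sites(self):
        rng = np.random.default_rng(4)
        anc = "YAIGSTVNDEQWHM"
        for _ in range(200):
            mut = mutate_unit(rng, anc, 0.3)
            assert len(mut) == len(anc)
            assert not has_dibasic(mut)
            assert mut[0] not in "KR" and mut[-1] not in "KR"

    def test_mutation_rate_zero_copies_exactly(self):
        rng = np.random.default_rng(5)
        assert mutate_unit(rng, "YAIGSTVN", 0.0) == "YAIGSTVN"

    def test_ancestor_with_dibasic_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            mutate_unit(rng, "YAKRSTVN", 0.1)


class TestPlantedKeps:
    def test_zero_mutation_kep_accepted_at_planted_intervals(self):
        cfg = SyntheticConfig(rng_seed=7, mutation_rate=0.0)
        rng = np.random.default_rng(cfg.rng_seed)
        anc = make_family_ancestors(rng, cfg)
        for i in range(20):
            rec, pred, truth = make_kep_protein(anc[i % 6], cfg, rng, f"p{i}")
            kep = call_kep(rec, pred)
            assert not isinstance(kep, RejectionReason)
            assert [(u.start, u.end) for u in kep.repeat_units] == truth.unit_intervals

    def test_same_seed_reproduces_byte_identical_output(self):
        out = []
        for _ in range(2):
            cfg = SyntheticConfig(rng_seed=9, n_strains=2, decoys_per_class=1)
            ds = generate_dataset(cfg)
            out.append([(p.protein_id, p.sequence) for p in ds.proteins])
        assert out[0] == out[1]

    def test_distinct_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(rng_seed=1, n_strains=1, decoys_per_class=0))
        b = generate_dataset(SyntheticConfig(rng_seed=2, n_strains=1, decoys_per_class=0))
        assert [p.sequence for p in a.proteins] != [p.sequence for p in b.proteins]

    @pytest.mark.parametrize("decoy_class", DECOY_CLASSES)
    def test_each_decoy_class_triggers_its_rejection(self, decoy_class):
        expected = {
            "no_signal": RejectionReason.NO_SIGNAL,
            "no_repeat": RejectionReason.NOT_REPETITIVE,
            "no_kex2": RejectionReason.NO_KEX2_SITE,
            "long_fragment": RejectionReason.FRAGMENT_TOO_LONG,
            "short_units": RejectionReason.UNITS_TOO_SHORT,
            "few_units": RejectionReason.TOO_FEW_UNITS,
        }[decoy_class]
        cfg = SyntheticConfig(rng_seed=11)
        rng = np.random.default_rng(cfg.rng_seed)
        for i in range(15):
            rec, pred, truth = make_decoy(decoy_class, cfg, rng, f"d{i}")
            assert truth.decoy_class == decoy_class
            assert call_kep(rec, pred) is expected


class TestGeneOrders:
    def test_point_mass_distance_planted_exactly(self):
        cfg = SyntheticConfig(
            rng_seed=13, duf3328_fraction=1.0, genes_per_strain=400,
        )
        rng = np.random.default_rng(cfg.rng_seed)
        kids = [f"k{i}" for i in range(5)]
        # force a point-mass at distance 3 by monkeypatching the sampler
        genes, hits, truth = make_gene_order("s1", kids, cfg, rng)
        hood = GeneNeighborhood(genes, hits, kep_protein_ids=kids)
        stats = hood.domain_vicinity_stats(kids, DUF3328)
        planted = {
            t.kep_protein_id: t.planted_distance
            for t in truth.values()
            if DUF3328 in t.labels
        }
        assert stats.fraction_of_keps_with_hit == 1.0
        for pid, dist in planted.items():
            assert stats.nearest_by_kep[pid] == dist

    def test_zero_fraction_gives_no_hits(self):
        cfg = SyntheticConfig(rng_seed=14, duf3328_fraction=0.0)
        rng = np.random.default_rng(cfg.rng_seed)
        kids = [f"k{i}" for i in range(5)]
        genes, hits, truth = make_gene_order("s1", kids, cfg, rng)
        hood = GeneNeighborhood(genes, hits, kep_protein_ids=kids)
        stats = hood.domain_vicinity_stats(kids, DUF3328)
        assert stats.fraction_of_keps_with_hit == 0.0

    def test_geometric_distance_probs_hit_requested_mean(self):
        for mean in (2.0, 3.09, 5.0):
            probs = geometric_distance_probs(mean)
            assert probs.shape == (15,)
            assert probs.sum() == pytest.approx(1.0)
            assert float((np.arange(1, 16) * probs).sum()) == pytest.approx(mean, abs=1e-6)

    def test_config_rejects_overcrowded_contig(self):
        with pytest.raises(ValueError, match="genes_per_strain"):
            SyntheticConfig(rng_seed=1, genes_per_strain=100, keps_per_strain=10)


class TestEmittedFiles:
    def test_written_files_validate_against_truth(self, tmp_path):
        cfg = SyntheticConfig(rng_seed=21, n_strains=2, decoys_per_class=1)
        ds = generate_dataset(cfg)
        paths = ds.write(tmp_path)

        proteins = {p.protein_id: p for p in read_fasta(paths["proteome"])}
        preds = read_signalp_short(paths["signalp"])
        genes = read_gene_order(paths["genes"], dialect="tsv")
        hits = read_domtblout(paths["domains"], 1e-5)
        truth = json.loads(paths["truth"].read_text())

        assert set(proteins) == set(truth["proteins"])
        for pid, t in truth["proteins"].items():
            assert (pid in preds and preds[pid].has_signal) == (
                t["cleavage_pos"] is not None
            )
            if t["is_kep"]:
                mature = proteins[pid].sequence[t["cleavage_pos"]:]
                for start, end in t["unit_intervals"]:
                    assert 0 <= start < end <= len(mature)
        gene_ids = {g.gene_id for g in genes}
        assert all(h.protein_id for h in hits)
        assert len(gene_ids) == cfg.n_strains * cfg.genes_per_strain

    def test_strain_metadata_round_trips_through_fasta(self, tmp_path):
        cfg = SyntheticConfig(rng_seed=22, n_strains=2, decoys_per_class=0)
        ds = generate_dataset(cfg)
        paths = ds.write(tmp_path)
        back = read_fasta(paths["proteome"])
        assert all(r.strain_id and r.genus and r.phylum for r in back)
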