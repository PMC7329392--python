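import numpy as np
import pandas as pd
import pytest

from kepmine.annotation import (
    AnnotationFlags,
    annotate_keps,
    flag_mating_factor,
    flag_pheromone,
    motif_content_rate,
    phylum_summary,
    type_summary,
)
from kepmine.families import KEPType
from kepmine.io_formats import DomainHit, ProteinRecord, SignalPrediction
from kepmine.kex2 import call_kep
from tests.conftest import random_protein_sequence, toy_kep


def make_kep(pid="k1", strain="s1", genus="G1", phylum="Ascomycota"):
    signal, mature = toy_kep()
    rec = ProteinRecord(pid, signal + mature, strain, genus, phylum)
    kep = call_kep(rec, SignalPrediction(pid, True, len(signal)))
    assert not isinstance(kep, type(None))
    return kep


def hit(pid, acc, evalue=1e-8):
    return DomainHit(pid, acc, acc, evalue, 1, 20)


class TestMatingFactorFlag:
    def test_mf_alpha_domain_flags(self):
        kep = make_kep()
        assert flag_mating_factor(kep, [hit("k1", "PF04648.10")])

    def test_mf_alpha_n_alone_flags(self):
        kep = make_kep()
        assert flag_mating_factor(kep, [hit("k1", "PF05436")])

    def test_no_hits_or_wrong_protein_does_not_flag(self):
        kep = make_kep()
        assert not flag_mating_factor(kep, [])
        assert not flag_mating_factor(kep, [hit("other", "PF04648")])

    def test_weak_evalue_does_not_flag(self):
        kep = make_kep()
        assert not flag_mating_factor(kep, [hit("k1", "PF04648", evalue=1e-3)])


class TestPheromoneFlag:
    def test_kep_identical_to_query_flags(self):
        kep = make_kep()
        query = ProteinRecord("q1", kep.protein.sequence)
        assert flag_pheromone(kep, [query])

    def test_random_sequence_vs_unrelated_queries_does_not_flag(self):
        rng = np.random.default_rng(0)
        kep = make_kep()
        queries = [
            ProteinRecord(f"q{i}", random_protein_sequence(rng, 80)) for i in range(3)
        ]
        assert not flag_pheromone(kep, queries)

    def test_empty_query_set_never_flags(self):
        assert not flag_pheromone(make_kep(), [])

    def test_annotate_keps_attaches_flags(self):
        kep = make_kep()
        annotate_keps([kep], domain_hits=[hit("k1", "PF04648")])
        assert isinstance(kep.annotation, AnnotationFlags)
        assert kep.annotation.is_yeast_alpha_mating_factor
        assert not kep.annotation.is_fungal_pheromone


class TestMotifRates:
    @pytest.mark.parametrize(
        "units,motif,rate",
        [
            (["YAIGSTVN", "AAAAAAAA"], "Y", 0.5),
            (["WWHHAAAA", "GGGGGGGG", "HHHHHHHH"], "HH", 2 / 3),
            (["YAIGSTVN", "YYYYYYYY"], "Y", 1.0),
            ([], "Y", 0.0),
        ],
    )
    def test_rates(self, units, motif, rate):
        assert motif_content_rate(units, motif) == pytest.approx(rate)

    def test_units_outside_length_range_excluded(self):
        # 4-aa and 120-aa sequences fall outside the 8..100 window
        units = ["YAIG", "Y" * 120, "AAAAAAAA"]
        assert motif_content_rate(units, "Y") == 0.0


class TestPhylumSummary:
    def test_two_strain_mean_and_sample_sd(self):
        keps = []
        for strain, n in (("s1", 5), ("s2", 7)):
            for i in range(n):
                keps.append(make_kep(f"{strain}_k{i}", strain, "G1", "Blastocladiomycota"))
        strains = pd.DataFrame(
            {"strain_id": ["s1", "s2"], "genus": ["G1", "G1"],
             "phylum": ["Blastocladiomycota"] * 2}
        )
        df = phylum_summary(keps, strains)
        row = df[df.phylum == "Blastocladiomycota"].iloc[0]
        assert row.keps_total == 12
        assert row.keps_per_found_strain == pytest.approx(6.00)
        assert row.sd == pytest.approx(1.41)

    def test_single_strain_sd_is_zero(self):
        keps = [make_kep(f"k{i}", "s1", "G1", "P1") for i in range(3)]
        strains = pd.DataFrame(
            {"strain_id": ["s1"], "genus": ["G1"], "phylum": ["P1"]}
        )
        df = phylum_summary(keps, strains)
        assert df[df.phylum == "P1"].iloc[0].sd == 0.0

    def test_totals_row_conserves_counts(self):
        keps = [make_kep(f"k{i}", f"s{i%3}", f"G{i%2}", ["P1", "P2"][i % 2])
                for i in range(8)]
        strains = pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(3)] + ["s_empty"],
                "genus": ["G0", "G1", "G0", "G1"],
                "phylum": ["P1", "P2", "P1", "P2"],
            }
        )
        df = phylum_summary(keps, strains)
        total = df[df.phylum == "Total"].iloc[0]
        parts = df[df.phylum != "Total"]
        assert total.keps_total == parts.keps_total.sum() == 8
        assert total.strains_surveyed == 4

    def test_strains_with_zero_keps_counted_as_surveyed_not_found(self):
        keps = [make_kep("k1", "s1", "G1", "P1")]
        strains = pd.DataFrame(
            {"strain_id": ["s1", "s2"], "genus": ["G1", "G1"], "phylum": ["P1", "P1"]}
        )
        row = phylum_summary(keps, strains).iloc[0]
        assert row.strains_surveyed == 2 and row.strains_found == 1
        assert row.keps_per_found_strain == 1.0


class TestTypeSummary:
    def test_counts_and_duf_split(self):
        keps = [make_kep(f"k{i}", "s1", "G1", "P1") for i in range(3)]
        for kep, duf in zip(keps, (True, False, True)):
            kep.duf3328_within_radius = duf
            kep.annotation = AnnotationFlags(is_yeast_alpha_mating_factor=duf)
        types = [KEPType(label="#1", member_ids=[k.protein_id for k in keps])]
        for k in keps:
            types[0].strain_counts[k.protein.strain_id] += 1
            types[0].genus_counts[k.protein.genus] += 1
            types[0].phylum_counts[k.protein.phylum] += 1
        df = type_summary(types, keps)
        row = df.iloc[0]
        assert row["count"] == 3
        assert row.keps_per_strain == pytest.approx(3.0)
        assert row.genera == 1 and row.phyla == 1
        assert row.with_duf3328 == 2 and row.without_duf3328 == 1
        assert row.yeast_alpha_mating_factors == 2
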