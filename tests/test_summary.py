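"""Composition, occupancy, organizational-form and correspondence statistics."""

import pandas as pd
import pytest

from satorg.annotate import MonomerHit
from satorg.boxes import (BOTH_BOXES, NO_BOXES, ONE_BOX, OrganizationalCall)
from satorg.seqio import GenomeSequence, GenomicInterval
from satorg.summary import (assembly_correspondence, form_summary,
                            genome_fraction_from_annotation, mean_occupancy,
                            occupancy_table, satellitome_fraction,
                            widespread_count)
from satorg.tables import load_table1, load_table2


def hit(family, seq_id, start):
    return MonomerHit(family, family,
                      GenomicInterval(seq_id, start, start + 100),
                      identity=0.9, consensus_coverage=1.0, complete=True)


@pytest.fixture(scope="module")
def table1():
    return load_table1()


@pytest.fixture(scope="module")
def panel1():
    return load_table2("GCA_902806645.1")


@pytest.fixture(scope="module")
def panel2():
    return load_table2("GCA_011032805.1")


class TestOccupancyTable:
    def test_presence_and_counts(self):
        hits = [hit("A", "chr1", 0), hit("A", "chr1", 500),
                hit("A", "scaf7", 0), hit("B", "chr2", 10)]
        occ = occupancy_table(hits, ["chr1", "chr2"])
        a = occ[occ.family_id == "A"].iloc[0]
        assert bool(a["chr1"]) and not bool(a["chr2"])
        assert a.chromosomes_occupied == 1
        assert a.monomers_on_chromosomes == 2
        assert a.monomers_on_scaffolds == 1
        assert a.mean_monomers_per_chromosome == 2

    def test_no_hits_empty_table(self):
        assert occupancy_table([], ["chr1"]).empty

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            occupancy_table([hit("A", "chr1", 0)], ["chr1", "chrX"],
                            all_seq_ids=["chr1", "scaf1"])

    def test_presence_monotone_under_added_hits(self):
        base = [hit("A", "chr1", 0)]
        more = base + [hit("A", "chr2", 0), hit("A", "scaf1", 0)]
        occ1 = occupancy_table(base, ["chr1", "chr2"])
        occ2 = occupancy_table(more, ["chr1", "chr2"])
        assert occ2.loc[0, "chr1"] and occ1.loc[0, "chr1"]
        assert occ2.loc[0, "chromosomes_occupied"] >= \
            occ1.loc[0, "chromosomes_occupied"]


class TestWidespread:
    def test_panel1_count(self, panel1):
        assert widespread_count(panel1) == 25

    def test_empty(self):
        assert widespread_count(pd.DataFrame()) == 0

    def test_toy_all_widespread(self):
        hits = [hit("F%d" % i, "chr%d" % c, 0)
                for i in range(3) for c in range(1, 11)]
        occ = occupancy_table(hits, [f"chr{c}" for c in range(1, 11)])
        assert widespread_count(occ) == 3


class TestMeanOccupancy:
    def test_helitron_families(self, table1, panel1):
        helitron = table1[table1.repbase_class == "DNA/Helitron"] \
            .family_id.unique()
        assert len(helitron) == 15
        assert mean_occupancy(panel1, helitron) == 9.7

    def test_repbase_annotated_families(self, table1, panel1):
        annotated = table1[table1.repbase_class != ""].family_id.unique()
        assert len(annotated) == 39
        assert mean_occupancy(panel1, annotated) == 7.3

    def test_singleton(self, panel1):
        assert mean_occupancy(panel1, ["CgiSat22"]) == 1.0

    def test_empty_subset_rejected(self, panel1):
        with pytest.raises(ValueError):
            mean_occupancy(panel1, [])


class TestSatellitomeFraction:
    def test_helitron_fraction(self, table1):
        value = satellitome_fraction(
            table1, lambda r: r.repbase_class == "DNA/Helitron")
        assert value == pytest.approx(75.61, abs=0.02)

    def test_mobile_element_fraction(self, table1):
        # the printed rows sum to 91.74 vs the printed total 91.76: compare
        # at print precision so the 0.02 rounding residue is tolerated
        value = satellitome_fraction(table1, lambda r: r.repbase_class != "")
        assert round(abs(value - 91.76), 2) <= 0.02

    def test_nucleosomal_band(self, table1):
        value = satellitome_fraction(
            table1, lambda r: 160 <= r.monomer_length <= 180)
        assert value == pytest.approx(33, abs=0.2)

    def test_empty_predicate(self, table1):
        assert satellitome_fraction(table1, lambda r: False) == 0.0

    def test_complementary_predicates_sum_to_total(self, table1):
        total = table1.satellitome_pct.sum()
        a = satellitome_fraction(table1, lambda r: r.monomer_length < 400)
        b = satellitome_fraction(table1, lambda r: r.monomer_length >= 400)
        assert a + b == pytest.approx(total, abs=0.01)


class TestFormSummary:
    def _call(self, category, monomers=1, family="F"):
        form = "standalone" if category == NO_BOXES else "element_associated"
        return OrganizationalCall(f"{family}|g:0-1(+)", family, monomers,
                                  category, form)

    def test_all_element_associated(self):
        summary = form_summary([self._call(BOTH_BOXES)] * 10)
        assert summary.pct_element_associated == 100.0
        assert summary.pct_standalone == 0.0

    def test_even_split(self):
        calls = [self._call(BOTH_BOXES), self._call(ONE_BOX),
                 self._call(NO_BOXES), self._call(NO_BOXES)]
        summary = form_summary(calls)
        assert summary.pct_element_associated == 50.0
        assert summary.pct_standalone == 50.0

    def test_histogram_total_and_max_lengths(self):
        calls = [self._call(BOTH_BOXES, 3), self._call(NO_BOXES, 7),
                 self._call(NO_BOXES, 1), self._call(ONE_BOX, 2)]
        summary = form_summary(calls)
        assert summary.histogram.to_numpy().sum() == summary.n_extractions
        assert summary.max_len_element_associated == 3
        assert summary.max_len_standalone == 7

    def test_order_invariance(self):
        calls = [self._call(BOTH_BOXES, 3), self._call(NO_BOXES, 7),
                 self._call(ONE_BOX, 2)]
        a = form_summary(calls)
        b = form_summary(calls[::-1])
        assert a.pct_element_associated == b.pct_element_associated
        assert a.histogram.equals(b.histogram)

    def test_mixed_families_rejected(self):
        with pytest.raises(ValueError):
            form_summary([self._call(NO_BOXES, family="A"),
                          self._call(NO_BOXES, family="B")])


class TestAssemblyCorrespondence:
    def test_published_panels(self, panel1, panel2):
        pairs = assembly_correspondence(panel1, panel2)
        assert len(pairs) == 4
        as_dict = {(r.chromosome_a, r.chromosome_b): r.supporting_families
                   for r in pairs.itertuples()}
        assert as_dict[("LG4", "chr8")] == "CgiSat22"
        assert as_dict[("LG8", "chr4")] == "CgiSat26"
        assert set(as_dict[("LG1", "chr7")].split(",")) == \
            {"CgiSat31", "CgiSat52"}
        assert as_dict[("LG2", "chr1")] == "CgiSat41"
        supporters = ",".join(as_dict.values()).split(",")
        assert sorted(supporters) == ["CgiSat22", "CgiSat26", "CgiSat31",
                                      "CgiSat41", "CgiSat52"]
        # CgiSat45 has 11 scaffold monomers, CgiSat36 is single-locus in
        # only one assembly: both must be excluded
        assert "CgiSat45" not in supporters
        assert "CgiSat36" not in supporters

    def test_no_family_pairs_two_partners(self, panel1, panel2):
        pairs = assembly_correspondence(panel1, panel2)
        seen = {}
        for row in pairs.itertuples():
            for fam in row.supporting_families.split(","):
                assert fam not in seen
                seen[fam] = (row.chromosome_a, row.chromosome_b)


class TestGenomeFraction:
    def test_simple_fraction(self, rng):
        from conftest import random_seq

        genome = GenomeSequence("g", random_seq(rng, 100_000))
        hits = [hit("A", "g", i * 200) for i in range(10)]  # 1000 bp total
        frac = genome_fraction_from_annotation(hits, [genome])
        assert frac["A"] == pytest.approx(1.0)

    def test_overlapping_hits_counted_once(self, rng):
        from conftest import random_seq

        genome = GenomeSequence("g", random_seq(rng, 10_000))
        hits = [hit("A", "g", 0), hit("A", "g", 50)]  # overlap 50 bp
        frac = genome_fraction_from_annotation(hits, [genome])
        assert frac["A"] == pytest.approx(1.5)

    def test_no_hits(self, rng):
        from conftest import random_seq

        genome = GenomeSequence("g", random_seq(rng, 1000))
        assert genome_fraction_from_annotation([], [genome]).empty
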