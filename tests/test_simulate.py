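"""Synthetic genome generator and recovery evaluation."""

import itertools

import numpy as np
import pytest

from satorg.annotate import MonomerHit, annotate_family
from satorg.boxes import BOTH_BOXES, NO_BOXES, ONE_BOX, OrganizationalCall
from satorg.seqio import GenomicInterval
from satorg.simulate import (EXPECTED_CATEGORY, FamilySim, PlantedCopy,
                             PlantedUnit, SimulationConfig, SyntheticManifest,
                             evaluate_recovery, mutate_sequence,
                             simulate_genome)

SMALL_FAMILIES = [
    FamilySim("S166", 166, "groupA", 4, 2, 4),
    FamilySim("S437", 437, "groupB", 4, 2, 4),
]


def small_config(**kw):
    defaults = dict(n_chromosomes=1, chromosome_length=90_000,
                    families=[FamilySim(**vars(f)) for f in SMALL_FAMILIES])
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = simulate_genome(small_config(seed=5))
        b = simulate_genome(small_config(seed=5))
        assert [g.sequence for g in a.genomes] == \
            [g.sequence for g in b.genomes]
        assert a.manifest.to_frame().equals(b.manifest.to_frame())
        assert a.manifest.copies_frame().equals(b.manifest.copies_frame())

    def test_different_seeds_differ(self):
        a = simulate_genome(small_config(seed=5))
        b = simulate_genome(small_config(seed=6))
        assert a.genomes[0].sequence != b.genomes[0].sequence

    def test_zero_units_background_only(self):
        cfg = small_config(families=[FamilySim("S", 100, "none", 0, 0, 0)])
        sim = simulate_genome(cfg)
        assert sim.manifest.units == []
        assert len(sim.genomes[0]) == cfg.chromosome_length

    def test_units_that_do_not_fit_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(small_config(chromosome_length=20_000))

    def test_unit_spacing_at_least_two_kb(self):
        sim = simulate_genome(small_config(seed=3))
        by_chrom = {}
        for u in sim.manifest.units:
            by_chrom.setdefault(u.seq_id, []).append(u)
        for units in by_chrom.values():
            units.sort(key=lambda u: u.start)
            for prev, cur in zip(units, units[1:]):
                assert cur.start - prev.end >= 2000

    def test_planted_sequences_match_manifest(self):
        """At zero divergence the genome substring at each copy interval is
        exactly the consensus (or its reverse complement)."""
        from satorg.seqio import reverse_complement

        sim = simulate_genome(small_config(seed=4))
        consensi = {f.family_id: f.consensus for f in sim.families}
        genomes = {g.id: g.sequence for g in sim.genomes}
        for u in sim.manifest.units:
            expected = consensi[u.family_id]
            if u.strand == "-":
                expected = reverse_complement(expected)
            for c in u.copies:
                assert genomes[u.seq_id][c.start : c.end] == expected
                assert c.identity == 1.0

    def test_box_group_constraint(self):
        with pytest.raises(ValueError, match="box group"):
            FamilySim("S", 100, "none", n_full=1)

    def test_single_monomer_units_dominate(self):
        sim = simulate_genome(SimulationConfig(seed=11))
        counts = [u.monomer_count for u in sim.manifest.units]
        assert sum(c == 1 for c in counts) / len(counts) >= 0.4

    def test_config_json_round_trip(self, tmp_path):
        cfg = small_config(seed=9, substitution_rate=0.1)
        p = tmp_path / "sim.json"
        cfg.to_json(p)
        back = SimulationConfig.from_json(p)
        assert back == cfg


class TestMutateSequence:
    def test_zero_rates_identity(self, rng):
        from conftest import random_seq

        s = random_seq(rng, 500)
        assert mutate_sequence(s, 0.0, 0.0, rng) == s

    def test_full_substitution_changes_every_base(self, rng):
        from conftest import random_seq

        s = random_seq(rng, 300)
        mutated = mutate_sequence(s, 1.0, 0.0, rng)
        assert len(mutated) == len(s)
        assert all(a != b for a, b in zip(s, mutated))

    def test_realized_rate_within_binomial_bounds(self, rng):
        from conftest import random_seq

        n, rate = 10_000, 0.2
        s = random_seq(rng, n)
        mutated = mutate_sequence(s, rate, 0.0, rng)
        mismatches = sum(a != b for a, b in zip(s, mutated))
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(mismatches - n * rate) <= 3 * sd

    def test_bad_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", -0.1, 0.0, rng)

    def test_indels_change_length(self, rng):
        from conftest import random_seq

        s = random_seq(rng, 2000)
        mutated = mutate_sequence(s, 0.0, 0.05, rng)
        assert mutated != s


def _manifest_unit(i, form, family="S166", group="groupA", count=1):
    start = 10_000 * (i + 1)
    copies = tuple(PlantedCopy(start + j * 166, start + (j + 1) * 166, 1.0)
                   for j in range(count))
    return PlantedUnit(family, "chr1", start - 100, start + count * 166 + 100,
                       "+", form, count, start, start + count * 166, group,
                       copies)


def _call_for(unit, category):
    form = "standalone" if category == NO_BOXES else "element_associated"
    eid = (f"{unit.family_id}|{unit.seq_id}"
           f":{unit.array_start}-{unit.array_end}(+)")
    return OrganizationalCall(eid, unit.family_id, unit.monomer_count,
                              category, form)


class TestEvaluateRecovery:
    def test_perfect_outputs(self):
        units = [_manifest_unit(0, "full"), _manifest_unit(1, "standalone")]
        manifest = SyntheticManifest(units)
        hits = [MonomerHit(u.family_id, u.family_id,
                           GenomicInterval(u.seq_id, c.start, c.end),
                           identity=1.0, consensus_coverage=1.0,
                           complete=True)
                for u in units for c in u.copies]
        calls = [_call_for(u, u.expected_category) for u in units]
        report = evaluate_recovery(manifest, hits, calls)
        assert report.monomer_recall == 1.0
        assert report.monomer_precision == 1.0
        assert report.form_accuracy == 1.0
        assert report.count_exactness == 1.0

    def test_empty_outputs(self):
        manifest = SyntheticManifest([_manifest_unit(0, "full")])
        report = evaluate_recovery(manifest, [], [])
        assert report.monomer_recall == 0.0
        assert report.monomer_precision is None
        assert report.missed_copies

    def test_relabelled_forms_match_enumeration(self):
        """Form accuracy over every possible relabelling of n <= 6 units
        equals the direct fraction-correct count (exhaustive oracle)."""
        forms = ["full", "truncated_left", "standalone"]
        units = [_manifest_unit(i, forms[i % 3]) for i in range(4)]
        manifest = SyntheticManifest(units)
        categories = [BOTH_BOXES, ONE_BOX, NO_BOXES]
        for labels in itertools.product(categories, repeat=len(units)):
            calls = [_call_for(u, lab) for u, lab in zip(units, labels)]
            report = evaluate_recovery(manifest, [], calls)
            expected = sum(
                lab == EXPECTED_CATEGORY[u.form]
                for u, lab in zip(units, labels)
            ) / len(units)
            assert report.form_accuracy == pytest.approx(expected)


class TestRecallMonotonicity:
    def test_recall_non_increasing_in_substitution_rate(self):
        """Averaged over seeds, raising the substitution rate never raises
        monomer recall."""
        rates = (0.0, 0.15, 0.3)
        mean_recall = []
        for rate in rates:
            recalls = []
            for seed in (1, 2, 3):
                sim = simulate_genome(small_config(
                    seed=seed, substitution_rate=rate))
                by_family = {}
                for fam in sim.families:
                    by_family.setdefault(fam.family_id, []).append(fam)
                hits = []
                for variants in by_family.values():
                    hits.extend(annotate_family(sim.genomes, variants))
                recalls.append(
                    evaluate_recovery(sim.manifest, hits).monomer_recall)
            mean_recall.append(np.mean(recalls))
        assert mean_recall[0] >= mean_recall[1] >= mean_recall[2]
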