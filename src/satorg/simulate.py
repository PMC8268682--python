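"""Synthetic genomes with planted satDNA units and a ground-truth manifest.

The generator emulates the repeat landscape the pipeline is built for:
Helitron-like elements whose central region is a short tandem array of
satDNA monomers. A *full* element reads

    start box .. spacer .. microsatellite .. [internal box] .. monomers .. spacer .. end box

a *truncated* element lacks the box on one side (one-sided truncation being
a frequent fate of these elements), and a *standalone* unit is a bare array
with no boxes at all. Units are planted on random background on either
strand, at least 2 kb apart so that the 2 kb flank excisions of neighbouring
units can never overlap and the manifest stays an exact oracle. Monomer
copies are mutated independently (substitutions plus short indels) and the
realized identity of every copy to its consensus is recorded, so that
detection misses can be traced to copies that genuinely fell below the
annotation threshold.

All randomness flows from one integer seed through a single generator;
outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import segment_identity
from .annotate import MonomerHit
from .boxes import (BOTH_BOXES, NO_BOXES, ONE_BOX, BoxDefinition, BoxLibrary,
                    OrganizationalCall)
from .seqio import GenomeSequence, SatDNAFamily, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FORM_FULL = "full"
FORM_TRUNCATED_LEFT = "truncated_left"
FORM_TRUNCATED_RIGHT = "truncated_right"
FORM_STANDALONE = "standalone"

EXPECTED_CATEGORY = {
    FORM_FULL: BOTH_BOXES,
    FORM_TRUNCATED_LEFT: ONE_BOX,
    FORM_TRUNCATED_RIGHT: ONE_BOX,
    FORM_STANDALONE: NO_BOXES,
}

# box lengths as found among the related Helitrons: 44/49 bp terminal and a
# 156 bp internal box for group A, 53/42 bp terminal for group B
BOX_BLUEPRINT = [
    ("Box1", 44, "start", "groupA"),
    ("Box2", 49, "end", "groupA"),
    ("Box3", 156, "internal", "groupA"),
    ("Box4", 53, "start", "groupB"),
    ("Box5", 42, "end", "groupB"),
]


@dataclass
class FamilySim:
    """Simulation spec for one satDNA family."""

    family_id: str
    monomer_length: int
    box_group: str                  # none | groupA | groupB
    n_full: int = 0
    n_truncated: int = 0
    n_standalone: int = 0
    mean_monomers: float = 2.0      # geometric mean of monomers per array
    max_monomers: int = 12
    consensus: str | None = None    # generated from seed when None

    def __post_init__(self) -> None:
        if self.box_group == "none" and (self.n_full or self.n_truncated):
            raise ValueError(
                f"{self.family_id}: element-associated units need a box group"
            )
        if any(n < 0 for n in (self.n_full, self.n_truncated,
                               self.n_standalone)):
            raise ValueError(f"{self.family_id}: negative unit count")


def default_families() -> list[FamilySim]:
    """Default family panel sampling the observed monomer-length range
    (very short, nucleosome-sized, mid-length and multi-kb monomers)."""
    return [
        FamilySim("SynSat21", 21, "none", 0, 0, 16),
        FamilySim("SynSat166", 166, "groupA", 14, 8, 12),
        FamilySim("SynSat437", 437, "groupB", 14, 8, 12),
        FamilySim("SynSat2056", 2056, "groupB", 8, 4, 8,
                  mean_monomers=1.5, max_monomers=3),
    ]


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 300_000
    gc: float = 0.5
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0
    min_spacing: int = 2_000
    microsat_repeat: str = "AC"
    microsat_n: int = 10
    families: list[FamilySim] = field(default_factory=default_families)

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= rate <= 0.5):
                raise ValueError(f"rate out of [0, 0.5]: {rate}")
        if not (0.0 < self.gc < 1.0):
            raise ValueError(f"gc out of (0, 1): {self.gc}")
        self.families = [
            FamilySim(**f) if isinstance(f, dict) else f
            for f in self.families
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class PlantedCopy:
    """One planted monomer copy (genome coordinates, realized identity)."""

    start: int
    end: int
    identity: float


@dataclass(frozen=True)
class PlantedUnit:
    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    form: str
    monomer_count: int
    array_start: int
    array_end: int
    box_group: str
    copies: tuple[PlantedCopy, ...]

    @property
    def expected_category(self) -> str:
        return EXPECTED_CATEGORY[self.form]

    @property
    def classifiable(self) -> bool:
        return self.box_group != "none"


@dataclass
class SyntheticManifest:
    units: list[PlantedUnit]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: getattr(u, k)
             for k in ("family_id", "seq_id", "start", "end", "strand",
                       "form", "monomer_count", "array_start", "array_end",
                       "box_group")}
            for u in self.units
        ]
        return pd.DataFrame(rows)

    def copies_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.units):
            for c in u.copies:
                rows.append({"unit": i, "family_id": u.family_id,
                             "seq_id": u.seq_id, "start": c.start,
                             "end": c.end, "identity": round(c.identity, 4)})
        return pd.DataFrame(rows)

    def write(self, units_path, copies_path) -> None:
        self.to_frame().to_csv(units_path, sep="\t", index=False)
        self.copies_frame().to_csv(copies_path, sep="\t", index=False)


@dataclass
class SimulationResult:
    genomes: list[GenomeSequence]
    families: list[SatDNAFamily]
    box_library: BoxLibrary
    manifest: SyntheticManifest


# ---------------------------------------------------------------------------
# sequence generation


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


def mutate_sequence(sequence: str, substitution_rate: float,
                    indel_rate: float, rng: np.random.Generator) -> str:
    """Mutate a sequence: independent per-position substitutions, plus
    insertions/deletions of length 1-3 at per-position probability."""
    if not (0.0 <= substitution_rate <= 1.0 and 0.0 <= indel_rate <= 1.0):
        raise ValueError("rates must be probabilities")
    out: list[str] = []
    i = 0
    n = len(sequence)
    while i < n:
        if indel_rate and rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append(rng.choice(_BASES, size=length).tobytes()
                       .decode("ascii"))
        base = sequence[i]
        if substitution_rate and rng.random() < substitution_rate:
            others = [b for b in "ACGT" if b != base]
            base = others[int(rng.integers(0, 3))]
        out.append(base)
        i += 1
    return "".join(out)


def _build_unit(family: FamilySim, consensus: str, form: str,
                monomer_count: int, boxes: dict[str, BoxDefinition],
                config: SimulationConfig, rng: np.random.Generator,
                ) -> tuple[str, int, int, list[tuple[int, int, float]]]:
    """Assemble one planted unit on the plus strand.

    Returns (sequence, array_start, array_end, copies) with coordinates and
    copies relative to the unit start.
    """
    parts: list[str] = []
    pos = 0

    def push(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    group = family.box_group
    has_left = form in (FORM_FULL, FORM_TRUNCATED_RIGHT)
    has_right = form in (FORM_FULL, FORM_TRUNCATED_LEFT)
    if form != FORM_STANDALONE:
        if has_left:
            push(boxes[f"{group}:start"].sequence)
            push(_random_seq(rng, 40, config.gc))
        push(config.microsat_repeat * config.microsat_n)
        internal = boxes.get(f"{group}:internal")
        if internal is not None:
            push(internal.sequence)
    array_start = pos
    copies: list[tuple[int, int, float]] = []
    for _ in range(monomer_count):
        copy = mutate_sequence(consensus, config.substitution_rate,
                               config.indel_rate, rng)
        identity = (1.0 if copy == consensus
                    else segment_identity(consensus, copy))
        copies.append((pos, pos + len(copy), identity))
        push(copy)
    array_end = pos
    if form != FORM_STANDALONE and has_right:
        push(_random_seq(rng, 40, config.gc))
        push(boxes[f"{group}:end"].sequence)
    return "".join(parts), array_start, array_end, copies


def simulate_genome(config: SimulationConfig) -> SimulationResult:
    """Generate the genome, consensus set, box library and manifest."""
    rng = np.random.default_rng(config.seed)

    box_defs: dict[str, BoxDefinition] = {}
    boxes: list[BoxDefinition] = []
    for box_id, length, side, group in BOX_BLUEPRINT:
        box = BoxDefinition(box_id, _random_seq(rng, length, config.gc),
                            side, group)
        boxes.append(box)
        box_defs[f"{group}:{side}"] = box

    families: list[SatDNAFamily] = []
    consensi: dict[str, str] = {}
    for fam in config.families:
        consensus = fam.consensus or _random_seq(rng, fam.monomer_length,
                                                 config.gc)
        consensi[fam.family_id] = consensus
        families.append(SatDNAFamily(fam.family_id, fam.family_id, consensus,
                                     repbase_class="DNA/Helitron"
                                     if fam.box_group != "none" else "",
                                     box_group=fam.box_group))
    box_library = BoxLibrary(
        boxes, {f.family_id: f.box_group for f in config.families})

    # blueprints: (family, form, monomer_count, strand)
    blueprints: list[tuple[FamilySim, str, int, str]] = []
    for fam in config.families:
        forms = ([FORM_FULL] * fam.n_full
                 + [FORM_TRUNCATED_LEFT] * (fam.n_truncated // 2)
                 + [FORM_TRUNCATED_RIGHT]
                 * (fam.n_truncated - fam.n_truncated // 2)
                 + [FORM_STANDALONE] * fam.n_standalone)
        for form in forms:
            count = min(int(rng.geometric(1.0 / fam.mean_monomers)),
                        fam.max_monomers)
            strand = "+" if rng.random() < 0.5 else "-"
            blueprints.append((fam, form, count, strand))
    order = rng.permutation(len(blueprints))
    blueprints = [blueprints[i] for i in order]

    # spacing must exceed the flank length (so excisions never reach a
    # neighbouring unit) and the array-merge distance of the longest
    # monomer (so two planted units can never fuse into one array)
    spacing = max(config.min_spacing,
                  max(len(c) for c in consensi.values()) + 50)

    # round-robin over chromosomes
    per_chrom: list[list[tuple[FamilySim, str, int, str]]] = [
        [] for _ in range(config.n_chromosomes)
    ]
    for i, bp in enumerate(blueprints):
        per_chrom[i % config.n_chromosomes].append(bp)

    genomes: list[GenomeSequence] = []
    units: list[PlantedUnit] = []
    for ci, chrom_units in enumerate(per_chrom):
        seq_id = f"chr{ci + 1}"
        built = []
        for fam, form, count, strand in chrom_units:
            unit_seq, a_start, a_end, copies = _build_unit(
                fam, consensi[fam.family_id], form, count, box_defs, config,
                rng)
            if strand == "-":
                n = len(unit_seq)
                unit_seq = reverse_complement(unit_seq)
                copies = [(n - e, n - s, ident)
                          for s, e, ident in reversed(copies)]
                a_start, a_end = n - a_end, n - a_start
            built.append((fam, form, count, strand, unit_seq, a_start,
                          a_end, copies))
        total = sum(len(b[4]) for b in built)
        k = len(built)
        slack = (config.chromosome_length - total
                 - (k + 1) * spacing)
        if slack < 0:
            raise ValueError(
                f"{seq_id}: units do not fit "
                f"(need {total + (k + 1) * spacing} bp, "
                f"have {config.chromosome_length})"
            )
        extra = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1))
        background = _random_seq(rng, config.chromosome_length, config.gc)
        pieces: list[str] = []
        cursor = 0
        pos = 0
        for j, (fam, form, count, strand, unit_seq, a_start, a_end,
                copies) in enumerate(built):
            gap = spacing + int(extra[j])
            pieces.append(background[cursor : cursor + gap])
            cursor += gap
            pos += gap
            units.append(PlantedUnit(
                family_id=fam.family_id, seq_id=seq_id, start=pos,
                end=pos + len(unit_seq), strand=strand, form=form,
                monomer_count=count, array_start=pos + a_start,
                array_end=pos + a_end, box_group=fam.box_group,
                copies=tuple(PlantedCopy(pos + s, pos + e, ident)
                             for s, e, ident in copies),
            ))
            pieces.append(unit_seq)
            pos += len(unit_seq)
        tail = config.chromosome_length - pos
        pieces.append(background[cursor : cursor + tail])
        genomes.append(GenomeSequence(seq_id, "".join(pieces)))

    units.sort(key=lambda u: (u.seq_id, u.start))
    return SimulationResult(genomes, families, box_library,
                            SyntheticManifest(units))


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryReport:
    """Pipeline performance against the manifest ground truth."""

    monomer_recall: float
    monomer_precision: float | None   # None when there are no hits
    form_accuracy: float | None       # None when nothing is classifiable
    count_exactness: float | None
    n_copies: int
    n_hits: int
    missed_copies: list[dict]


def _reciprocal_overlap(a_start, a_end, b_start, b_end,
                        threshold: float) -> bool:
    ov = min(a_end, b_end) - max(a_start, b_start)
    return (ov >= threshold * (a_end - a_start)
            and ov >= threshold * (b_end - b_start))


def _parse_extraction_id(extraction_id: str) -> tuple[str, str, int, int]:
    fam, rest = extraction_id.split("|", 1)
    seq_id, coords = rest.rsplit(":", 1)
    span = coords.split("(")[0]
    start, end = span.split("-")
    return fam, seq_id, int(start), int(end)


def evaluate_recovery(
    manifest: SyntheticManifest,
    hits: Sequence[MonomerHit],
    calls: Sequence[OrganizationalCall] | None = None,
    min_reciprocal: float = 0.5,
) -> RecoveryReport:
    """Score annotation and classification against the planted truth.

    A planted monomer copy is recovered when a hit of the same family on the
    same sequence overlaps it reciprocally by >= min_reciprocal; a hit is a
    true positive when it recovers some copy. Form accuracy is judged over
    classifiable units (those of families with a box group): the unit's call
    is the one whose array span reciprocally overlaps the planted array.
    """
    hit_index: dict[tuple[str, str], list[MonomerHit]] = {}
    for h in hits:
        hit_index.setdefault((h.family_id, h.interval.seq_id), []).append(h)

    n_copies = 0
    matched_copies = 0
    matched_hits: set[int] = set()
    missed: list[dict] = []
    for u in manifest.units:
        cands = hit_index.get((u.family_id, u.seq_id), [])
        for c in u.copies:
            n_copies += 1
            found = False
            for h in cands:
                if _reciprocal_overlap(c.start, c.end, h.interval.start,
                                       h.interval.end, min_reciprocal):
                    found = True
                    matched_hits.add(id(h))
            if found:
                matched_copies += 1
            else:
                missed.append({"family_id": u.family_id, "seq_id": u.seq_id,
                               "start": c.start, "end": c.end,
                               "identity": c.identity})
    n_hits = len(hits)
    recall = matched_copies / n_copies if n_copies else 1.0
    precision = (len(matched_hits) / n_hits) if n_hits else None

    form_accuracy = None
    count_exactness = None
    if calls is not None:
        call_spans = [(c, _parse_extraction_id(c.extraction_id))
                      for c in calls]
        correct = 0
        exact = 0
        matched_units = 0
        classifiable = [u for u in manifest.units if u.classifiable]
        for u in classifiable:
            match = None
            for call, (fam, seq_id, start, end) in call_spans:
                if fam == u.family_id and seq_id == u.seq_id and \
                        _reciprocal_overlap(u.array_start, u.array_end,
                                            start, end, min_reciprocal):
                    match = call
                    break
            if match is not None:
                matched_units += 1
                if match.box_category == u.expected_category:
                    correct += 1
                if match.monomer_count == u.monomer_count:
                    exact += 1
        if classifiable:
            form_accuracy = correct / len(classifiable)
            count_exactness = (exact / matched_units if matched_units
                               else None)
    return RecoveryReport(recall, precision, form_accuracy, count_exactness,
                          n_copies, n_hits, missed)
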