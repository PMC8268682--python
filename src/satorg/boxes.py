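"""Detection of conserved Helitron boxes in extraction flanks and
classification of each extraction's organizational form.

Related Helitrons share short conserved segments: group A elements carry a
44 bp box at the element start (Box1), a 49 bp box at the end (Box2) and a
156 bp internal box (Box3); group B elements carry a 53 bp start box (Box4)
and a 42 bp end box (Box5). Terminal boxes designate the element ends, so
their presence in the flanks of a satDNA array diagnoses mobile-element
association: boxes on both sides -> intact element; a box on one side ->
truncated element (still element-associated); no boxes -> standalone repeat.
Internal boxes are reported but never used for classification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import semiglobal_search
from .extract import Extraction
from .seqio import read_consensus_fasta, reverse_complement

DEFAULT_BOX_MIN_IDENTITY = 0.70
DEFAULT_BOX_MIN_COVERAGE = 0.80

BOTH_BOXES = "both_boxes"
ONE_BOX = "one_box"
NO_BOXES = "no_boxes"
ELEMENT_ASSOCIATED = "element_associated"
STANDALONE = "standalone"


@dataclass(frozen=True)
class BoxDefinition:
    """One conserved Helitron box."""

    box_id: str
    sequence: str
    element_side: str  # start | end | internal
    group: str         # groupA | groupB

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"box {self.box_id} has empty sequence")
        if self.element_side not in ("start", "end", "internal"):
            raise ValueError(f"box {self.box_id}: bad side {self.element_side}")

    @property
    def terminal(self) -> bool:
        return self.element_side in ("start", "end")


@dataclass(frozen=True)
class BoxHit:
    """One box match within an extraction flank."""

    box_id: str
    flank: str      # left | right
    offset: int     # start within the flank
    end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class OrganizationalCall:
    """Box-based classification of one extraction."""

    extraction_id: str
    family_id: str
    monomer_count: int
    box_category: str  # both_boxes | one_box | no_boxes
    form: str          # element_associated | standalone
    boxes: tuple[BoxHit, ...] = ()


@dataclass
class BoxLibrary:
    """Boxes plus the family -> box group map."""

    boxes: list[BoxDefinition]
    family_groups: Mapping[str, str]  # family_id -> groupA | groupB | none

    def group_boxes(self, group: str, terminal_only: bool = False,
                    ) -> list[BoxDefinition]:
        out = [b for b in self.boxes if b.group == group]
        if terminal_only:
            out = [b for b in out if b.terminal]
        return out

    def group_for(self, family_id: str) -> str:
        return self.family_groups.get(family_id, "none")


def load_box_library(fasta_path, config_path) -> BoxLibrary:
    """Read a box library: FASTA of box sequences plus a TSV config.

    The config has rows ``box<TAB>box_id<TAB>element_side<TAB>group`` for
    each box and ``family<TAB>family_id<TAB>group`` rows mapping satDNA
    families to the box group of their related Helitrons.
    """
    seqs = {f.variant_id: f.consensus for f in read_consensus_fasta(fasta_path)}
    boxes: list[BoxDefinition] = []
    family_groups: dict[str, str] = {}
    with open(config_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            kind = row[0]
            if kind == "box":
                _, box_id, side, group = row[:4]
                if box_id not in seqs:
                    raise ValueError(f"box {box_id} missing from FASTA")
                boxes.append(BoxDefinition(box_id, seqs[box_id], side, group))
            elif kind == "family":
                _, family_id, group = row[:3]
                family_groups[family_id] = group
            else:
                raise ValueError(f"unknown config row kind {kind!r}")
    return BoxLibrary(boxes, family_groups)


def annotate_boxes(
    extraction: Extraction,
    box_library: BoxLibrary | Sequence[BoxDefinition],
    min_identity: float = DEFAULT_BOX_MIN_IDENTITY,
    min_coverage: float = DEFAULT_BOX_MIN_COVERAGE,
    include_internal: bool = True,
) -> list[BoxHit]:
    """Search the family's boxes in both flanks, both strands.

    The extraction must be oriented first. The search never touches the
    array itself, so box hits cannot overlap the array span.
    """
    if not extraction.oriented:
        raise ValueError("orient the extraction before box annotation")
    if isinstance(box_library, BoxLibrary):
        group = box_library.group_for(extraction.array.family_id)
        boxes = box_library.group_boxes(group,
                                        terminal_only=not include_internal)
        if group != "none" and not boxes:
            raise ValueError(
                f"family {extraction.array.family_id} maps to {group} "
                "but the library holds no such boxes"
            )
    else:
        boxes = list(box_library)

    hits: list[BoxHit] = []
    for side, flank in (("left", extraction.left_flank),
                        ("right", extraction.right_flank)):
        if not flank:
            continue
        for box in boxes:
            for strand, query in (("+", box.sequence),
                                  ("-", reverse_complement(box.sequence))):
                if len(flank) < 1:
                    continue
                for raw in semiglobal_search(query, flank, min_identity,
                                             min_coverage):
                    hits.append(BoxHit(box.box_id, side, raw.start, raw.end,
                                       strand, raw.identity))
    hits.sort(key=lambda h: (h.flank, h.offset, h.box_id))
    return hits


def classify_extraction(extraction: Extraction,
                        box_hits: Sequence[BoxHit],
                        terminal_box_ids: set[str] | None = None,
                        ) -> OrganizationalCall:
    """Classify by which flanks carry terminal boxes.

    Both flanks hit -> both_boxes; exactly one -> one_box (still element-
    associated, one-sided truncation being frequent); neither -> standalone.
    ``terminal_box_ids`` restricts which hits count (internal boxes never
    do); None counts every hit.
    """
    counted = [
        h for h in box_hits
        if terminal_box_ids is None or h.box_id in terminal_box_ids
    ]
    sides = {h.flank for h in counted}
    if {"left", "right"} <= sides:
        category = BOTH_BOXES
    elif sides:
        category = ONE_BOX
    else:
        category = NO_BOXES
    form = STANDALONE if category == NO_BOXES else ELEMENT_ASSOCIATED
    return OrganizationalCall(
        extraction_id=extraction.extraction_id,
        family_id=extraction.array.family_id,
        monomer_count=extraction.monomer_count,
        box_category=category,
        form=form,
        boxes=tuple(box_hits),
    )


def classify_family(
    extractions: Sequence[Extraction],
    box_library: BoxLibrary,
    min_identity: float = DEFAULT_BOX_MIN_IDENTITY,
    min_coverage: float = DEFAULT_BOX_MIN_COVERAGE,
) -> list[OrganizationalCall]:
    """Annotate boxes and classify every extraction of one family."""
    calls = []
    for ex in extractions:
        group = box_library.group_for(ex.array.family_id)
        terminal = {b.box_id for b in box_library.group_boxes(group, True)}
        hits = annotate_boxes(ex, box_library, min_identity, min_coverage)
        calls.append(classify_extraction(ex, hits, terminal))
    return calls


def box_matrix(calls: Sequence[OrganizationalCall],
               box_ids: Sequence[str]) -> pd.DataFrame:
    """0/1 presence matrix, one row per extraction, one column per box."""
    rows = []
    for call in calls:
        present = {h.box_id for h in call.boxes}
        rows.append({"extraction_id": call.extraction_id,
                     **{b: int(b in present) for b in box_ids}})
    return pd.DataFrame(rows, columns=["extraction_id", *box_ids])


def calls_to_frame(calls: Iterable[OrganizationalCall]) -> pd.DataFrame:
    rows = [
        {
            "extraction_id": c.extraction_id,
            "family_id": c.family_id,
            "monomer_count": c.monomer_count,
            "box_category": c.box_category,
            "form": c.form,
            "n_box_hits": len(c.boxes),
        }
        for c in calls
    ]
    columns = ["extraction_id", "family_id", "monomer_count", "box_category",
               "form", "n_box_hits"]
    return pd.DataFrame(rows, columns=columns)
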