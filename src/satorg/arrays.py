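"""Grouping monomer hits into tandem arrays.

An array is a run of same-strand copies of one family on one assembly
sequence whose neighbours lie within a configurable gap (default one monomer
length); a single isolated monomer is a 1-copy array. The array (or single
monomer) is the unit whose flanks are later excised and classified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .annotate import MonomerHit
from .seqio import GenomeSequence, GenomicInterval

DEFAULT_MAX_GAP_FACTOR = 1.0
DEFAULT_MIN_N_RUN = 10


@dataclass(frozen=True)
class SatArray:
    """A tandem array (>= 1 monomer) of one satDNA family."""

    family_id: str
    seq_id: str
    hits: tuple[MonomerHit, ...]
    strand: str
    contains_assembly_gap: bool = False

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.hits[0].interval.start,
                               self.hits[-1].interval.end, self.strand)

    @property
    def monomer_count(self) -> int:
        return len(self.hits)

    @property
    def has_complete_monomer(self) -> bool:
        return any(h.complete for h in self.hits)


def build_arrays(
    hits: Sequence[MonomerHit],
    monomer_length: int,
    max_gap_factor: float = DEFAULT_MAX_GAP_FACTOR,
) -> list[SatArray]:
    """Merge consecutive same-strand hits into arrays.

    Adjacent hits on the same sequence and strand join one array when the
    gap between them is <= max_gap_factor * monomer_length. Every hit
    belongs to exactly one array; arrays are sorted by position.
    """
    families = {h.family_id for h in hits}
    if len(families) > 1:
        raise ValueError(f"hits span several families: {sorted(families)}")
    if not hits:
        return []
    family_id = next(iter(families))
    max_gap = max_gap_factor * monomer_length

    arrays: list[SatArray] = []
    by_pos = sorted(hits, key=lambda h: (h.interval.seq_id, h.interval.start,
                                         h.interval.end))
    run: list[MonomerHit] = []

    def flush() -> None:
        if run:
            arrays.append(SatArray(family_id, run[0].interval.seq_id,
                                   tuple(run), run[0].interval.strand))

    for hit in by_pos:
        if run and (
            hit.interval.seq_id != run[-1].interval.seq_id
            or hit.interval.strand != run[-1].interval.strand
            or hit.interval.start - run[-1].interval.end > max_gap
        ):
            flush()
            run = []
        run.append(hit)
    flush()
    arrays.sort(key=lambda a: (a.seq_id, a.span.start, a.span.end))
    return arrays


def filter_arrays(arrays: Iterable[SatArray],
                  require_complete: bool = True) -> list[SatArray]:
    """Keep arrays holding at least one complete monomer (the inspection
    criterion for flank classification); no-op when require_complete=False."""
    if not require_complete:
        return list(arrays)
    return [a for a in arrays if a.has_complete_monomer]


_N_RUN_CACHE_LIMIT = 8


def flag_assembly_gaps(array: SatArray, genome: GenomeSequence,
                       min_n_run: int = DEFAULT_MIN_N_RUN) -> SatArray:
    """Set contains_assembly_gap when an N-run >= min_n_run lies in the span."""
    span = array.span
    if span.end > len(genome):
        raise ValueError(
            f"array span {span} exceeds {genome.id} length {len(genome)}"
        )
    segment = genome.sequence[span.start : span.end]
    gap = re.search("N" * min_n_run, segment) is not None
    return replace(array, contains_assembly_gap=gap)


def arrays_to_frame(arrays: Iterable[SatArray]) -> pd.DataFrame:
    rows = [
        {
            "family_id": a.family_id,
            "seq_id": a.seq_id,
            "start": a.span.start,
            "end": a.span.end,
            "strand": a.strand,
            "monomer_count": a.monomer_count,
            "has_complete_monomer": a.has_complete_monomer,
            "contains_assembly_gap": a.contains_assembly_gap,
        }
        for a in arrays
    ]
    columns = ["family_id", "seq_id", "start", "end", "strand",
               "monomer_count", "has_complete_monomer",
               "contains_assembly_gap"]
    return pd.DataFrame(rows, columns=columns)
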