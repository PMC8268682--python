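"""Genome-wide annotation of satDNA monomer copies.

Each consensus monomer is searched on both strands of every assembly
sequence at a configurable identity floor (default 0.70, i.e. tolerating up
to 30% divergence so diverged sequence variants are still captured).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .alignment import semiglobal_search
from .seqio import GenomeSequence, GenomicInterval, SatDNAFamily, reverse_complement

MIN_CONSENSUS_LENGTH = 10
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_COVERAGE = 0.50
DEFAULT_COMPLETENESS = 0.90
DEFAULT_OVERLAP_TOLERANCE = 0.20


@dataclass(frozen=True)
class MonomerHit:
    """One aligned genomic copy (or fragment) of a satDNA monomer."""

    family_id: str
    variant_id: str
    interval: GenomicInterval
    identity: float
    consensus_coverage: float
    complete: bool = False


def mark_completeness(hit: MonomerHit,
                      completeness_threshold: float = DEFAULT_COMPLETENESS,
                      ) -> MonomerHit:
    """Annotate whether the hit covers enough of the consensus to count as a
    complete monomer (as opposed to a fragment at an array edge)."""
    return replace(hit, complete=hit.consensus_coverage >= completeness_threshold)


def resolve_overlaps(hits: Sequence[MonomerHit], monomer_length: int,
                     overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
                     ) -> list[MonomerHit]:
    """Greedy overlap resolution among hits of one family on one sequence.

    Winners are chosen by descending identity, then leftmost start, then
    longest span; a remaining hit is dropped when it overlaps any winner by
    more than ``overlap_tolerance`` x monomer_length.
    """
    limit = overlap_tolerance * monomer_length
    order = sorted(
        hits,
        key=lambda h: (-h.identity, h.interval.start, -len(h.interval)),
    )
    winners: list[MonomerHit] = []
    for cand in order:
        if all(cand.interval.overlap(w.interval) <= limit for w in winners):
            winners.append(cand)
    winners.sort(key=lambda h: (h.interval.seq_id, h.interval.start,
                                h.interval.end))
    return winners


def annotate_monomers(
    genome: GenomeSequence,
    family: SatDNAFamily,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    completeness_threshold: float = DEFAULT_COMPLETENESS,
    resolve: bool = True,
) -> list[MonomerHit]:
    """All copies of one consensus variant on both strands of one sequence.

    Returns hits sorted by start position. ``resolve=False`` skips the
    greedy overlap resolution (used when several variants of one family are
    annotated together and resolved jointly afterwards).
    """
    if family.monomer_length < MIN_CONSENSUS_LENGTH:
        raise ValueError(
            f"consensus {family.variant_id} shorter than "
            f"{MIN_CONSENSUS_LENGTH} bp"
        )
    if not (0.0 < min_identity <= 1.0):
        raise ValueError(f"min_identity out of (0, 1]: {min_identity}")

    hits: list[MonomerHit] = []
    for strand, query in (
        ("+", family.consensus),
        ("-", reverse_complement(family.consensus)),
    ):
        for raw in semiglobal_search(query, genome.sequence, min_identity,
                                     min_coverage):
            hit = MonomerHit(
                family_id=family.family_id,
                variant_id=family.variant_id,
                interval=GenomicInterval(genome.id, raw.start, raw.end, strand),
                identity=raw.identity,
                consensus_coverage=raw.query_coverage,
            )
            hits.append(mark_completeness(hit, completeness_threshold))
    if resolve:
        hits = resolve_overlaps(hits, family.monomer_length)
    else:
        hits.sort(key=lambda h: (h.interval.start, h.interval.end))
    return hits


def annotate_family(
    genomes: Iterable[GenomeSequence],
    variants: Sequence[SatDNAFamily],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    completeness_threshold: float = DEFAULT_COMPLETENESS,
) -> list[MonomerHit]:
    """Annotate all variants of one family over an assembly.

    Variants are searched independently; overlapping hits of the same family
    (e.g. a locus matched by both CgiSat01a and CgiSat01b) are resolved
    jointly so each genomic copy is counted once. Hits are sorted by
    (seq_id, start).
    """
    fam_ids = {v.family_id for v in variants}
    if len(fam_ids) != 1:
        raise ValueError(f"variants span several families: {sorted(fam_ids)}")
    ref_length = int(pd.Series([v.monomer_length for v in variants]).median())
    out: list[MonomerHit] = []
    for genome in genomes:
        per_seq: list[MonomerHit] = []
        for variant in variants:
            per_seq.extend(
                annotate_monomers(genome, variant, min_identity, min_coverage,
                                  completeness_threshold, resolve=False)
            )
        out.extend(resolve_overlaps(per_seq, ref_length))
    out.sort(key=lambda h: (h.interval.seq_id, h.interval.start,
                            h.interval.end))
    return out


def hits_to_frame(hits: Iterable[MonomerHit]) -> pd.DataFrame:
    """Tabular view of hits (one row per monomer copy)."""
    rows = [
        {
            "family_id": h.family_id,
            "variant_id": h.variant_id,
            "seq_id": h.interval.seq_id,
            "start": h.interval.start,
            "end": h.interval.end,
            "strand": h.interval.strand,
            "identity": round(h.identity, 4),
            "coverage": round(h.consensus_coverage, 4),
            "complete": h.complete,
        }
        for h in hits
    ]
    columns = ["family_id", "variant_id", "seq_id", "start", "end", "strand",
               "identity", "coverage", "complete"]
    return pd.DataFrame(rows, columns=columns)


def frame_to_hits(df: pd.DataFrame) -> list[MonomerHit]:
    """Inverse of :func:`hits_to_frame` (used to chain CLI stages)."""
    return [
        MonomerHit(
            family_id=row.family_id,
            variant_id=row.variant_id,
            interval=GenomicInterval(row.seq_id, int(row.start),
                                     int(row.end), row.strand),
            identity=float(row.identity),
            consensus_coverage=float(row.coverage),
            complete=bool(row.complete),
        )
        for row in df.itertuples()
    ]
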