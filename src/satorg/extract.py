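"""Excision of arrays/single monomers together with their flanking regions.

Each retained array is cut out with up to 2000 bp of genomic sequence on
each side. Minus-strand extractions are normalized to consensus orientation
(whole excision reverse-complemented, flanks swapped) before box search so
"left"/"right" always refer to the element's own orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .arrays import SatArray
from .seqio import GenomeSequence, GenomicInterval, reverse_complement

DEFAULT_FLANK_LENGTH = 2000


@dataclass(frozen=True)
class Extraction:
    """An array plus its left/right flanks, ready for box annotation."""

    array: SatArray
    left_flank: str
    right_flank: str
    array_seq: str
    left_truncated: bool
    right_truncated: bool
    source_positions: GenomicInterval
    oriented: bool = False

    @property
    def extraction_id(self) -> str:
        sp = self.array.span
        return (f"{self.array.family_id}|{self.array.seq_id}"
                f":{sp.start}-{sp.end}({self.array.strand})")

    @property
    def monomer_count(self) -> int:
        return self.array.monomer_count


def extract_with_flanks(array: SatArray, genome: GenomeSequence,
                        flank_length: int = DEFAULT_FLANK_LENGTH) -> Extraction:
    """Excise the array with up to ``flank_length`` bp on each side.

    Flanks are clipped at sequence ends; the truncation flags record when a
    flank is shorter than requested for that reason.
    """
    if flank_length <= 0:
        raise ValueError(f"flank_length must be positive, got {flank_length}")
    span = array.span
    if array.seq_id != genome.id or span.end > len(genome):
        raise ValueError(f"array span {span} outside genome {genome.id}")
    left_start = max(0, span.start - flank_length)
    right_end = min(len(genome), span.end + flank_length)
    return Extraction(
        array=array,
        left_flank=genome.sequence[left_start : span.start],
        right_flank=genome.sequence[span.end : right_end],
        array_seq=genome.sequence[span.start : span.end],
        left_truncated=span.start - left_start < flank_length,
        right_truncated=right_end - span.end < flank_length,
        source_positions=GenomicInterval(genome.id, left_start, right_end,
                                         array.strand),
    )


def orient_extraction(extraction: Extraction) -> Extraction:
    """Normalize a minus-strand excision to consensus orientation.

    Reverse-complements the whole excision and swaps the flanks (and their
    truncation flags) so the monomers read in consensus orientation.
    Idempotent; plus-strand extractions only gain the oriented flag.
    """
    if extraction.oriented or extraction.array.strand == "+":
        return replace(extraction, oriented=True)
    return replace(
        extraction,
        left_flank=reverse_complement(extraction.right_flank) if extraction.right_flank else "",
        right_flank=reverse_complement(extraction.left_flank) if extraction.left_flank else "",
        array_seq=reverse_complement(extraction.array_seq),
        left_truncated=extraction.right_truncated,
        right_truncated=extraction.left_truncated,
        oriented=True,
    )


def extractions_to_fasta(extractions: Iterable[Extraction], path) -> None:
    """Multi-FASTA of excisions; the header encodes family, position, strand
    and monomer count."""
    with open(path, "w") as fh:
        for ex in extractions:
            fh.write(
                f">{ex.extraction_id} monomers={ex.monomer_count} "
                f"oriented={ex.oriented}\n"
            )
            seq = ex.left_flank + ex.array_seq + ex.right_flank
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def extractions_to_frame(extractions: Iterable[Extraction]) -> pd.DataFrame:
    """Index table mirroring the excision FASTA (positions of the array and
    of its flanks on the source sequence)."""
    rows = []
    for ex in extractions:
        sp = ex.array.span
        rows.append(
            {
                "extraction_id": ex.extraction_id,
                "family_id": ex.array.family_id,
                "seq_id": ex.array.seq_id,
                "array_start": sp.start,
                "array_end": sp.end,
                "strand": ex.array.strand,
                "monomer_count": ex.monomer_count,
                "excision_start": ex.source_positions.start,
                "excision_end": ex.source_positions.end,
                "left_flank_len": len(ex.left_flank),
                "right_flank_len": len(ex.right_flank),
                "left_truncated": ex.left_truncated,
                "right_truncated": ex.right_truncated,
            }
        )
    columns = ["extraction_id", "family_id", "seq_id", "array_start",
               "array_end", "strand", "monomer_count", "excision_start",
               "excision_end", "left_flank_len", "right_flank_len",
               "left_truncated", "right_truncated"]
    return pd.DataFrame(rows, columns=columns)
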