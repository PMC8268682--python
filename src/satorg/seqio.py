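"""Sequence containers and FASTA/BED/GFF3 input/output.

Coordinates are 0-based half-open throughout the package (BED convention);
GFF3 output converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = set("ACGTN")
STRICT_ALPHABET = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA record violates the expected alphabet or structure."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeSequence:
    """One assembly sequence (chromosome / linkage group / scaffold)."""

    id: str
    sequence: str
    category: str = "chromosome"  # chromosome | scaffold

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.sequence) == 0:
            raise ValueError(f"sequence {self.id} is empty")
        if self.category not in ("chromosome", "scaffold"):
            raise ValueError(f"invalid category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SatDNAFamily:
    """A satDNA consensus monomer, possibly one of several subfamily variants.

    ``family_id`` groups variants (e.g. CgiSat01a/CgiSat01b both belong to
    CgiSat01); family-level statistics count each family once.
    ``box_group`` names the Helitron box set used for flank classification
    ("none" for families whose related elements have no determinable boxes).
    """

    family_id: str
    variant_id: str
    consensus: str
    repbase_class: str = ""
    box_group: str = "none"  # none | groupA | groupB

    def __post_init__(self) -> None:
        if not set(self.consensus) <= STRICT_ALPHABET:
            bad = sorted(set(self.consensus) - STRICT_ALPHABET)
            raise FastaParseError(
                f"consensus {self.variant_id}: non-ACGT residue(s) {bad}"
            )

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, category: str = "chromosome",
               alphabet: set = GENOME_ALPHABET) -> list[GenomeSequence]:
    """Read a (optionally gzipped) FASTA file into GenomeSequence records.

    Sequences are uppercased; record order is preserved; the id is the header
    token up to the first whitespace. Residues outside ``alphabet`` raise
    :class:`FastaParseError` naming the offending record.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            extra = set(seq) - alphabet
            if extra:
                raise FastaParseError(
                    f"record {rec.id}: non-IUPAC residue(s) {sorted(extra)}"
                )
            if rec.id in seen:
                raise FastaParseError(f"duplicate sequence id {rec.id}")
            seen.add(rec.id)
            records.append(GenomeSequence(rec.id, seq, category=category))
    return records


def read_consensus_fasta(path) -> list[SatDNAFamily]:
    """Read satDNA consensus monomers.

    Headers are either ``familyId|variantId`` or a bare id (variant == family).
    N bases are not allowed in consensus sequences.
    """
    families: list[SatDNAFamily] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if "|" in rec.id:
                fam, var = rec.id.split("|", 1)
            else:
                fam = var = rec.id
            families.append(SatDNAFamily(fam, var, str(rec.seq).upper()))
    return families


def write_fasta(records: Iterable, path) -> None:
    """Write (id, sequence) pairs or GenomeSequence records as FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, GenomeSequence):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def at_content(sequence: str) -> float:
    """Fraction of A+T bases; N counts in the denominator."""
    if not sequence:
        raise ValueError("at_content of empty sequence")
    s = sequence.upper()
    return (s.count("A") + s.count("T")) / len(s)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; other bases raise ValueError."""
    s = sequence.upper()
    if not set(s) <= GENOME_ALPHABET:
        bad = sorted(set(s) - GENOME_ALPHABET)
        raise ValueError(f"cannot complement residue(s) {bad}")
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation output


def write_annotations(hits, path, fmt: str = "BED") -> None:
    """Write interval annotations as BED6 or GFF3.

    ``hits`` carry .interval (GenomicInterval), .variant_id and .identity.
    BED score = round(identity * 1000); GFF3 is 1-based inclusive.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unsupported format {fmt}")
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
        for h in hits:
            iv = h.interval
            score = round(h.identity * 1000)
            if fmt == "BED":
                fh.write(
                    f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{h.variant_id}"
                    f"\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(
                    f"{iv.seq_id}\tsatorg\tsatellite_DNA\t{iv.start + 1}"
                    f"\t{iv.end}\t{h.identity:.3f}\t{iv.strand}\t."
                    f"\tName={h.variant_id}\n"
                )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED6 (or BED3) intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 else "+"
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       strand))
    return out
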