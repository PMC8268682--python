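"""Shared fixtures and the independent brute-force annotation oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from satorg.seqio import GenomeSequence, SatDNAFamily, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode("ascii")


def substitute(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute an exact fraction of positions (distinct bases)."""
    n = len(seq)
    k = round(n * fraction)
    sites = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20210624)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive per-offset semi-global scan


def _oracle_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    try:
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
    return aligner


def brute_force_scan(query: str, target: str, min_identity: float,
                     ) -> list[tuple[int, int, float]]:
    """All maximal semi-global matches of query in target, by exhaustion.

    For every start offset the query is aligned against a window long
    enough to hold any qualifying alignment; per-offset results are then
    reduced to local maxima (greedy by identity, discarding near-duplicate
    placements). Only for tiny targets.
    """
    aligner = _oracle_aligner()
    m = len(query)
    slack = int(m * (1.0 - min_identity) / min_identity) + 1
    candidates = []
    for start in range(len(target)):
        window = target[start : start + m + slack]
        if len(window) < max(4, m // 2):
            break
        aln = aligner.align(window, query)[0]
        wrow, qrow = str(aln[0]), str(aln[1])
        # leading window overhang shifts the true start; a candidate is
        # only "anchored at start" when its alignment begins immediately
        lead = 0
        i = 0
        while i < len(wrow) and qrow[i] == "-":
            lead += 1
            i += 1
        if lead:
            continue
        matches = columns = consumed = 0
        j = len(wrow) - 1
        tail = 0
        while j >= 0 and qrow[j] == "-":
            tail += 1
            j -= 1
        for idx in range(0, j + 1):
            columns += 1
            if wrow[idx] != "-":
                consumed += 1
            if wrow[idx] == qrow[idx]:
                matches += 1
        if columns and matches / columns >= min_identity:
            candidates.append((start, start + consumed, matches / columns))
    # reduce to non-overlapping local maxima
    chosen: list[tuple[int, int, float]] = []
    for cand in sorted(candidates, key=lambda c: (-c[2], c[0])):
        if all(min(cand[1], c[1]) - max(cand[0], c[0]) <= 0.2 * m
               for c in chosen):
            chosen.append(cand)
    chosen.sort()
    return chosen


def brute_force_both_strands(query: str, target: str, min_identity: float):
    """Oracle hits on both strands as (start, end, strand, identity)."""
    fwd = [(s, e, "+", i)
           for s, e, i in brute_force_scan(query, target, min_identity)]
    rev = [(s, e, "-", i)
           for s, e, i in brute_force_scan(reverse_complement(query), target,
                                           min_identity)]
    return sorted(fwd + rev)


@pytest.fixture
def toy_genome(rng):
    """3 kb genome with two exact copies and one reverse-complement copy of
    an 80 bp consensus, all well separated."""
    consensus = random_seq(rng, 80)
    background = random_seq(rng, 3000)
    seq = (background[:500] + consensus + background[500:1500] + consensus
           + background[1500:2200] + reverse_complement(consensus)
           + background[2200:])
    genome = GenomeSequence("toy", seq)
    family = SatDNAFamily("SatX", "SatX", consensus)
    positions = [(500, 580, "+"), (1580, 1660, "+"), (2360, 2440, "-")]
    return genome, family, positions
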