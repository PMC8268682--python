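"""Semi-global approximate matching used by monomer and box annotation.

The search finds every infix of the target whose alignment to the full
query reaches the requested identity. Identity is defined as
matches / alignment columns, gaps counting as columns, measured on an
affine-gap alignment (match +1, mismatch -1, gap open -2, gap extend -1):
the affine penalties keep random gap-rich alignments from inflating the
match fraction on biased-composition sequence.

The strategy is exhaustive rather than heuristic, in two stages:

1. *Location*: edlib's bit-parallel semi-global aligner is run with
   edit-distance cap k = floor(m * (1 - t) / t). Any region carrying an
   alignment of identity t over C columns has unit-cost distance
   <= (1 - t) * C <= (1 - t) * m / t = k, so every qualifying region is
   located. All optimal locations are collected, the inspected regions are
   masked, and the scan repeats until nothing at distance <= k remains.
   Masking uses a character outside the DNA alphabet, so inspected regions
   can only accumulate mismatches, never be re-reported.
2. *Verification*: each located window is re-aligned with the affine-gap
   scheme (free end gaps on the window side) and kept if the affine
   alignment reaches the identity and query-coverage floors.

Query positions hanging over a sequence end or a masked neighbour are
trimmed before identity is computed — that is how monomer fragments at
array edges and boxes cut by an excision boundary are scored. Trimming is
only permitted where the window really abuts such a boundary; in the middle
of a target the full query must align, so partial matches cannot sneak over
the identity threshold on a trimmed core.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

MASK_CHAR = "#"

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -2
GAP_EXTEND = -1


@dataclass(frozen=True)
class RawHit:
    """One verified alignment of the query inside the target."""

    start: int          # target coords, half-open
    end: int
    identity: float     # matches / alignment columns
    query_coverage: float  # query columns in the trimmed core / query length
    matches: int
    columns: int


def max_edit_distance(query_length: int, min_identity: float) -> int:
    """Largest unit-cost edit distance compatible with the identity floor."""
    if not (0.0 < min_identity <= 1.0):
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    return int(query_length * (1.0 - min_identity) / min_identity)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps on the window (target) side: semi-global in the query.
    # "deletion" in PairwiseAligner nomenclature = target consumed opposite
    # a query gap, which is exactly a window overhang.
    try:
        aligner.end_deletion_score = 0
    except AttributeError:  # older property name
        aligner.target_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _score_window(query: str, window: str, trim_lead: bool = True,
                  trim_tail: bool = True) -> tuple[int, int, int, int, int]:
    """Affine-gap alignment statistics of query against one window.

    Returns (matches, columns, query_core_columns, lead_target,
    tail_target): counts over the trimmed alignment core plus the number of
    window bases trimmed off each end (free window overhang, or query
    overhang where ``trim_lead``/``trim_tail`` allow it).
    """
    aln = _ALIGNER.align(window, query)[0]
    wrow, qrow = str(aln[0]), str(aln[1])
    cols = list(zip(wrow, qrow))

    # free window overhang (unaligned window bases at the ends)
    lead_target = tail_target = 0
    while cols and cols[0][1] == "-":
        cols.pop(0)
        lead_target += 1
    while cols and cols[-1][1] == "-":
        cols.pop()
        tail_target += 1

    def overhang_cut(columns_in) -> int:
        """Longest terminal segment that is gap-dominated with score <= 0.

        The affine optimum sometimes hides a query overhang as an internal
        gap run by pairing a lucky straggler base at the very window edge,
        so a pure terminal-gap-run rule misses it; scoring the segment and
        requiring gap columns to outnumber aligned ones keeps the rule from
        shaving genuine terminal mismatches off diverged copies.
        """
        score = gaps = aligned = cut = 0
        best_score = 0
        in_gap = False
        for i, (wch, qch) in enumerate(columns_in):
            if wch == "-" or qch == "-":
                score += GAP_EXTEND if in_gap else GAP_OPEN
                in_gap = True
                gaps += 1
            else:
                in_gap = False
                aligned += 1
                score += MATCH_SCORE if wch == qch else MISMATCH_SCORE
            if score < best_score and gaps > aligned:
                best_score = score
                cut = i + 1
        return cut

    if trim_lead and cols:
        cut = overhang_cut(cols)
        lead_target += sum(1 for wch, _ in cols[:cut] if wch != "-")
        cols = cols[cut:]
    if trim_tail and cols:
        cut = overhang_cut(cols[::-1])
        if cut:
            tail_target += sum(1 for wch, _ in cols[-cut:] if wch != "-")
            cols = cols[:-cut]

    matches = sum(w == q for w, q in cols)
    qcols = sum(1 for _, q in cols if q != "-")
    return matches, len(cols), qcols, lead_target, tail_target


def semiglobal_search(
    query: str,
    target: str,
    min_identity: float,
    min_coverage: float = 0.5,
    max_iterations: int = 100_000,
) -> list[RawHit]:
    """All non-overlapping semi-global matches of query in target.

    Matches are returned sorted by start. ``min_coverage`` filters hits
    whose trimmed alignment core spans less than that fraction of the query
    (fragments at sequence or mask boundaries).
    """
    m = len(query)
    if m == 0:
        raise ValueError("empty query")
    k = max_edit_distance(m, min_identity)
    masked = bytearray(target.encode("ascii"))
    mask_byte = ord(MASK_CHAR)
    hits: list[RawHit] = []
    for _ in range(max_iterations):
        res = edlib.align(query, masked.decode("ascii"), mode="HW",
                          task="locations", k=k)
        if res["editDistance"] == -1:
            break
        taken_end = -1
        accepted_any = False
        rejected: list[tuple[int, int]] = []
        # pad the verification window a little: the unit-cost optimum can
        # clip a few bases the affine optimum needs. The pad must stay well
        # below the monomer length, or the free-end alignment would wander
        # onto phase-shifted placements over neighbouring tandem copies
        pad = 4 + m // 50
        for s, e in sorted(set(res["locations"])):
            if s <= taken_end:
                continue
            ws, we = s, e
            while ws > 0 and s - ws < pad and masked[ws - 1] != mask_byte:
                ws -= 1
            while (we < len(masked) - 1 and we - e < pad
                   and masked[we + 1] != mask_byte):
                we += 1
            window = masked[ws : we + 1].decode("ascii")
            trim_lead = ws == 0 or masked[ws - 1] == mask_byte
            trim_tail = we == len(masked) - 1 or masked[we + 1] == mask_byte
            matches, columns, qcols, lead_t, tail_t = _score_window(
                query, window, trim_lead, trim_tail)
            accepted = False
            if columns > 0:
                identity = matches / columns
                coverage = qcols / m
                hs, he = ws + lead_t, we + 1 - tail_t
                if (identity >= min_identity and coverage >= min_coverage
                        and hs < he):
                    hits.append(RawHit(hs, he, identity, coverage,
                                       matches, columns))
                    # mask only the claimed core so neighbouring tandem
                    # copies keep every base they own
                    masked[hs:he] = MASK_CHAR.encode("ascii") * (he - hs)
                    accepted = accepted_any = True
            if not accepted:
                rejected.append((s, e))
            taken_end = max(e, we)
        if not accepted_any:
            # Nothing qualified at this distance level. A rejected location
            # only proves that one placement fails - its bases may still
            # belong to a qualifying alignment in another frame - so rather
            # than retiring the region, mask a single centre base. That
            # inflates the failed placement's edit distance by one per
            # round, letting weaker but genuine placements surface, while
            # costing any overlapped genuine copy at most a few bases.
            progressed = False
            for s, e in rejected:
                mid = (s + e) // 2
                for probe in range(mid, e + 1):
                    if masked[probe] != mask_byte:
                        masked[probe] = mask_byte
                        progressed = True
                        break
            if not progressed:  # pragma: no cover - defensive
                break
    else:  # pragma: no cover - defensive
        raise RuntimeError("semiglobal_search did not converge")
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def segment_identity(query: str, segment: str) -> float:
    """Identity of the affine semi-global alignment of query into segment.

    Exactly the scoring rule the search applies to a located window (free
    end gaps on the segment side, no boundary trimming of the query), so it
    serves as the per-copy oracle for planted monomers: a planted copy whose
    segment identity falls below the annotation threshold is expected to be
    missed, and vice versa.
    """
    matches, columns, _, _, _ = _score_window(query, segment,
                                              trim_lead=False,
                                              trim_tail=False)
    return matches / columns if columns else 0.0


def global_identity(a: str, b: str) -> float:
    """Identity of the unit-cost global alignment of two sequences.

    Same matches-over-columns rule as the search (no trimming); used e.g.
    to record the realized divergence of simulated monomer copies.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    import re

    for num, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        columns += int(num)
        if op == "=":
            matches += int(num)
    return matches / columns if columns else 0.0
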