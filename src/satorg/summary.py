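"""Satellitome composition, occupancy and organizational-form statistics.

All operations work equally on tables computed by the annotation pipeline
and on the packaged transcriptions of the published tables, so the printed
summary numbers are recomputable without any download.

Family-level statistics merge subfamily variants: CgiSat01a/CgiSat01b are
one family for occupancy counting, while their satellitome percentages sum.
Rounding follows the printed precision: occupancy means to 1 decimal,
percentages to 2 decimals, mean monomers per chromosome to integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import MonomerHit, hits_to_frame
from .boxes import ELEMENT_ASSOCIATED, NO_BOXES, STANDALONE, OrganizationalCall
from .seqio import GenomeSequence


def _as_hits_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    return hits_to_frame(hits)


def occupancy_table(hits, chromosome_ids: Sequence[str],
                    all_seq_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-family chromosome presence and monomer counts.

    ``chromosome_ids`` declares which assembly sequences are chromosomes;
    every other sequence carrying hits counts as an unplaced scaffold. When
    ``all_seq_ids`` is given, each declared chromosome must be in it.

    Returns one row per family with one boolean presence column per
    chromosome plus chromosomes_occupied / monomers_on_chromosomes /
    monomers_on_scaffolds / mean_monomers_per_chromosome. The chromosome
    order is kept in ``df.attrs["chromosome_ids"]``.
    """
    chromosome_ids = list(chromosome_ids)
    if all_seq_ids is not None:
        missing = set(chromosome_ids) - set(all_seq_ids)
        if missing:
            raise ValueError(f"chromosome ids absent from assembly: "
                             f"{sorted(missing)}")
    df = _as_hits_frame(hits)
    rows = []
    for family_id, grp in df.groupby("family_id", sort=True):
        on_chrom = grp[grp.seq_id.isin(chromosome_ids)]
        presence = {c: bool((on_chrom.seq_id == c).any())
                    for c in chromosome_ids}
        occupied = sum(presence.values())
        n_chrom = len(on_chrom)
        n_scaf = len(grp) - n_chrom
        mean = round(n_chrom / occupied) if occupied else 0
        rows.append({"family_id": family_id, **presence,
                     "chromosomes_occupied": occupied,
                     "monomers_on_chromosomes": n_chrom,
                     "monomers_on_scaffolds": n_scaf,
                     "mean_monomers_per_chromosome": mean})
    out = pd.DataFrame(rows, columns=["family_id", *chromosome_ids,
                                      "chromosomes_occupied",
                                      "monomers_on_chromosomes",
                                      "monomers_on_scaffolds",
                                      "mean_monomers_per_chromosome"])
    out.attrs["chromosome_ids"] = chromosome_ids
    return out


def widespread_count(occupancy: pd.DataFrame,
                     total_chromosomes: int = 10) -> int:
    """Number of families present on every chromosome."""
    if occupancy.empty:
        return 0
    return int((occupancy.chromosomes_occupied == total_chromosomes).sum())


def mean_occupancy(occupancy: pd.DataFrame,
                   family_subset: Iterable[str],
                   decimals: int = 1) -> float:
    """Mean number of occupied chromosomes over a family subset."""
    subset = list(family_subset)
    if not subset:
        raise ValueError("empty family subset")
    sel = occupancy[occupancy.family_id.isin(subset)]
    if sel.empty:
        raise ValueError("no occupancy rows match the subset")
    return round(float(sel.chromosomes_occupied.mean()), decimals)


def satellitome_fraction(composition: pd.DataFrame,
                         predicate: Callable[[pd.Series], bool],
                         decimals: int = 2) -> float:
    """Sum of satellitome percentages over variant rows matching the
    predicate (each subfamily variant contributes its own row)."""
    if composition.empty:
        return 0.0
    mask = composition.apply(predicate, axis=1)
    return round(float(composition.loc[mask, "satellitome_pct"].sum()),
                 decimals)


@dataclass
class FormSummary:
    """Organizational-form statistics of one family's extractions."""

    family_id: str
    n_extractions: int
    pct_element_associated: float
    pct_standalone: float
    histogram: pd.DataFrame  # index monomer_count, columns box categories
    max_len_element_associated: int  # monomers; 0 when the form is absent
    max_len_standalone: int


def form_summary(calls: Sequence[OrganizationalCall]) -> FormSummary:
    """Percentages, monomers-per-extraction histogram and maximum array
    lengths per organizational form, for one family's calls."""
    if not calls:
        raise ValueError("no calls to summarize")
    families = {c.family_id for c in calls}
    if len(families) != 1:
        raise ValueError(f"calls span several families: {sorted(families)}")
    n = len(calls)
    n_assoc = sum(c.form == ELEMENT_ASSOCIATED for c in calls)
    df = pd.DataFrame(
        {"monomer_count": [c.monomer_count for c in calls],
         "box_category": [c.box_category for c in calls]}
    )
    hist = (df.groupby(["monomer_count", "box_category"]).size()
            .unstack(fill_value=0))
    max_assoc = max((c.monomer_count for c in calls
                     if c.form == ELEMENT_ASSOCIATED), default=0)
    max_stand = max((c.monomer_count for c in calls
                     if c.form == STANDALONE), default=0)
    return FormSummary(
        family_id=next(iter(families)),
        n_extractions=n,
        pct_element_associated=round(100.0 * n_assoc / n, 2),
        pct_standalone=round(100.0 * (n - n_assoc) / n, 2),
        histogram=hist,
        max_len_element_associated=max_assoc,
        max_len_standalone=max_stand,
    )


def form_summaries_to_frame(summaries: Iterable[FormSummary]) -> pd.DataFrame:
    rows = [
        {
            "family_id": s.family_id,
            "n_extractions": s.n_extractions,
            "pct_element_associated": s.pct_element_associated,
            "pct_standalone": s.pct_standalone,
            "max_len_element_associated": s.max_len_element_associated,
            "max_len_standalone": s.max_len_standalone,
        }
        for s in summaries
    ]
    columns = ["family_id", "n_extractions", "pct_element_associated",
               "pct_standalone", "max_len_element_associated",
               "max_len_standalone"]
    return pd.DataFrame(rows, columns=columns)


def assembly_correspondence(occupancy_a: pd.DataFrame,
                            occupancy_b: pd.DataFrame) -> pd.DataFrame:
    """Chromosome pairing between two assemblies from single-locus satDNAs.

    A family votes for a chromosome pair when it occupies exactly one
    chromosome in each assembly and has zero monomers on unplaced scaffolds
    (a missing scaffold column counts as zero — some assemblies report no
    scaffolds at all). Returns one row per distinct pair with the supporting
    families.
    """
    chrom_a = occupancy_a.attrs.get("chromosome_ids")
    chrom_b = occupancy_b.attrs.get("chromosome_ids")
    if chrom_a is None or chrom_b is None:
        raise ValueError("occupancy tables must carry chromosome_ids attrs")

    def single_locus(occ: pd.DataFrame, chroms: list[str]) -> dict[str, str]:
        out = {}
        for _, row in occ.iterrows():
            scaf = row.get("monomers_on_scaffolds", 0)
            scaf = 0 if pd.isna(scaf) else int(scaf)
            if row.chromosomes_occupied == 1 and scaf == 0:
                chrom = next(c for c in chroms if row[c])
                out[row.family_id] = chrom
        return out

    in_a = single_locus(occupancy_a, chrom_a)
    in_b = single_locus(occupancy_b, chrom_b)
    votes: dict[tuple[str, str], list[str]] = {}
    for family in sorted(set(in_a) & set(in_b)):
        votes.setdefault((in_a[family], in_b[family]), []).append(family)
    rows = [
        {"chromosome_a": a, "chromosome_b": b,
         "supporting_families": ",".join(fams), "n_supporting": len(fams)}
        for (a, b), fams in sorted(votes.items())
    ]
    return pd.DataFrame(rows, columns=["chromosome_a", "chromosome_b",
                                       "supporting_families", "n_supporting"])


def genome_fraction_from_annotation(hits, genomes: Sequence[GenomeSequence],
                                    ) -> pd.Series:
    """Assembly-occupancy percentage per family: non-overlapping annotated
    bp over total assembly bp. (An assembly-based analogue of read-cluster
    abundance estimates; the two can differ for collapsed repeats.)"""
    total_bp = sum(len(g) for g in genomes)
    df = _as_hits_frame(hits)
    out = {}
    for family_id, grp in df.groupby("family_id", sort=True):
        covered = 0
        for _, seq_grp in grp.groupby("seq_id"):
            ivs = sorted(zip(seq_grp.start, seq_grp.end))
            cur_s, cur_e = None, None
            for s, e in ivs:
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                covered += cur_e - cur_s
        out[family_id] = 100.0 * covered / total_bp
    return pd.Series(out, dtype=float, name="genome_pct")


# ---------------------------------------------------------------------------
# optional plots


def plot_monomer_length_spectrum(composition: pd.DataFrame, ax=None):
    """Monomer length vs genomic contribution, one point per variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(composition.monomer_length, composition.genome_pct,
           width=np.maximum(composition.monomer_length * 0.05, 5.0))
    ax.set_xlabel("monomer length (bp)")
    ax.set_ylabel("% of genome")
    return ax


def plot_form_histogram(summary: FormSummary, ax=None):
    """Stacked monomers-per-extraction histogram coloured by box category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summary.histogram.plot.bar(stacked=True, ax=ax)
    ax.set_xlabel("monomers per extraction")
    ax.set_ylabel("extractions")
    ax.set_title(summary.family_id)
    return ax
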