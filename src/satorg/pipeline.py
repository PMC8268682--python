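"""End-to-end orchestration: annotate -> arrays -> extract -> classify ->
summarize, with a run log and deterministic outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotate import (DEFAULT_COMPLETENESS, DEFAULT_MIN_COVERAGE,
                       DEFAULT_MIN_IDENTITY, MonomerHit, annotate_family,
                       hits_to_frame)
from .arrays import (DEFAULT_MAX_GAP_FACTOR, SatArray, arrays_to_frame,
                     build_arrays, filter_arrays, flag_assembly_gaps)
from .boxes import (DEFAULT_BOX_MIN_COVERAGE, DEFAULT_BOX_MIN_IDENTITY,
                    BoxLibrary, OrganizationalCall, box_matrix,
                    calls_to_frame, classify_family, load_box_library)
from .extract import (DEFAULT_FLANK_LENGTH, Extraction, extract_with_flanks,
                      extractions_to_fasta, extractions_to_frame,
                      orient_extraction)
from .seqio import (GenomeSequence, SatDNAFamily, read_consensus_fasta,
                    read_fasta)
from .summary import (FormSummary, form_summaries_to_frame, form_summary,
                      occupancy_table)


@dataclass
class PipelineParams:
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    completeness_threshold: float = DEFAULT_COMPLETENESS
    max_gap_factor: float = DEFAULT_MAX_GAP_FACTOR
    flank_length: int = DEFAULT_FLANK_LENGTH
    box_min_identity: float = DEFAULT_BOX_MIN_IDENTITY
    box_min_coverage: float = DEFAULT_BOX_MIN_COVERAGE
    require_complete: bool = True
    include_scaffolds: bool = True
    chromosome_ids: list[str] | None = None  # None: every sequence


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (flags override config-file values,
    which override defaults)."""

    genome: str
    consensus: str
    output_dir: str
    box_fasta: str | None = None
    box_config: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)


@dataclass
class PipelineResult:
    hits: list[MonomerHit]
    arrays: list[SatArray]
    extractions: list[Extraction]
    calls: list[OrganizationalCall]
    form_summaries: list[FormSummary]
    occupancy: pd.DataFrame


def run_stages(
    genomes: Sequence[GenomeSequence],
    variants: Sequence[SatDNAFamily],
    box_library: BoxLibrary | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full analysis in memory.

    Variants are grouped by family; each family is annotated independently,
    its hits grouped into arrays, arrays with a complete monomer excised
    with flanks, and (when the family maps to a box group) each extraction
    classified as element-associated or standalone.
    """
    params = params or PipelineParams()
    genome_by_id = {g.id: g for g in genomes}
    if not params.include_scaffolds:
        keep = set(params.chromosome_ids or [])
        genomes = [g for g in genomes
                   if g.category == "chromosome" or g.id in keep]

    by_family: dict[str, list[SatDNAFamily]] = {}
    for v in variants:
        by_family.setdefault(v.family_id, []).append(v)
    if not by_family:
        raise ValueError("no consensus records supplied")

    all_hits: list[MonomerHit] = []
    all_arrays: list[SatArray] = []
    all_extractions: list[Extraction] = []
    all_calls: list[OrganizationalCall] = []
    summaries: list[FormSummary] = []

    for family_id in sorted(by_family):
        fam_variants = by_family[family_id]
        ref_length = int(pd.Series(
            [v.monomer_length for v in fam_variants]).median())
        hits = annotate_family(genomes, fam_variants,
                               params.min_identity, params.min_coverage,
                               params.completeness_threshold)
        all_hits.extend(hits)
        arrays = build_arrays(hits, ref_length, params.max_gap_factor)
        arrays = [flag_assembly_gaps(a, genome_by_id[a.seq_id])
                  for a in arrays]
        all_arrays.extend(arrays)
        retained = filter_arrays(arrays, params.require_complete)
        extractions = [
            orient_extraction(
                extract_with_flanks(a, genome_by_id[a.seq_id],
                                    params.flank_length))
            for a in retained
        ]
        all_extractions.extend(extractions)
        if (box_library is not None
                and box_library.group_for(family_id) != "none"
                and extractions):
            calls = classify_family(extractions, box_library,
                                    params.box_min_identity,
                                    params.box_min_coverage)
            all_calls.extend(calls)
            summaries.append(form_summary(calls))

    chrom_ids = params.chromosome_ids or [g.id for g in genomes
                                          if g.category == "chromosome"]
    occupancy = occupancy_table(hits_to_frame(all_hits), chrom_ids,
                                all_seq_ids=[g.id for g in genomes])
    return PipelineResult(all_hits, all_arrays, all_extractions, all_calls,
                          summaries, occupancy)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run writing all stage outputs plus a run log.

    Fails before any computation when an input is missing. Re-running with
    identical inputs reproduces identical outputs (no randomness anywhere in
    the analysis stages).
    """
    inputs = {"genome": config.genome, "consensus": config.consensus}
    if config.box_fasta:
        inputs["box_fasta"] = config.box_fasta
        inputs["box_config"] = config.box_config
    for name, path in inputs.items():
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"{name} input not found: {path!r} — supply it before running"
            )

    genomes = read_fasta(config.genome)
    variants = read_consensus_fasta(config.consensus)
    box_library = None
    if config.box_fasta:
        box_library = load_box_library(config.box_fasta, config.box_config)

    result = run_stages(genomes, variants, box_library, config.params)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits_to_frame(result.hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    arrays_to_frame(result.arrays).to_csv(out / "arrays.tsv", sep="\t",
                                          index=False)
    extractions_to_fasta(result.extractions, out / "extractions.fasta")
    extractions_to_frame(result.extractions).to_csv(
        out / "extractions.tsv", sep="\t", index=False)
    calls_to_frame(result.calls).to_csv(out / "calls.tsv", sep="\t",
                                        index=False)
    if box_library is not None:
        all_box_ids = [b.box_id for b in box_library.boxes]
        box_matrix(result.calls, all_box_ids).to_csv(
            out / "box_matrix.tsv", sep="\t", index=False)
    form_summaries_to_frame(result.form_summaries).to_csv(
        out / "form_summary.tsv", sep="\t", index=False)
    result.occupancy.to_csv(out / "occupancy.tsv", sep="\t", index=False)

    log = {
        "version": __version__,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                   for k, v in inputs.items()},
        "params": vars(config.params),
        "counts": {
            "sequences": len(genomes),
            "consensus_variants": len(variants),
            "hits": len(result.hits),
            "arrays": len(result.arrays),
            "extractions": len(result.extractions),
            "calls": len(result.calls),
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return result
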