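# Methods

## The analysis in one paragraph

Given a genome assembly and a library of satDNA consensus monomers, the
pipeline annotates every monomer copy at ≥ 70% identity on both strands,
groups copies into tandem arrays, excises each array (with at least one
complete monomer) together with up to 2000 bp of flanking sequence per
side, searches the flanks for the conserved terminal segments ("boxes") of
the Helitron transposons related to that satDNA family, and classifies the
extraction as element-associated (boxes on both sides, or on one side —
one-sided truncation of Helitrons is frequent) or standalone (no boxes).
Composition, occupancy and organizational-form statistics are then computed
per family, either from the pipeline's own tables or from the packaged
transcriptions of the published tables.

## Monomer annotation

**Contract.** For a consensus of length m and identity floor t (default
0.70), report every maximal semi-global alignment of the full consensus
against either strand with identity ≥ t, where identity is
matches / alignment columns and gaps count as columns. Fragments are
reportable down to 50% consensus coverage, but only where the sequence
actually ends (an assembly-sequence boundary or the edge of an
already-claimed copy); "complete" monomers require ≥ 90% coverage.

**Algorithm.** Two stages, exhaustive rather than seeded-heuristic:

1. *Location.* edlib's bit-parallel semi-global aligner runs with
   edit-distance cap k = ⌊m·(1−t)/t⌋. Any region carrying an alignment of
   identity t over C columns has unit-cost distance ≤ (1−t)·C ≤ k, so every
   qualifying region is located. All optimal locations are collected, then
   the scan repeats on a masked copy of the target until nothing at
   distance ≤ k remains.
2. *Verification.* Each located window (padded by 4 + m/50 unmasked bases,
   because the unit-cost optimum can clip a few bases the affine optimum
   needs) is re-aligned with affine-gap scoring — match +1, mismatch −1,
   gap open −2, gap extend −1, free end gaps on the window side — and kept
   if the affine alignment reaches the identity and coverage floors.
   Affine verification matters on biased-composition sequence: unit-cost
   optima can inflate matches/columns with gap-rich paths, producing
   borderline ~0.70-identity matches between unrelated sequences that the
   affine optimum correctly scores below threshold.

Masking bookkeeping preserves neighbours: an accepted hit masks only its
claimed core, so adjacent tandem copies keep every base they own; a
rejected location is only *nudged* (one centre base masked per round),
because rejection disproves one placement, not the underlying bases — fully
retiring rejected windows was observed to destroy weak copies overlapped by
phase-shifted near-miss placements. The pad stays well below m so the
free-end alignment cannot wander onto phase-shifted placements over
neighbouring tandem copies.

Query overhangs at a permitted boundary are trimmed by a score rule: the
terminal segment with minimal cumulative affine score is removed provided
its gap columns outnumber its aligned columns. The gap-dominance condition
stops the rule from shaving genuine terminal mismatches off diverged
copies, while still catching overhangs that the affine optimum disguises by
pairing a lucky straggler base at the extreme window edge.

Overlapping hits of one family (including across subfamily variants, so a
locus matched by two variants is counted once) are resolved greedily:
descending identity, then leftmost start, then longest span; a hit is
dropped when it overlaps a winner by more than 20% of the monomer length.
The result is equivalent to a brute-force per-offset semi-global scan with
the same identity rule; the test suite checks this equivalence against an
independently implemented exhaustive oracle on small genomes.

**Identity definition near the threshold.** Detectability at the boundary is
decided by the affine alignment's identity, which on substitution-only
divergence equals the simple match fraction but can differ from a unit-cost
alignment's identity by 1–3% when gaps compete with mismatches. The
synthetic manifest therefore records each planted copy's realized identity
under the same affine semi-global rule the detector uses, which is what
makes "the missed copies are exactly the below-threshold copies" an exact
statement rather than an approximate one.

## Arrays, extraction, classification

*Arrays.* Same-strand copies of one family on one sequence merge when the
gap between consecutive copies is ≤ 1.0 × monomer length (parameter
`max_gap_factor`). No grouping distance is standard for this kind of data;
one monomer length is the smallest rule that keeps tandem copies with small
indels together while splitting dispersed single copies, and downstream
counts (notably the monomers-per-extraction histograms) depend on it. Runs
of ≥ 10 N inside a span set `contains_assembly_gap` but never break the
array. Only arrays holding ≥ 1 complete monomer are carried into flank
analysis.

*Extraction.* Flanks are clipped at sequence ends and flagged truncated;
truncated-flank extractions are kept and classified. Minus-strand
excisions are reverse-complemented (flanks swapped) before box search, so
left/right always refer to the element's own orientation and the box
library needs only one orientation per box.

*Boxes.* The box library maps each family to an element group — groupA
(Box1 44 bp at element start, Box2 49 bp at the end, Box3 156 bp internal)
or groupB (Box4 53 bp start, Box5 42 bp end) — or to `none` for families
whose related Helitrons have no determinable boxes; `none` families are
annotated and extracted but excluded from classification. Terminal boxes
are searched in both flanks on both strands with the same engine as the
monomers, at identity ≥ 0.70 and box coverage ≥ 0.80 (the coverage floor
blocks spurious short partial matches; partial coverage arises only where
an excision boundary cuts a box). Which box lands on which side is
recorded in the 0/1 box matrix but not enforced for classification: a side
counts as hit if any terminal box of the group matches it. The internal
Box3 is reported in the matrix but never classifies.

## Synthetic genomes

The generator emulates the organizational forms the classifier must
distinguish. A full element reads

    start box · spacer(40) · (AC)₁₀ microsatellite · [internal box, groupA] ·
    monomer copies · spacer(40) · end box

truncated elements omit one terminal box, standalone units are bare arrays.
The microsatellite and internal box exist as realistic decoys for the box
detector; neither is used by the classifier. Defaults (the package's study
conditions): 4 chromosomes × 300 kb of uniform i.i.d. background
(gc = 0.5); four families sampling the observed monomer-length range — 21,
166, 437 and 2056 bp, the 21 bp family boxless and standalone-only as its
real counterparts effectively are for classification; 104 units total
(full/truncated/standalone mixtures per family); monomers per array
geometric with mean 2 (mean 1.5, max 3 for the 2056 bp family), so single
monomers dominate as they do in real data; per-copy substitution and indel
rates configurable, 0 by default. Units are planted on either strand with
spacing ≥ max(2000, longest monomer + 50) bp, which guarantees that no 2 kb
flank reaches a neighbouring unit and that two units can never satisfy the
array-merge rule — the manifest is then an exact oracle for every stage.
All randomness flows from one integer seed; outputs are byte-identical
across runs.

Uniform background composition is part of the design: at gc = 0.5, random
2 kb flanks essentially never carry a ≥ 0.70-identity match to a 42–53 bp
box (measured < 1% of flanks, matching the detector's intended null), so
classification accuracy on clean genomes measures the classifier rather
than background coincidence. On AT-rich background (e.g. gc = 0.35,
comparable to the real oyster genome) the same threshold yields ~9% of
flanks with a spurious box match — a property of short-query alignment
statistics at 70% identity, not of the implementation; real-data analyses
at these settings should expect a corresponding false-association floor
(the published workflow adds a manual inspection step at exactly this
point). Even at gc = 0.5 a run with ~90 classifiable units has roughly one
chance in four of containing a single such coincidence somewhere, so
form-classification accuracy on clean genomes is 1.0 for most but not all
seeds. Very short monomers behave analogously: a 21 bp consensus at 70%
identity legitimately matches random background at ~100 sites/Mb/strand,
which depresses reported monomer *precision* (recall and classification are
unaffected; the published satellitome's shortest family would behave
identically under the same threshold).

*Recovery metrics.* A planted copy counts as recovered when a same-family
hit overlaps it reciprocally by ≥ 50%; a hit is a true positive when it
recovers some copy. Form accuracy is scored over classifiable units via
the extraction whose array span reciprocally overlaps the planted array;
count exactness is the fraction of matched units whose monomer count is
exact. At 0% divergence (seed 7: 104 units, 188 copies) recall, form
accuracy and count exactness are all 1.0; at 25% substitutions recall is
0.95 and the missed copies are exactly those with realized identity < 0.70.

## Printed-table fixtures

The published composition table (53 variant rows, 52 families) and both
occupancy panels were transcribed once into TSV, frozen with sha256
checksums verified at load, thousands separators normalized, "-" Repbase
entries mapped to empty strings. Family-level statistics merge subfamily
variants (CgiSat01a/b count once for occupancy; their satellitome
percentages sum). Recomputation notes: the Helitron fraction sums to 75.60
vs the printed 75.61 and the mobile-element fraction to 91.74 vs 91.76 —
print-rounding residues of the row values; the published mean occupancy of
mobile-element-unrelated families (7.0) is not recoverable from either
panel under any obvious subset (the 13 unannotated families give 85/13 =
6.5 on the GCA_902806645.1 panel), so both computable variants are exposed
and neither is asserted. "% of the genome" in the composition table came
from read clustering; the package's assembly-based analogue
(`genome_fraction_from_annotation`, non-overlapping annotated bp / assembly
bp) measures a related but distinct quantity — collapsed repeats depress
it — and the two should not be compared numerically.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 0.70 | monomer annotation identity floor (≤ 30% divergence) |
| `min_coverage` | 0.50 | minimum reportable consensus coverage (fragments) |
| `completeness_threshold` | 0.90 | coverage for a "complete" monomer |
| `max_gap_factor` | 1.0 | array merge distance, × monomer length |
| `flank_length` | 2000 bp | excised flank per side |
| `box_min_identity` | 0.70 | box match identity floor |
| `box_min_coverage` | 0.80 | box match coverage floor |
| `min_n_run` | 10 | N-run length flagging an assembly gap |
| overlap tolerance | 0.20 × m | permitted overlap between retained hits |

All are exposed on the library calls, the pipeline config and the CLI
(flags override config-file values, which override defaults).

## Limitations

- Alignment statistics, not biology, set the floor for short queries: at
  70% identity, 21 bp monomers and (on AT-rich background) 42–53 bp boxes
  match random sequence at non-negligible rates. Raising thresholds or
  requiring both terminal boxes trades this against sensitivity to
  genuinely diverged copies; the defaults mirror the published analysis.
- Fragments embedded mid-sequence (not at an assembly or array boundary)
  are scored against the full consensus and are typically lost below
  ~0.57 coverage; the semi-global contract makes this inherent.
- The simulator mutates copies independently; it does not model concerted
  evolution (library effects, within-array gradients), nested or
  overlapping insertions, or segmental duplications. Passing recovery
  tests therefore demonstrates correctness of detection and bookkeeping,
  not performance on every real repeat landscape.
- Array grouping and hence monomers-per-extraction histograms depend on
  `max_gap_factor`; comparisons across parameterizations are not
  meaningful.
- Chromosome correspondence uses only single-locus, scaffold-free families
  and transfers no coordinates; it pairs chromosomes, nothing finer.
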