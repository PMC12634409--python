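# Methods

## Model and procedure

`zdnascan` predicts Z-DNA forming sequences (ZFS) from primary sequence
alone, using a linear dinucleotide scoring system. The biological premise
is that the left-handed Z conformation requires regular
pyrimidine–purine alternation with some G+C content: (GC)n is the
strongest motif, (GT)n/(CA)n intermediate, and pure (AT)n tracts
generally do not form Z-DNA. The model therefore assigns one score per
alternating dinucleotide class (GC/CG; GT/TG/CA/AC; AT/TA), while the
eight purine–purine / pyrimidine–pyrimidine steps (AA, CC, GG, TT, AG,
CT, GA, TC) — and any step touching a non-ACGT symbol — are *breaks*
that can never occur inside a hit.

Scanning is a single left-to-right pass over the **overlapping**
dinucleotide steps (stride 1, so an L-bp window holds L−1 steps). A run
terminates at a break step, at a step whose class is scored 0 by the
active model, or at the end of the sequence; each maximal run is tested
exactly once (no sub-window rescue search) against two thresholds:

* `min_length` — default **12 bp**, one full Z-DNA helical turn;
* `min_score_percent` — default **50**, where score % normalizes the raw
  step-score sum by the best achievable sum for the same step count
  (`(L−1) × max(score_gc, score_gt, score_at)`), keeping score % ≤ 100
  under arbitrary custom parameters.

The overlapping-step convention was chosen because it is frame-invariant
and reproduces the documented behavior of the two presets on the mixed
tract `GCGTGCATGTGTGC`: under Model 1 (GC=25, GT=3, AT=0) the lone AT
step is rated 0, splitting the tract into two 7-bp fragments below the
12-bp minimum, whereas Model 2 (GC=2, GT=1, AT=0.5) scores it whole
(raw 16.5 of a possible 26, 63.46%).

The class map is closed under reverse complement, which gives the
scanner exact strand symmetry: hits on the reverse complement are the
coordinate-mirrored hits of the forward strand with identical scores and
richness values (property-tested).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `score_gc`, `score_gt`, `score_at` | per preset | score per step of each alternating class; a 0 acts as a break |
| `min_length` | 12 bp | minimum run length (one Z-DNA turn) |
| `min_score_percent` | 50 | minimum normalized score |
| long-ZFS threshold | 24 bp | two turns; used only for the long-hit filter |
| BedGraph value | score % | `raw_score` selectable |
| compartment counting rule | midpoint | `overlap` (≥ 1 bp) selectable |

The published description of the method names `min_score_percent` but
prints no default; 50 was adopted as this package's default and is
recorded in every output's provenance header, and the `sweep` subcommand
(default 40–70 in steps of 5) exists precisely to locate an operating
point against published per-chromosome tables.

Case is ignored: soft-masked (lowercase) residues score normally, since
ZFS are dinucleotide repeats and frequently soft-masked. IUPAC ambiguity
codes are treated as breaks, not expanded.

## Statistics and interval operations

Per-sequence summaries report hit count, summed bp, median and maximum
hit length (0 when there are no hits), frequency = 1000 × count /
sequence length, and coverage % = 100 × summed bp / sequence length.
G+C content is computed over ACGT bases only, excluding assembly-gap Ns
from the denominator. Medians with an even count average the two middle
values. Pooled (TOTAL) rows recompute frequency and coverage from summed
totals — never by averaging per-sequence values — and recompute the
median over the pooled hit-length multiset.

Interval benchmarking uses 0-based half-open coordinates throughout. A
reference interval is *matched* when ≥ 1 bp of any predicted interval
overlaps it (half-open adjacency is not overlap); sensitivity is the
matched fraction of the reference and the false-positive rate the
unmatched fraction of predictions. The 2/3-set bp Venn decomposition
merges each input first so nested intervals never double count, then
sweeps elementary segments between all boundary points; the regions sum
exactly to the union bp (property-tested). Compartment densities
(per kb) count a hit by the compartment containing its midpoint by
default — boundary handling is not fixed by the published description,
so the ≥ 1 bp-overlap rule is available behind a flag. The
expected-random-overlap helper is the elementary `n_hits ×
feature_fraction` estimate. A strand-aware promoter-window helper
(499 bp upstream to 100 bp downstream of a TSS) is provided as a
data-preparation convenience for external annotations, not a scanned
output.

## Synthetic data: what it does and does not emulate

The fixture generator plants (GC)n, (CA)n, (AT)n and mixed GCGT-period
motifs at chosen coordinates in a uniform-ACGT background that is
verified hit-free under both presets at default thresholds (redrawn on
violation, so truth tables are exact). Two copies of a plant's first
(last) base are written immediately before (after) it, forcing break
steps at both junctions; realized hit coordinates therefore equal plant
coordinates exactly. Expected detectability per model is computed by
scanning each isolated motif, not asserted by hand — e.g. (CA)20 scores
exactly 50% under Model 2 (detected at the default threshold, not
above), and (AT)n is break-split under Model 1 but a 25% run under
Model 2.

Uniform background with planted motifs deliberately does *not* emulate
real genomes: no repeat landscape, GC heterogeneity, soft-masking
structure or assembly gaps. Passing fixture tests therefore demonstrates
algorithmic correctness (coordinates, scores, thresholds, truth
recovery), not genome-scale biological realism; the genome-scale check
against the published *D. melanogaster* dm6 table is separate and
requires the assembly to be supplied locally.

## Numerical and engineering choices

* The scanner is numpy-vectorized (class lookup tables over byte codes,
  prefix sums per chunk) and incremental: FASTA input is consumed in
  1 MiB chunks with only one carry character and the currently open run
  held between chunks, so memory is bounded regardless of chromosome
  length. Equivalence of chunked and one-shot scanning is tested down
  to 1-byte chunks.
* All preset scores are binary-representable (25, 3, 0, 2, 1, 0.5), so
  raw scores are exact in double precision; comparisons in tests still
  use tolerances where floats are involved. Threshold comparisons are
  inclusive (`≥`), so a run at exactly 50% passes the default.
* A brute-force, character-by-character run enumerator lives in the
  test suite (and, re-stated, in the acceptance script) with no code
  shared with the scanner; scan output is required to match it exactly
  on 1000 randomized planted sequences per run.
* CSV export uses RFC-4180 quoting, UTF-8, LF endings, 2-decimal reals,
  and a `#` provenance line carrying the model name, all three scores
  and both thresholds; it also carries 1-based inclusive display
  coordinates beside the 0-based half-open ones. BedGraph output is
  sorted and refuses overlapping intervals (the format forbids them; a
  single-model scan cannot produce them).
* Degenerate inputs: an empty sequence or all-N sequence yields an
  empty hit list, not an error; an empty FASTA file yields header-only
  outputs and exit 0; usage errors exit 2 and runtime errors 1.

## Problem sizes used by the default test run

Oracle-equivalence checks use 1000 sequences of 50–5000 bp (mixed
random and planted); property tests run 60 derandomized examples per
invariant; fixtures use 400-bp backgrounds with four plants. These sizes
keep the default suite and the acceptance script each well under a
minute while exercising every code path, including multi-chunk runs.

## Known limitations

* The scoring is pattern-based: no thermodynamics (supercoiling energy,
  salt, methylation) and no learned sequence context; scores rank
  propensity within a model but are not free energies.
* The exact operating threshold of the published web implementation is
  not printed; genome-scale count reproduction therefore requires the
  `sweep` step to locate it before comparison.
* Interval utilities assume consistent chromosome naming between sets
  (a `chr` prefix is the caller's responsibility); mismatched
  chromosomes count as unmatched with a logged warning.
* Statistical significance of enrichment ratios is out of scope; the
  package reports ratios and expectations only.
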