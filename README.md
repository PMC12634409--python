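# zdnascan

Detection of **Z-DNA forming sequences (ZFS)** in nucleotide sequences by
dinucleotide run scoring, with genome-browser-ready exports and interval
benchmarking utilities.

Z-DNA is the left-handed double-helical DNA conformation, favored by
tracts of regularly alternating pyrimidines and purines — canonically
(GC)n and (GT)n/(CA)n repeats — under negative supercoiling. `zdnascan`
locates such tracts at genome scale: whole eukaryotic chromosomes scan in
seconds on one CPU. It is written for genome biologists who want ZFS
coordinates, scores and summary statistics they can overlay on functional
annotations, and for tool builders who need a fast, fully parameterized
pattern-based baseline.

## The scoring model

Every overlapping dinucleotide step of a sequence falls into one of four
classes:

| class | steps | preset *Model 1* | preset *Model 2* |
|---|---|---|---|
| GC | GC, CG | 25 | 2 |
| GT/CA | GT, TG, CA, AC | 3 | 1 |
| AT | AT, TA | 0 | 0.5 |
| break | AA, CC, GG, TT, AG, CT, GA, TC, any non-ACGT | — | — |

An L-bp window has L−1 steps; its **raw score** is the sum of step scores
and its **score %** is

```
score% = 100 · Σ step_score / ((L−1) · max(score_GC, score_GT, score_AT))
```

The scanner walks left to right, extending a run until it meets a break
step or a step whose class is scored 0 under the active model (so AT
breaks under Model 1 but not Model 2). At each break the maximal run just
ended is tested once against the two thresholds — minimum length (default
12 bp, one full Z-DNA helical turn) and minimum score % (default 50) —
and, if it passes, reported as a ZFS with its coordinates (0-based
half-open), raw score, score %, and GC / GT-class step richness.

Model 1 is strict (essentially (GC)n with limited GT/CA admixture);
Model 2 is permissive and rescues mixed tracts: `GCGTGCATGTGTGC` splits
into two sub-threshold 7-bp fragments under Model 1 (the lone AT step is
rated 0) but is one 14-bp hit under Model 2.

## Worked example

```python
>>> import zdnascan as z
>>> z.scan_sequence("GCGTGCATGTGTGC", z.MODEL_1)
[]
>>> (hit,) = z.scan_sequence("GCGTGCATGTGTGC", z.MODEL_2)
>>> hit.start, hit.end, hit.raw_score, round(hit.score_percent, 2)
(0, 14, 16.5, 63.46)
>>> round(hit.gc_richness, 2), round(hit.gt_richness, 2)
(30.77, 61.54)
```

The 13 steps of the 14-bp tract are 4 GC-class (×2), 8 GT-class (×1) and
1 AT-class (×0.5) = 16.5 raw, against a best-possible 13 × 2 = 26, i.e.
63.46%; 4/13 = 30.77% of steps are GC-class and 8/13 = 61.54% GT-class.

From a shell:

```
zdnascan scan genome.fa --model model2 --out-dir results/
zdnascan compare results/genome.hits.bed reference_a.bed reference_b.bed
zdnascan sweep genome.fa --model model1 --lo 40 --hi 70 --step 5
zdnascan fixtures --seed 1 --out-dir fixtures/
```

`scan` writes per-hit CSV (with a provenance header recording the full
parameter set), BED, BedGraph (UCSC-browser-ready), and a per-sequence
statistics table (hit count, summed bp, median/max length, frequency per
1000 bp, % coverage, plus a pooled TOTAL row). `compare` benchmarks a
prediction BED against reference BEDs under the "≥ 1 bp overlap" match
rule (sensitivity, false-positive rate, and the bp Venn decomposition of
2–3 sets). `sweep` tabulates totals across a minimum-score-% range, and
`fixtures` writes deterministic planted-motif test data with truth BEDs.

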