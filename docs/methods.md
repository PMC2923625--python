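# Methods

## Coordinate and data model

All coordinates are 0-based, half-open `[start, end)` following the UCSC
table convention; 1-based positions appear only in human-readable output.
The TSS of a plus-strand transcript is `txStart`; of a minus-strand
transcript, `txEnd − 1`. A gene is a cluster of isoforms, taken from a
knownIsoforms-style map when available; without a map, same-strand
transcripts sharing ≥ 1 bp of exonic sequence are joined by single linkage —
this fallback matches the working definition of a gene as a set of
transcripts that share sequence, and is exercised against a brute-force
connected-components oracle in the tests. Malformed annotation records are
skipped with counted warnings rather than aborting, to tolerate real table
dialects.

## Pair identification

Within a gene, transcripts are ordered by TSS along the direction of
transcription. The caller returns the first ordered pair (P1 upstream, P2
downstream) with distinct TSSs where P2's first exon is entirely contained
in one intron of P1 and neither first exon overlaps any exon of the partner
transcript; one pair per gene, so loci with more than two promoters
contribute only the first two encountered along the DNA. Interpretation
choices that the source material leaves open:

- "unique first exon" is operationalized as zero-bp overlap — a single
  shared base pair disqualifies;
- TSS ties between candidate transcripts break by transcript id, making
  output deterministic;
- the caller scans ordered TSS pairs and returns the first *qualifying*
  pair (promoters rejected by the containment rule do not use up one of the
  two slots).

Filters for the expression pipeline: either first exon ≤ 60 bp, overlapping
≥ 1 bp of any repeat (all repeat classes), or without an overlapping probe
drops the pair; every rule that fires is recorded as a flag, so filter order
is irrelevant to the final set. The repeat-class exclusions (Simple_repeat,
Satellite, Low_complexity) apply only to the DAlFE-vs-CFE repeat-association
statistic, not to this filter. The CFE control set comprises loci whose
isoforms all share an identical first exon and whose representative isoform
(most exons, ties by id) has ≥ 3 exons. CpG status of a promoter uses a
±500 bp TSS window — the promoter extent is not defined by the source
analysis, so this is a package default, configurable.

## Replicate summarization

For each probe × tissue triplet the reference median *m* is computed once
over all replicates; a value *v* is discarded as "above" when *v* > 3.5 *m*
and "below" when *v* < *m*/3.5 (strict inequalities: a value exactly at the
3.5-fold boundary is kept, since it does not *exceed* the fold difference);
the summary is the median of the kept values. The reference median is not
recomputed after exclusion — the single pass is deterministic and idempotent
on clean data, and with three replicates at most the extreme values can be
excluded, so the summary always lies within the observed range. "3.5-fold
difference" is read as a ratio (not an absolute difference of 3.5 *m*),
consistent with how fold differences are used throughout this analysis
domain. Multiple probes per first exon combine by the median of their
summaries; the combination rule is a package choice (about four probes per
exon is typical, with no canonical pooling rule). An all-zero triplet
summarizes to 0.

## Entropy statistic and classes

The specificity score adds a pseudocount of 5 to every intensity *before*
normalization, guarding against spurious specificity at near-zero signals,
then computes Shannon entropy in bits. Two statistics are offered:
`shannon` (range [0, log₂ n]; default) and the Schug-style
`q_max = H − log₂ max_t p_t` (range [0, 2 log₂ n]). The transformed score
used in the original tissue-panel study is not algebraically recoverable
from its description (its printed values exceed both statistics' maxima for
n = 11), so no third form is guessed; class thresholds (default < 3
tissue-specific, ≥ 7 uniform) are therefore configurable, and on the raw
Shannon scale the defaults classify conservatively (nothing reaches 7 for
n = 11). For synthetic-recovery tests the calibrated thresholds 2.85/3.45
separate the generator's planted classes on the Shannon scale.

## Tissue preference and the independence model

A tissue is preferred when its summarized intensity strictly exceeds 2× the
promoter's center across tissues. The center defaults to the **median**
(the statistic's primary description), with `mean` available because the
tabular presentation of the same analysis is headed "2× Average"; the
discrepancy is inherited from the source material. The most-preferred
tissue is the argmax intensity, required to pass the threshold; argmax ties
break by tissue name.

With counts pooled over P1 and P2 (2G promoters), the expected number of
gene pairs sharing tissue *t* as most-preferred is (count/2G)² × G. The
test is a two-category chi-square goodness of fit with df = 1 and no
continuity correction:

    chi² = (O−E)²/E + ((G−O)−(G−E))²/(G−E)

which matches an independent statistical-library oracle to six significant
digits and reproduces the reference panel's printed p-values to about two
significant digits given count rounding. Note a calibration property
verified in the tests: when the expected count is the *plug-in* estimate
from the same data (as in the pipeline report), the test is mildly
conservative under the null, because observed and estimated-expected counts
are positively correlated; fed the true expectation, its null p-values are
uniform. Conservatism is the safe direction for the significance claims the
report makes.

## Tag islands, profiles and CAGE

Island calling uses a 100-bp window sliding at 1-bp resolution: a window
qualifies when it covers ≥ 3 tag positions; qualifying windows that overlap
or abut merge, and each island is trimmed to its outermost contributing
tags (so islands on a chromosome are disjoint). The merge rule is a package
decision — the cited island algorithm is not restated in the source — and
is verified against a brute-force every-window oracle. Tags are single
5′-end positions. Promoter mark status is YES when an island overlaps a
±1 kb TSS window (a package default; ±0 gives point-in-island semantics).
Tag profiles orient distances by strand (negative = upstream) and report,
per 100-bp bin over ±5 kb, the percentage of TSSs whose bin holds ≥ 3 tags.
CAGE support requires a strand-matched cluster overlapping a 201-nt window
centered on the TSS (±100 bp; ±50 bp/101-nt also supported).

## Synthetic data

The generator emulates the statistical structure of the real study
conditions: 11 tissues (breast, cerebellum, heart, kidney, liver, muscle,
pancreas, prostate, spleen, testes, thyroid) × 3 replicates; log-normal
baseline intensities (median ≈ 30, chosen so magnitudes resemble the tens
reported for typical promoters — cosmetic only); specificity classes mixed
at 14% tissue-specific / 79% heterogeneous / 7% uniform with a 20× preferred-
tissue effect; per-value replicate outlier rates 5.6% above / 2.8% below
(the exclusion fractions observed on the real arrays), injected as 5–10×
multiplicative distortions with **at most one outlier per triplet** so the
triplet median stays anchored and the per-value planted rate is exact;
inter-TSS distances drawn from a short (median 700 bp) / long (median 15 kb)
log-normal mixture, with co-marked pairs biased toward the short group so
the joint-status distance ordering is recoverable; H3K4me3-like joint status
at 52%/34%/14% (both/one/neither); 10 tags within ±300 bp of each active
TSS over a sparse background; 90% CAGE hit rate. Gene types beyond `dalfe`
each violate exactly one rule (shared first exon, overlapping first exons,
≤ 60 bp first exon, repeat in first exon, missing probes, single isoform).
Genes occupy disjoint 60-kb territories on one synthetic chromosome; minus-
strand genes are generated in transcription-local coordinates and reflected.

What the generator does **not** emulate: nucleotide sequence, probe GC/
cross-hybridization effects, array batch structure, overlapping gene loci,
or realistic repeat landscapes. Passing tests therefore demonstrate
correctness of the interval logic, summarization and statistics under the
declared generative model — not robustness to array artifacts on real data.

A separate lightweight simulator draws paired most-preferred-tissue labels
directly (default frequencies: the reference panel's per-tissue
most-preferred counts over 2,894 promoters), with a copy-rate parameter for
co-preference; the rate that doubles the expected shared-pair total is
derived analytically as ρ = Σq²/(Σq − Σq²) ≈ 0.174. This is what the
200-seed calibration and power checks use: at G = 1447, null p-values (vs
the true expectation) pass a Kolmogorov–Smirnov uniformity check, and the
2× co-preference alternative rejects at p < 10⁻⁶ in every seed tested.

## Problem sizes and determinism

Tests run the callers against brute-force oracles on 1,000 random clusters
and 200 random tag sets, the summarizer on ~10⁵ planted triplets, and the
preference test on 200 simulated panels of 1,447 genes; pipeline-level
checks use 25–200-gene synthetic bundles. All randomness flows from
explicit seeds; `run-all` with a fixed config and inputs is byte-identical
across reruns (the report bundle contains no timestamps, and the config
hash covers analysis parameters only).

## Known limitations

- Only the first two qualifying promoters per gene are modeled; loci with
  three or more alternative promoters are out of scope.
- Normalization (PLIER-style or quantile) is assumed done upstream; inputs
  are taken as normalized intensities.
- The entropy-class thresholds are scale-dependent and must be calibrated
  to the chosen statistic; cross-study comparison of class fractions is not
  meaningful without that calibration.
- The independence model pools P1 and P2 preference frequencies; if the two
  promoter positions had systematically different preference profiles, the
  pooled expectation would be biased.
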