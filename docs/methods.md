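# Methods

This note documents the models, conventions and numerical choices behind
`damagemap`, and what the synthetic-data experiments do and do not show.

## Coordinates and calling convention

All in-memory coordinates are 0-based half-open (BED-native); 1-based
coordinates appear only in mutation-catalog inputs, converted on read.
Damage-seq places the lesion one base 5′ of the read start on the read's
strand: a + read with 5′ end *p* ⇒ site *p*−1 on +; a − read with 5′ end
*p* ⇒ site *p*+1 on −, base = complement of the reference. Calls are kept
regardless of the reference base — non-G calls *are* the background signal
in the base-composition diagnostic — and the restriction to guanine happens
only in signature extraction. Reads are not deduplicated by default (the
5′-end collision rate is reported instead), and premature-stall reads are
never reassigned; they are quantified diagnostically through the −1/−2
composition table.

## Synthetic damage model

`DamageModel` is the generative counterpart of the measurement process:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `context_weights` | sampling weight per NGN triad (16) | CpG-flavoured: ×3.0 for 5′C, ×0.6 for 5′T, ×1.8 for 3′G, ×0.7 for 3′T | a fixed, non-trivial preference with the 5′-CpG flavour reported for bulky guanine adducts; recoverable by the signature pipeline |
| `open_region_survival` | weight multiplier inside open-chromatin intervals | 1.0 (0.4 in cohorts) | < 1 emulates faster repair of accessible DNA |
| `ts_survival` | multiplier on the transcribed (template) strand of genes | 1.0 (0.6 in cohorts) | transcription-coupled repair analog |
| `purity` | adduct-derived read fraction | per sample | dose is modelled as purity: planted landscape is shared, only the adduct read fraction grows |
| `premature_stall_fraction` | adduct reads starting at −2 | 0.05 | the early-stall species is reported qualitatively only; 5% is a conservative minor fraction, config-exposed |
| `background_g_bias` | P(G at −1) of background reads | 0.30 | reproduces the elevated G frequency of untreated libraries |

Genomes are sampled i.i.d. within 10 kb blocks whose GC is drawn from a
clipped normal (mean 0.41, SD 0.05 by default) — an isochore-like
heterogeneity that gives binned GC correlations something to see. Damage
positions are drawn **without replacement** over all eligible G positions
on both strands (both strands independently eligible; a G/C pair can carry
two distinct sites), with probability ∝ context weight × chromatin survival
× strand survival. At the sampling fractions used in validation (5–12% of
eligible positions) the no-replacement constraint measurably flattens
high-weight contexts relative to the naive "frequency ∝ weight" limit; the
test oracles therefore use the exact inclusion probabilities of sequential
weighted sampling (π_i = 1 − exp(−θw_i), with θ set by Σπ = n).

Adduct reads are allocated over planted sites as evenly as possible (floor
multiplicity plus a random remainder), so with n_reads ≥ n_sites every
planted site is covered and calling at purity 1 inverts the generator
exactly. Fragments overhanging a contig end are truncated (the informative
5′ end is kept); only reads whose 5′ end itself leaves the contig are
resampled. Background reads have G at the −1 position with exactly
`background_g_bias` probability (positions are drawn from precomputed
G/non-G pools), which makes the mixture expectation at the called position
exactly `purity + (1 − purity) × bias`. Not emulated: sequencing errors,
quality scores, PCR duplicates, mappability, immunoprecipitation sequence
bias — so passing tests demonstrate correctness of the analysis logic under
a clean generative model, not robustness to real-library artifacts.

## Distribution statistics

**Normalization.** Bin rates are counts per million called sites (CPM) per
sample; the relative abundance is log₂((cell+ε)/(nDNA+ε)) on the rate
scale with ε = 1. Bins empty in both samples are missing (NaN), never 0;
swapping the samples negates every value exactly. Replicate summaries
average per-replicate log-ratios, not ratios.

**Correlations** are Spearman throughout (ties by average rank), matching
standard practice for binned genomic signals; replicate tracks report the
mean ± SD of per-replicate coefficients.

**Bin-size evaluation.** Counts at a common base resolution (the gcd of
the candidate widths) are modelled as Poisson observations of a latent
rate that is constant within each candidate bin, i.e. the candidate
binning is a block-average smoother of the base-resolution signal. The
score is AIC = −2 log L + 2·tr(S), where the trace of the block smoother
equals the number of candidate bins. Too-small bins buy little likelihood
per parameter; bins wider than the genuine rate structure pay in
likelihood — so for homogeneous data the AIC is flat-to-decreasing in
width, while clustered data place the minimum at or below the cluster
scale. Widths within 5% (of the observed AIC range) of the minimum are
flagged as the selected range; widths exceeding the longest contig are
skipped with a warning.

**Hot/cold spots** use strict percentile thresholds (99.99 / 0.01 by
default); with fewer than 10⁴ usable bins those defaults cannot select
anything meaningful and are scaled to the 1/n tails with a warning.

**Strand bias.** "Transcribed strand" means the template strand (antisense
to the mRNA): for a + gene, TS counts are − strand sites in the gene body.
Aggregate significance is a two-sided Wilcoxon signed-rank across genes
(the number of genes, not reads, is the unit of replication); the pooled
ratio ΣTS/ΣNTS is reported alongside. Degenerate inputs (one gene, all
ties) return p = 1 rather than failing.

**Metagene profiles** use 25 bp bins over anchor ± flank (default 2 kb),
oriented 5′→3′ of each gene so upstream plots left; the aggregate curve is
the per-gene mean of CPM-scaled bin counts. LOESS smoothing is available
for presentation only and never feeds a statistic.

## Signature extraction

Context profiles are read 5′→3′ on the damaged strand (minus-strand triads
reverse-complemented), weighted by read support, excluding contig edges
and N-containing windows. Enrichment correction divides observed triad
frequencies by genomic triad frequencies (counted over every position on
both strands) and renormalizes to unit sum — under the generative model
this cancels availability exactly, so the corrected profile estimates the
planted context preference. NMF (Frobenius objective, random
initialization) runs with 50 restarts by default, keeping the lowest
reconstruction error (ties → lowest restart seed). Signatures are
unit-sum columns of W; contributions are unit-sum columns of H; columns
are ordered by contribution in the untreated (background) sample,
descending, so the background-like signature comes first and the
damage-like signature last. NMF runs on background-corrected unit-sum
profiles by default (`context_matrix(..., correct_background=False)`
switches to raw frequencies).

**Rank selection** pools restart signatures per candidate k, clusters them
(k-means on unit-normalized columns) and scores the mean cosine
silhouette; the selected rank is the largest k that is stable (silhouette
≥ 0.8; k = 1 counts as stable) *and* still reduces the reconstruction
error by ≥ 5% of the data norm relative to k−1. On cohorts generated by a
background process plus one damage process this recovers k = 2.

**Reference comparison.** A G-centered damage triad 5′f-G-t3′ maps to the
pyrimidine-centered mutation context comp(t)-C-comp(f) (reverse complement
of the full triad); the 16 bars of the chosen substitution channel and the
mapped damage vector are both unit-summed before the cosine. This mapping
is stated explicitly because orientation errors here are silent: it is a
bijection between the two 16-bar spaces and is covered by a dedicated
test.

## Site matching

Mutation records are strand-agnostic; a damage call on either strand of
the G:C pair at the mutation's coordinate counts as a match (an explicit,
documented choice). Replicate read support is summed within each exposure
condition; flags: `multi_condition` = damage in ≥ 2 conditions,
`multi_read` = ≥ 2 reads in at least one condition across its replicates.
Recurrence percentiles are the fraction of catalog records with recurrence
≤ the match's (the most recurrent site scores 100).

## Validation scale and determinism

End-to-end validation uses a 2 Mb single-contig genome with 50,000 planted
sites and ~120,000 reads per sample for signature recovery, and a 1 Mb /
20,000-site six-sample cohort for rank selection — sizes at which the
binomial/χ² test bands are tight while the whole suite runs in well under
a minute. Every random draw flows from a single seed through
`numpy.random.SeedSequence` spawning; writers use fixed float formatting,
so identical (config, seed) pairs produce byte-identical outputs.

## Known limitations

- The AIC bin-size model documents one concrete realization of a
  smoothed-count criterion; other estimators of the same family would
  shift absolute AIC values (the selected range is what is meaningful).
- Background correction assumes the genome-wide triad availability is the
  right null; regional composition biases (e.g. immunoprecipitation
  preferences) are not modelled.
- The generator's dose model (purity of a shared lesion landscape) ignores
  saturation and dose-dependent context shifts; only monotonicity of the
  dose response is claimed or tested.
- Matching treats coordinates as exact; no liftover, no indel handling.
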