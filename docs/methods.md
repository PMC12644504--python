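# Methods notes

This document records the models, conventions, parameter choices and known
limitations behind `panacr`, in the order data flows through the pipeline.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read. Bookended intervals ([100,200) and [200,300)) **do**
fuse during merging with `min_gap=0`: this is the reduce-style behaviour of
standard genome-arithmetic toolkits and keeps union lengths stable, but it
means counts can differ by a small margin from tools that only fuse
strictly-overlapping intervals. Strand is ignored by all overlap
computations (chromatin accessibility is unstranded) and used only to
orient TSS-relative windows and profiles. Contig names are matched by exact
string equality; the validation pass reports contigs present in one input
but not another, because silent naming mismatches are the dominant
real-world failure mode.

Interval operations are a sorted-array sweep-line over a folded coordinate
axis (contig index × 2⁴⁰ + position), which lets one `maximum.accumulate`
pass cluster a whole genome. Every operation is tested against an
independent per-bp boolean-mask oracle on contigs ≤ 100 kb.

## Consensus construction

Filter order is: per-sample length filter → WGS-control subtraction →
cross-sample support. The order matters only for logging (each filter
reports its removal count); the surviving set is order-independent.

- **Length filter**: peaks strictly longer than 4,000 bp are removed
  (a 4,000 bp peak is kept). The rule applies to *called peaks* only;
  single-linkage fusion may chain staggered peaks into consensus ACRs
  longer than 4 kb, and those are retained.
- **WGS subtraction**: any ATAC peak sharing ≥ 1 bp with a control peak
  from the matching accession is removed entirely (not trimmed).
- **Support**: support is counted as *distinct samples* per fusion cluster;
  a sample contributing two peaks to one cluster counts once. With
  `min_support=1` the consensus reduces to the plain merged union;
  raising support is monotone non-increasing in ACR count.

## The pan-ACR index and the sharing null

Species-scope consensus sets are fused across species; pan-ACR ids are
coordinate-derived (`chrom:start-end`) and therefore deterministic. The
sharing table assigns each pan-ACR to its exact open-species set.

The permutation null shuffles whole samples across species labels with the
per-species sample multiset fixed (asserted every iteration), recomputing
consensus, index and counts each time — so the null carries all of the
sample-size and within-species-replication structure of the design.

Two intervals are reported per species combination:

1. the **t interval for the mean** of the permuted counts,
   x̄ ± t(0.975, n−1)·s/√n. This is the headline labeling rule
   (`label`), but note it is an interval for the *mean of the null
   distribution*, with width ~s/10 at n=100 permutations. A single
   observed count drawn from the same distribution falls inside it only
   ~16% of the time, so this rule is intentionally sensitive: almost any
   real deviation is labeled enriched/depleted.
2. the **empirical 2.5/97.5 permutation percentiles**
   (`label_empirical`). This is the interval whose coverage actually
   calibrates: on label-exchangeable data ~95% of combinations fall
   inside it (the acceptance suite verifies 95 ± 5 points over 200
   replicate datasets).

Consumers who want conventional type-I control should use
`label_empirical`; `label` reproduces the sensitive headline-style calls.

## Frequencies, spectra and fixed dACRs

An accession is open for a pan-ACR iff at least one of its samples has an
overlapping peak (≥ 1 bp); replicate samples within an accession are thus
collapsed by union. Per-species frequency is the fraction of open
accessions, so the joint frequency spectrum's axis bins are the attainable
fractions {0, 1/n, …, 1} given the accession counts. Fixed dACRs use exact
frequency 1 vs 0. Note the frequency definition is agnostic to *why* a
region is differential: a region open only in the wild species also
satisfies the fixed-closed criterion for every crop, which is the
biologically correct reading (it is fixed open in the wild ancestor and
fixed closed in the crop).

State-change percentages (opened/closed bp between a crop and the wild
reference) use pan-ACR fused lengths and, by default, the *effective*
genome size denominator (the mappable-genome size handed to a peak caller,
e.g. 439 Mb against a 434.9 Mb assembly); the assembly length is available
as an option.

## Selective sweeps

Sweep regions are the top `top_fraction` (default 0.01% = 1e-4) of
genome-wide score windows: k = max(1, ⌊f·n⌋) windows by descending score
with deterministic (score, chrom, start) tie-breaking (an include-all-ties
mode exists), merged into regions. The cutoff is applied per species over
the genome-wide window list, not per chromosome.

Enrichment of sweep bp inside dACR bp is an upper-tail hypergeometric with
population = genome bp, successes = sweep bp, draws = dACR bp. Treating
each bp as an exchangeable unit ignores spatial autocorrelation — sweeps
and dACRs are blocks, not loose bp — so the result carries a caveat field
and `block_permutation_p` offers a placement-permutation robustness check.
The synthetic-data acceptance checks quantify the practical effect: with
top-0.01% selection and dACRs at ~0.2–1% of the genome, random sweep
placement produces p < 0.05 in only a few percent of replicates.

Gene association uses "within 2 kb" of the TSS or TTS measured as the gap
between the interval's nearest edge and the site, inclusive at exactly
2,000 bp, or any overlap of the gene body.

## Annotation

Feature categories use a single-label precedence on any-bp overlap:
upstream (2 kb) > exon > intron > downstream (2 kb) > intergenic. A
precedence is unavoidable once each ACR gets one label; promoter-first
reflects the regulatory weight of promoter-proximal accessibility and is
configurable. The genome-wide background applies the same rule to
non-overlapping tiling windows (10 bp default).

A cytosine counts as methylated when its methylated-read fraction is
≥ τ = 0.5 (configurable). The synthetic methylome emits binary calls, so τ
is inert in tests. The context decomposition (methylated Cs of one context
over *all* Cs) sums to the overall methylated fraction by construction.

TE-superfamily enrichment counts TE *copies* (population = all copies,
draws = ACR-overlapping copies); methylation enrichment counts cytosine
*positions*. Raw p-values at α = 0.05 drive the labels; Bonferroni columns
are emitted alongside but do not change the labels.

## Statistics

Hypergeometric tails and t quantiles are delegated to scipy's log-space
implementations, which are stable at genome-bp population sizes (~4×10⁸).
Both tails are inclusive and satisfy lower(k) + upper(k+1) = 1; tests
verify exact agreement with Fraction-arithmetic enumeration for every
parameter set with N ≤ 12 and Monte-Carlo coverage of the t interval.

## Divergence dating

T(Mya) = Ks/(2r)·10⁻⁶ is only dimensionally coherent with r in
substitutions·site⁻¹·year⁻¹ and T in Mya, which is how it is implemented;
the worked pair (Ks = 0.63, T = 32.81 Mya ⇔ r = 9.6×10⁻⁹) round-trips to
machine precision. Ks estimation itself (alignment, codon models, mixture
peaks) is out of scope; only the closed-form relation is provided.

## The synthetic data generator

The generator emulates a five-species domestication panel: three crops
(*caudatus*, *cruentus*, *hypochondriacus*), the wild ancestor
(*hybridus*) and a second wild relative (*quitensis*); 18 accessions and
42 samples (22 leaf / 20 seedling; every accession has at least a leaf and
a seedling sample) on a 2 × 5 Mb genome with 400 genes (≥ 4 kb apart so
2-kb flanks never collide) and ~2,800 TE copies in 10 superfamilies.

2,000 pan-ACRs are planted with non-overlapping placements (≥ 300 bp apart,
widened when jitter is enabled) in six sharing classes — core 0.48,
species-specific 0.32, domesticate-shared 0.10, wild-specific 0.05,
fixed-open 0.03, fixed-closed 0.02 — proportions in the neighbourhood of
what multi-species ACR panels report (all-species sharing as the largest
single class, ~a third species-specific, fixed differential regions a few
percent). Non-fixed classes *segregate within species*: each nominally open
species has each accession open with probability 0.5, conditioned on ≥ 1
open accession. Fixed classes sit at frequency 1 in their target species
and 0 elsewhere. ACR lengths are right-skewed (150–3,000 bp, mean ≈ 800 bp,
most below 1 kb); oversize outliers (> 4 kb) can be requested to exercise
the length filter.

Per-sample noise: edge jitter (truncated so lengths stay in [50, 4000] bp),
sample dropout (default 0.05; a truly open ACR is missed by one sample),
and false-positive singleton peaks (default expectation 2% of the ACR
count per sample) placed ≥ 1 kb from any true ACR and disjoint from one
another, so the two-sample support rule removes exactly them. Fifty
mappability-artifact intervals are injected into *every* sample and
emitted as the WGS control sets, so control subtraction removes exactly
them. In the noiseless limit (dropout = jitter = false positives = 0) the
full pipeline recovers the planted truth bit-exactly; the acceptance suite
asserts this for the sharing table, state changes, spectra and fixed sets.

The methylome samples cytosine positions at density 0.02/bp, assigns
contexts (CpG 12%, CHG 12%, CHH 76%) and draws binary calls at
per-context rates 75.77 / 41.64 / 5.47% — multiplied by 1.25 inside TEs
(capped at 1) and by 0.1 inside ACRs, reproducing TE hypermethylation and
open-chromatin hypomethylation. Sweep tracks tile the genome in 250 bp
windows with gamma(2,1) background scores; planted sweeps cover half of
each crop's fixed dACRs and score above the background's top-0.01%
quantile plus an elevation margin (default 6).

Every output is a pure function of (config, seed): the root seed spawns an
independent `SeedSequence` sub-stream per output (and per sample file), so
adding an output never perturbs earlier ones and written bundles are
byte-identical across reruns.

**What the generator does not model** — and hence what passing tests do
not show about real data: read-level noise (fragment sizes, Tn5 insertion
bias, duplicate reads), peak-caller behaviour (inputs are taken as already
depth-filtered peak calls), correlated dropout between samples of one
batch, genome sequence (cytosines are placed positionally, not from
dinucleotide content), TE nesting/fragmentation, and linkage between sweep
windows beyond the planted blocks. Scale is also reduced (10 Mb vs a
~435 Mb genome; 2,000 vs tens of thousands of ACRs) to keep the default
test and acceptance runs fast; all rates and filters are scale-free.

## Numerical and degenerate-input choices

- Zero-variance permutation counts give a zero-width CI; an equal observed
  count is labeled "within".
- Empty region/cytosine intersections report "not available" with counts
  rather than NaN arithmetic.
- Sweep-score ties at the cutoff: deterministic ordering wins by default.
- Methylation sites with zero coverage are excluded and counted.
- `k` in top-fraction selection is clamped to [1, n].
- Depth profiles normalize by the window mean and assert mean(output) = 1
  to 1e-12.
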