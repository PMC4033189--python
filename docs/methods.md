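# Methods

## Coordinate and counting conventions

All intervals are BED-convention 0-based half-open, including the
refGene-style annotation (UCSC txStart is already 0-based). A read
"overlaps" a window iff the intersection is at least 1 bp (coverageBed
semantics), and counting is strand-specific throughout the gene-level
analysis because GRO-seq reads carry the transcription strand. Duplicate
reads are counted as given; no deduplication is applied.

For a gene on the + strand with annotation span [txStart, txEnd):

* TSS = txStart; promoter window [TSS−100, TSS+400); body window
  [txStart+1000, txEnd).
* Minus-strand genes are strand-reflected: TSS = txEnd−1, promoter
  [TSS−399, TSS+101), body [txStart, txEnd−1000).
* Genes with span ≤ 1 kb have no body window and are excluded from all
  gene-level tables. Promoter windows that would start before the
  chromosome origin are clipped at 0.

The body window deliberately drops the first kilobase downstream of the
TSS so promoter-proximal polymerase pausing does not inflate gene-body
quantification; fpkm for the body is count / (window kb) / (mapped-read
millions), with the library's total mapped reads as the depth denominator.

## Differential transcription model

Counts K_ij are modelled negative-binomially with mean s_j·q_i and
variance μ + α·μ² — the classic exact-test formulation, reimplemented here
rather than called from R.

**Size factors.** s_j = median over genes of K_ij / g_i, with g_i the
geometric mean of gene i across libraries; genes with a zero geometric
mean are excluded. Note the median-of-ratios estimator is defined only up
to the geometric-mean reference: multiplying one library's counts by c
multiplies its size factor by c relative to the other libraries (a common
factor c^(1/m) is absorbed by the reference). All downstream statistics
are invariant to that common factor.

**Dispersion ("blind", "fit-only").** All libraries are pooled as a single
group regardless of condition. Per gene, q̂ is the mean and w the sample
variance of the normalised counts K_ij/s_j, and the moment estimate is
α_raw = (w − ξ·q̂)/q̂² with ξ = mean_j(1/s_j) removing the expected shot
noise. Genes with non-positive α_raw carry no overdispersion signal and
are excluded from the trend fit. The mean–dispersion trend
α(q) = a₀ + a₁/q is fitted by gamma-family GLM regression with identity
link (the parametric choice; deterministic and dependency-free at fixture
scale, in place of the local regression older implementations defaulted
to). Every gene's working dispersion is the fitted value at its pooled
mean — "fit-only", never the per-gene estimate — floored at 1e−8. When
fewer than two positive moment estimates exist, or the GLM fails, the
model degrades to a constant dispersion (mean/median of the positive
estimates) with a warning. Blind pooling makes the caller conservative
when the tested conditions genuinely differ; that is the intended
behaviour of the reimplemented method and is visible in the planted-truth
tests as near-zero empirical FDR.

**Exact test.** Conditioned on the total T = K_A + K_B with pooled mean
q = T/(s_A+s_B), each condition total is NB with mean s_c·q and variance
μ_c + α·s_c²·q² (equivalently, NB size r = 1/α for both conditions; the
Poisson limit is used when α ≤ 1e−8). The two-sided p-value sums the
probabilities of all splits (a, T−a) no more probable than the observed
one (relative log-tolerance 1e−10 guards float ties), normalised by the
total over all splits. The full support is enumerated for T ≤ 10,000; for
larger totals the enumeration is restricted to a window around the
conditional mode (±10 crude NB standard deviations, widened to always
contain the observed split) that covers all but < 1e−12 of the conditional
mass — the same switch point a normal approximation would use, but
strictly more accurate, and verified in the tests against full
enumeration.

**Calling.** BH step-up adjustment (delegated to statsmodels) and calling
at padj ≤ 0.1. With multi-isoform annotations the isoform with the largest
|log fold change| represents its gene (infinite and zero folds rank above
any finite fold; 0/0 ranks last); fold changes are reported without
pseudocounts, so infinite and zero values are legitimate outputs.

## Pausing and divergence indices

PI = (promoter count / promoter bp) / (body count / body bp), reusing the
−100..+400 and TSS+1kb..end windows so one windowing convention serves the
whole package. PI is undefined (flagged, excluded from rankings) when the
body count is zero. Promoter enrichment is tested one-sided with Fisher's
exact test on [[promoter reads, promoter bp − reads], [body reads, body bp
− reads]]; the table construction is this package's choice (only the test
itself is canonical), and when a window holds more reads than bp the table
is undefined and the p-value reported as NaN while the PI stands.

DI = antisense reads in [TSS−1000, TSS) on the opposite strand / sense
reads in [TSS, TSS+1000) on the gene strand (strand-reflected for minus
genes), so high divergence sorts high. DI is undefined when the sense
count is zero, and genes with fewer than 10 reads total in the two windows
are flagged unrankable. Window size, orientation and the read floor are
exposed as parameters since conventions differ between studies.

## Poisson background activity model

A fixed fraction (default 3%) of each library is taken to be background
distributed uniformly over the genome. For an interval of length L,
λ = background_fraction × total_mapped × L / genome_length and
p = P(Poisson(λ) ≥ N). An interval is called transcriptionally active when
p ≤ α (default 0.01) — i.e. when its read count is improbable under
background. The decision direction is exposed (`active_when`) as a guard
because the convention is easy to invert in prose descriptions; the
default follows the methodology the model derives from (regions are active
when observed reads are improbable under background). `genome_length` is
the summed length of the annotated chromosomes supplied in config; real
analyses should use the effective (mappable) genome size if known.

## Consensus sites and eRNA analysis

Peaks from all experiments are pooled and union-merged with bookended
merging (bedtools default). An experiment supports a merged footprint iff
at least one of its peaks overlaps it by ≥ 1 bp — "found in" is not
otherwise defined, so ≥ 1 bp overlap is this package's choice. Sites with
support ≥ 5 (of 7 by default) are retained.

Each site yields two strand-assigned copies; a copy is dropped iff it
overlaps any annotated gene on the same strand (the unstranded footprint
is retained either way, so a site can survive with one strand). Per
stranded copy and library the package reports the strand-matched count,
fpkm over the footprint length, and the Poisson activity call; a site is
active in a library when either surviving strand is. Fold changes between
two libraries are computed over fpkm only for copies with > 0 reads in
both libraries of that comparison.

Categorisation measures edge-to-edge distance between the site footprint
and gene spans (0 when overlapping): distal when every gene is > 25 kb
away, otherwise proximal-to-target when any target gene is within 25 kb
(targets take precedence over non-targets — the category counts imply
precedence without stating it, so it is made explicit here), otherwise
proximal-to-non-target. The TSS-distance histogram instead measures site
midpoint minus TSS, sign-flipped for minus-strand genes so positive always
means downstream in the reading direction (the axis orientation is this
package's choice); bins are 1 kb within ±25 kb flanked by ten 5-kb bins
per side, and genes whose nearest site lies beyond ±75 kb are dropped.

## Gene-set statistics

Overlap significance is the exact upper-tail hypergeometric probability
P(X ≥ k) computed in log space, so extreme enrichments are reported as a
finite log₁₀ even when the linear p underflows. Basal classification uses
R = (fpkm_A + ε)/(fpkm_B + ε) with a pseudocount ε = 0.1 fpkm stabilising
barely-transcribed genes (ε and both fold thresholds, default 2.0 and the
reciprocal 0.5, are parameters; zero-handling in ratio displays is rarely
stated in the literature, so it is made explicit and configurable here).
Binding enrichment asks whether genes of a set harbor a site footprint
within a radius (default 25 kb, edge-to-edge) more often than the universe
does, with the same hypergeometric tail; the universe defaults to all
annotated genes and should be restricted to the commonly measured set when
comparing across platforms.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, on
one synthetic chromosome ("chrS") by default:

* **Design**: four conditions (wild-type and TF-null, each vehicle and
  treated), n replicates each (default 2), every library exactly
  `reads_per_sample` 50-bp stranded reads (default 10⁶).
* **Genes**: 500 genes of 2–20 kb placed without overlap and with ≥ 3 kb
  gaps on a 50-Mb chromosome; lognormal(0, 1) baselines rescaled into
  expected-read units so genes share the library left over after the
  background and enhancer budgets; 10% of genes induced sixfold, in the
  treated wild-type condition only.
* **Read placement within a gene** realises the planted pausing ratio r
  and divergence ratio d exactly in expectation: sense reads fall in the
  promoter region at r times the density of the rest of the gene, and
  antisense reads fall uniformly in the 1 kb upstream of the TSS with
  total weight d × (expected sense reads in the 1 kb downstream).
  Pausing ratios are log-uniform on [1, 40] and divergence ratios
  log-uniform on [0.05, 2].
* **Noise**: one gamma(1/α, α) factor per gene per library multiplies all
  of the gene's components, and the whole library is drawn as a single
  multinomial over every source, so per-gene counts are negative-binomial
  with variance μ + αμ² (the differential caller's model, making
  parameter recovery well-posed) while the library size stays exact and
  the planted within-gene ratios are undisturbed. α = 0 gives the Poisson
  limit.
* **Background**: the background weight is set per library so its expected
  share is exactly `background_fraction` (default 3%) whatever the signal
  total; background reads are uniform over the genome on random strands.
* **Enhancers**: 200 sites of 600 bp in intergenic space (≥ 2 kb from any
  gene span, clear of divergence-window read spill); a fraction (default
  20%) is deliberately placed 5–20 kb from an induced gene. Active sites
  (30% of ordinary sites, 80% of target-proximal ones — the pre-activated
  contrast) emit reads symmetrically on both strands within the footprint
  at a mean of `erna_reads_per_active_site` (default 100) per strand per
  library.
* **Peak experiments**: 7 experiments; each true site appears with
  probability 0.85 with ±50 bp boundary jitter, plus Poisson(20) false
  peaks per experiment. At these rates a true site reaches the 5-of-7
  consensus with probability ≈ 0.93, so the consensus stage has realistic
  dropout to contend with.

What the generator does **not** emulate: mappability and GC bias,
read-quality structure, duplicate artefacts, transcript isoform structure
(single-span genes only), multi-chromosome genomes by default, enhancer
transcription responding to treatment, and genuine biological covariance
between pausing, divergence and induction (they are planted
independently — which is what makes the no-correlation checks meaningful).
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to artefacts real
libraries can contain.

## Problem sizes and numerical choices

The standard fixture (500 genes × 8 libraries × 10⁶ reads, 200 sites,
7 peak experiments) is the package's documented reference scale: large
enough for the planted fold-6 genes to be recovered at ≥ 90% sensitivity
with ≤ 10% empirical FDR and for pausing/divergence medians to land within
a few percent of truth, small enough to simulate and analyse in seconds.
Published catalogue-scale numbers that are pure bookkeeping (the
stranded-record count at 106,600 sites) are exercised at full size; counts
that derive from ~10⁸-read libraries are exercised at fixture scale
against planted truth instead.

Tolerances and tie-breaks: dispersion floor 1e−8; exact-test probability
tie tolerance 1e−10 in log space; windowed enumeration above totals of
10,000 (coverage < 1e−12 mass deficit); closest-interval ties break to the
leftmost subject start; a query chromosome with no subjects yields an
infinite distance (treated as maximally distal) rather than an error;
empty annotation in site categorisation warns and returns all-distal.

## Known limitations

* The dispersion trend is parametric (a₀ + a₁/q) rather than the local
  regression of the original R implementation; per-gene p-values can
  differ slightly from that implementation even on identical input.
* The Fisher table for promoter enrichment (reads vs remaining bp) becomes
  undefined at extreme depth (more reads than bp in a window).
* Activity calls treat libraries independently; no multiple-testing
  correction is applied across sites (matching the method it implements).
* The CLI's `de` step compares exactly one condition pair per run.
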