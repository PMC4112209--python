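# Methods

This note documents the models, estimators and design choices behind
`tepop`, and what the synthetic experiments do and do not demonstrate.

## Detection model

An insertion segregating in a sample but absent from the reference produces
read pairs straddling the junction: one mate maps uniquely to the
(repeat-masked) genome, the other maps to a TE library sequence. The
classifier emits:

* **supporting** evidence — one mate unique-genomic, one mate on a TE. The
  genomic mate's proximal end (its 3′ coordinate on the forward strand, 5′ on
  the reverse) and strand define the evidence position and side: a
  forward-strand genomic mate sits upstream of the junction, a
  reverse-strand mate downstream.
* **spanning** evidence — both mates unique-genomic, forward-reverse inward
  on one chromosome, outer insert within mean ± 3 SD. The inner span (between
  the mates' footprints) is retained.
* everything else (both mates on TEs, any multi-mapped genomic mate,
  discordant pairs) is dropped. For externally supplied SAM, "unique" means
  MAPQ ≥ 20 and neither secondary nor supplementary; the built-in exact
  matcher assigns MAPQ 60 to reads with exactly one full-length exact match
  and MAPQ 0 otherwise. A mate on a TE sequence is accepted as the TE side
  regardless of its MAPQ — multi-mapping within a TE family is expected and
  carries family information either way.

Clustering is greedy left-to-right chaining of same-chromosome, same-family,
same-side evidence after a position sort: an item joins the open cluster if
it lies within the cluster window (insert mean + 3 SD, default 505 bp) of the
last member. On sorted positions this equals the transitive closure of the
pairwise within-window relation (verified against a brute-force union-find
oracle). A forward and a reverse cluster whose innermost positions are
within the window (nearest gap first) merge into one observation at the
midpoint; single-sided clusters reaching `min_support` (default 2) are kept,
flagged lower-confidence, at their innermost position.

### Frequency estimate

The per-side primitive is `f = supporting / (supporting + spanning)`, with
spanning pairs counted only when their inner span strictly contains the
position estimate. An observation's frequency is the **mean of the two
per-side ratios** (the single ratio for one-sided detections). The mean is
used rather than pooling both sides into one ratio because the supporting
window exists on *both* sides of the junction while a spanning pair opposes
the insertion only once: pooling makes the heterozygote expectation 2/3
instead of 1/2 regardless of insert size. With per-side averaging,
heterozygous sites at 20× concentrate at 0.53 ± 0.11 and homozygous sites at
1.0 in simulation, which is what the 0.2/0.8 genotype thresholds assume.

### Masked-region exclusion

The reference genome carries masked (N) TE copies of its own. Reads from
those copies in any individual generate junction-like evidence at the mask
boundaries that describes the *reference* TE, not a polymorphic insertion;
calling reference copies is out of scope. Supporting evidence whose genomic
position falls within one cluster window of a masked span is therefore
excluded before clustering. The site simulator keeps true sites ≥ 1 kb from
masked spans so this filter cannot swallow genuine signal.

## Genotyping and merging

Frequencies > 0.8 are homozygous, < 0.2 are treated as detection errors
(absent), intermediate values heterozygous; the boundary values 0.2 and 0.8
fall in the heterozygous band because the outer rules are strict
inequalities. Error-band observations are dropped *before* cross-sample
merging — they never seed a site, but a sample can still be recorded absent
at a site formed by other samples.

Observations within 200 bp (transitive chaining; an anchor-based variant is
available via `method="anchor"`) on the same chromosome are merged into one
site. Merging additionally requires the same TE family — the field default
of position-only merging can chimerize co-located insertions of different
families; a flag disables the requirement. The consensus coordinate is the
floor of the mean of member positions (merged sites have no span of their
own, so all downstream distance and compartment logic uses this point).
When one sample contributes several member observations, its genotype comes
from the best-supported one.

## Population summaries

* **Copy number** is presence-based (heterozygous and homozygous calls each
  count one site), matching insertion-count semantics; `dosage=True` counts
  homozygotes twice. Compartments (arms vs pericentromere) partition the
  genome, so stratified counts sum exactly to the genome-wide count.
* **Population frequency**: selfers — carriers / individuals, any non-absent
  call counting as a carrier (selfed individuals are effectively homozygous,
  so a nominally heterozygous call is still presence); outcrossers — each
  haplotype an independent sample, (2·hom + het) / (2n). Frequency
  calculations can be restricted to a seeded subsample (defaults 8
  individuals per selfing species, 4 for the outcrosser) to equalize the
  number of sampled haplotypes across species.
* **Spectra**: proportions over right-closed bins spanning (0, 1] (default
  deciles; frequency-1 sites land in the top bin, and `include_fixed=False`
  drops them first). CIs are percentile bootstrap over *sites* (200
  replicates, 95%): resampling individuals would perturb the frequencies
  themselves, and with many sites the site-resampling CIs are narrow, which
  is the regime the method targets. Bands are clamped to contain the point
  estimate.
* **Distance to genes**: gap from the site's consensus position to the
  nearer edge of the closest gene, 0 inside a gene, undefined on gene-less
  chromosomes; per-individual counts in half-open 100-bp bins, reported as
  mean ± SE across individuals.

## Statistical comparisons

Kruskal-Wallis (tie-corrected H, χ² p), Mann-Whitney (U = #{(a,b): a > b} +
half-ties, tie-corrected normal approximation with continuity), Wilcoxon
signed rank (V = sum of positive-difference ranks after dropping zeros;
tie-corrected normal approximation with continuity correction), and a
log-link Poisson GLM on a categorical predictor (Wald z per group vs the
first group in sorted order; an all-zero group is flagged with a −∞
coefficient rather than fitted). The paired unit for the signed-rank
comparison in the pipeline is the per-species mean copy indicator over
shared 1-kb windows, declared in the output metadata. No multiple-testing
correction is applied anywhere.

## Synthetic data generator

What it emulates: a small repeat-masked reference (uniform-random
background; centred pericentromere covering 20% of each chromosome; genes
only on the arms; a few verbatim TE copies planted in the pericentromere and
masked to N), a TE library of four families ≥ 400 bp each, three populations
over a shared site pool (TE sites ≥ 500 bp apart, enriched ~3× in
pericentromeres, family mix 59/19/11/11% LTR/DNA/Helitron/non-LTR), and
paired 108-bp reads (insert 430 ± 25 bp — a typical paired-end library for
that read length; pair count Poisson around coverage·G/(2·read length);
constant quality strings). Selfers carry a site with probability equal to
its frequency, always homozygous; outcrossers draw two haplotypes
independently (Hardy-Weinberg). The three default species profiles differ in
site occupancy and frequency shape: an outcrosser with many rare insertions
(Beta(0.6, 1.8), occupancy 0.80), a young selfer with an excess of rare
insertions and the highest abundance (Beta(0.5, 1.0), occupancy 0.95), and
an older selfer with few but common/fixed insertions (Beta(1.8, 0.6),
occupancy 0.30).

What it does **not** emulate: sequencing errors by default (an error rate
parameter exists), indels, within-family TE divergence (a per-copy mutation
rate parameter exists, default 0), nested or truncated insertions,
target-site duplications, SNPs between individuals, or non-uniform genome
composition. Passing tests therefore demonstrate the *logic* of the chain —
evidence classification, clustering, thresholds, merging, estimators — under
clean mappability, not robustness to alignment noise in real genomes; with
real data the alignment step should come from a full read aligner, supplied
as SAM.

## Experimental design of the self-checks

* **Hybrid check**: two fully homozygous parents with partially disjoint
  site sets; detection on each parent and on their read merge. Expected:
  pure samples concentrated at frequency 1, the merge shifted toward 0.5 at
  sites homozygous in exactly one parent (which converge to 0.5 as coverage
  grows). Replicated on 120-kb genomes at 30×.
* **Pooled vs individual**: the pooled copy-number statistic is the sum of
  pooled insertion-frequency estimates (expected insertions per individual)
  — the pooled analogue of the per-individual mean; the count of distinct
  pooled sites is *not* comparable, since it grows with the number of
  segregating rare sites.
* **Reference swap**: detection re-run against a genome with 1% random
  substitutions (exact matching then loses ~66% of reads and ~89% of pairs,
  so absolute counts drop). The ordering to preserve is the simulated design
  ordering of three species with clearly distinct abundance (site occupancy
  0.30/0.60/0.95): with nearly-tied species, "ordering preserved" would be
  decided by noise rather than by reference bias.
* **Calibration**: type-I error of each test under its null (normal or
  Poisson samples, 2,000 replicates, α = 0.05); ordering power with
  low/mid/high Poisson copy-number means (10/15/20) at the study's group
  sizes (10/8/24); bootstrap-CI coverage against a fixed known 10-bin
  multinomial with 400 sites per replicate.

## Problem sizes and numerics

The acceptance experiments use a 500-kb genome, 50 true sites and 3 × 8
individuals at 20× (the detection run takes ~20 s; the full acceptance
suite ~1 minute on one CPU); unit tests use 60–150-kb genomes. All
randomness flows from one root seed through named substreams
(`subseed(seed, name)`), so results are independent of execution order and
reruns are byte-identical. Positions are 0-based half-open internally;
GFF3 is written 1-based closed, BED 0-based half-open, SAM 1-based.
Cluster pairing is nearest-gap-first; site ids are assigned after a final
(chromosome, position, family) sort; merge ties are broken by sample id and
support so output never depends on input order.

## Known limitations

The built-in matcher is exact and intended for the simulator's error-free
reads and for unit-scale fixtures; real data must be aligned externally.
Reference TE copies are masked out rather than genotyped (no absence
calling). Genotype calling is threshold-based, not likelihood-based, and
inherits the assumption that ~20× coverage gives stable
frequency estimates; at much lower coverage the 0.2/0.8 thresholds will
misclassify more heterozygotes. The Venn/sharing counts and family shares
of the synthetic demo reflect the simulator's profile defaults, not any real
species.
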