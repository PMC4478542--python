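# Methods

This note documents the models behind `seedgwas`: what the synthetic panels
emulate and deliberately leave out, how the mixed-model scan and the exact
tests are computed, the numerical choices, and the open design decisions we
resolved.

## The synthetic panel

The generator (`seedgwas.simulate`) emulates a crop diversity panel of the
sorghum-association-panel type: a few hundred highly inbred accessions in a
small number of ancestry groups, genotyped at SNPs whose LD is organised into
haplotype blocks, with much longer blocks in recombination-poor
pericentromeric regions.

**Genome and markers.** Chromosome count and length, SNP count, and block
length are configurable. The packaged study conditions
(`sap_like_config`) use 354 accessions, three subpopulations, two 15-Mb
chromosomes and 11,000 SNPs — one SNP per ~2.7 kb, matching the density of a
~265k-SNP panel on a 730-Mb genome — with 150-kb blocks stretched 10× over
the middle 40% of each chromosome (the pericentromeric span; both factor and
span are configurable).

**Arc-haplotype blocks.** Per block and subpopulation the generator draws
2–8 founder haplotypes. The (subpopulation, founder) slots are arranged on a
line — interleaved across subpopulations for ancestry-balanced variation, or
subpopulation-contiguous (with probability equal to the divergence parameter)
for ancestry-aligned variation — and every *tag* SNP (80% of SNPs by default)
marks a contiguous arc of that line: the block's *anchor arc* (its major
haplotype split, 40% of tags), a *recombinant derivative* of the anchor with
end points shifted by up to ~55% of its length (40%), or a random arc (20%),
plus a small per-founder mutation rate (up to 5%). Identical arcs give
r² ≈ 1, partially overlapping arcs a continuum of intermediate r² — the
graded, nested LD of real blocks. Non-tag SNPs segregate independently at
Balding–Nichols subpopulation frequencies derived from a uniform ancestral
spectrum, so allele-frequency divergence between groups grows with the
divergence parameter through both routes. Accessions inherit two founder
chains block-wise; with probability 0.05 a chain carries its founder index
into the next block (a weak between-block continuity; blocks are otherwise
independent given subpopulation).

**Inbreeding.** Residual heterozygotes collapse to a homozygote per locus
with probability `inbreeding_rate` (default 0.98), but the *direction* of
collapse is drawn once per accession and block: selfing fixes one haplotype,
and a per-locus random direction would destroy within-block LD. With
`inbreeding_rate = 1` genotypes are exactly {0, 2}.

**MAF floor.** SNPs drifting below `maf_floor` (default 0.05, the usual GBS
filter) are redrawn at the founder level (bounded retries) and, as a last
resort, minor-allele homozygotes are injected, so the floor holds exactly
after generation. A floor of 0.5 or more is rejected as infeasible.

**Planted QTL.** Each planted locus (chromosome, position, effect, allele
frequency) is resolved to the nearest SNP (an error if none lies within half
a block length). Its block is generated with the anchor arc sized to the
requested frequency and the causal column is the anchor-arc indicator
itself, mutation-free — a causal variant riding the block's major haplotype,
surrounded by graded LD. The realized frequency is the usage-weighted anchor
frequency and can differ from the request by a few percent.

**Phenotypes.** Trait values are additive: planted effects × minor-allele
counts, an optional polygenic term (small effects on a random SNP subset,
scaled to a requested variance), optional subpopulation intercepts (for
structured-null experiments), and environment-specific Gaussian noise. The
noise scale is set from the realized genetic variance so that the
broad-sense repeatability across environments equals `target_h2` exactly in
expectation; per-environment multipliers skew noise across environments.
`target_h2 = 1` with several noisy environments is rejected as
contradictory.

**Ortholog maps.** Collinear gene pairs between two genomes are generated in
runs assigned cyclically to chromosome pairs, with optional run inversions
(rank order reversed in genome B) and a per-gene loss rate (the gene lacks a
partner). Planted blocks place a chosen number of genes inside designated
intervals of both genomes — the positive control for correspondence tests.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: genotyping error and missing-call structure
(missingness is optional and independent), linked selection and admixture
gradients, allele-frequency spectra from real demography (the spectrum here
is uniform-ish by construction), epistasis and genotype×environment effect
changes (environments share effects and differ only in noise), and any
sequence-level realism. The panel reproduces the *statistical geometry* the
pipeline depends on — structure, block LD, modest-effect architecture —
not the biology underneath it.

## Population structure and trait statistics

Genotype PCA centres each SNP and scales by the expected binomial standard
deviation √(2·maf·(1−maf)) (the standard genotype-PCA normalisation; the
choice is configurable only by pre-transforming the matrix). Missing calls
are mean-imputed inside PCA and kinship only, never persisted. Signs are
fixed by making each component's largest-magnitude loading positive. K-means
uses the first two components and k = 3 by default, best of `n_restarts`
initialisations, with clusters relabelled by ascending centroid on the first
axis so labels are deterministic.

Group trait differentiation uses two-sided Welch t-tests for every group
pair (the unequal-variance form is the robust default; Student's form is a
flag), flagged at p ≤ 10⁻⁴. Pairs with under two observations in a group are
reported missing; two identical constant groups report p = 1.

Repeatability (broad-sense H) comes from a one-way random-effects ANOVA on
accession across environments: H = σ²ₐ/(σ²ₐ + σ²ₑ) with the unequal-n
coefficient k₀ = (N − Σn²ᵢ/N)/(a − 1) and negative components clamped to
zero, so H ∈ [0, 1]. The estimator is invariant to shifting and rescaling
the trait.

## The mixed-model scan

Kinship is VanRaden's marker matrix: K = WW′ / Σ2p(1−p) with W the
mean-centred dosage matrix. The scan model per marker is

    y = μ + PCs·α + g·β + u + e,  u ~ N(0, K σ²_g),  e ~ N(0, I σ²_e).

Variance components are estimated by REML through the spectral decomposition
of K under the null (no-marker) model — the likelihood is profiled over
γ = σ²_g/σ²_e on a log grid with a bounded polish and an explicit γ → 0
boundary check — and reused for every marker (the
population-parameters-previously-determined shortcut; exact per-marker REML
is a config switch for small data). Each marker then gets a
generalized-least-squares Wald t-test of β = 0 with n − p − 1 degrees of
freedom, computed by residualising the rotated genotype and trait against
the rotated fixed effects. With K = I the weights are constant and every
p-value equals the ordinary-regression p-value exactly; the same holds
whenever γ̂ = 0.

Compression (the CMLM device) clusters accessions by average linkage on the
kinship-induced squared distance, replaces K by Z K_group Z′ (group-mean
kinship expanded by the incidence matrix) and proceeds identically; with as
many groups as accessions it reproduces the uncompressed scan, and `"auto"`
scans {1, 2, 4, …, n} group counts keeping the null-REML maximiser.
Non-positive-semidefinite kinship is shrunk toward its diagonal until the
smallest eigenvalue clears −10⁻⁸, with a logged weight.

SNPs failing the MAF filter (default 0.05 — rare variants are underpowered
in association panels) or the missingness filter (default 0.2) are excluded
from output; markers collinear with the fixed effects get a missing p-value.
Missing genotype calls are mean-imputed per marker inside the scan.

PVE of a peak-SNP set is the joint ordinary-least-squares R² of the trait on
the listed allele counts, with collinear columns dropped and the effective
count reported.

## LD and thresholds

r² is the composite (genotype-correlation) measure: the squared Pearson
correlation of dosage vectors over accessions called at both SNPs. For
highly inbred unphased material this tracks haplotype r² without phasing,
and it is the measure used consistently by the hotspot caller. Decay curves
average r² (median by option) in distance bins over up to 200,000 sampled
intra-chromosomal pairs (seeded); the extent is the upper edge of the first
bin whose summary drops below the background level (default 0.1), censored
when no bin does. Note the genome-wide extent of the packaged panel exceeds
the euchromatic block length because pericentromeric blocks are 10× longer.

Two thresholds: Bonferroni α/N, and the LD-bin correction α/(G/L) with G the
genome size and L the average LD extent; the effective test count G/L is
kept real-valued (4,866.67 for 730 Mb / 150 kb) before dividing. A helper
reports the nearest power of ten of a cutoff. For the quoted panel the
Bonferroni quotient is 1.8833×10⁻⁷ (often quoted rounded as 1.89×10⁻⁷) and
the LD-bin cutoff 1.03×10⁻⁵ ≈ 10⁻⁵.

## Hotspots, anchoring and interval algebra

A hotspot grows from a seed SNP with p ≤ 10⁻⁵: minor significant SNPs
(10⁻⁵ < p ≤ 10⁻³) on the same chromosome within 2 Mb (configurable) and with
r² ≥ 0.5 *to the seed* are collected, and the seed emits a hotspot when it
gathers at least 10. Both thresholds are inclusive, r² is seed-to-minor
(minor-to-minor chaining is deliberately not the default; the rule is
seed-centric), and the boundary is exactly the span of seed ∪ linked minors
— no padding. Seeds sharing a linked minor or overlapping spans merge into
one hotspot (union of members); hotspots are called genome-wide, not only
inside known QTL intervals. The implementation is tested for exact set
equality against a quadratic brute-force enumeration.

QTL likelihood intervals are anchored to physical coordinates by scanning
outward from the likelihood-peak marker in genetic order and taking on each
side the first marker with alignment information; the aligned peak itself
may serve as a bound when a side has none, and a side with no aligned marker
at all yields a one-sided interval extended to the chromosome end. Aligned
flankers on different chromosomes are a hard "discordant anchoring" error.

All coordinates are 1-based inclusive internally (genome-browser style);
only BED I/O converts. Interval merging unions same-chromosome intervals
sharing at least one base — touching-but-disjoint intervals stay separate —
and is idempotent. The refinement ratio is the QTL length over the
co-localized hotspot length.

## Exact enrichment tests

`fisher_exact` enumerates the hypergeometric support with the margins fixed.
For table totals up to 50,000 (every use in this package) the enumeration
uses exact big-integer weights with correctly-rounded float division; above
that it switches to log-space `gammaln` sums. One-sided p is P(A ≥ a) in the
enrichment direction; two-sided p sums all outcomes no more likely than the
observed table (the point-probability convention). Degenerate margins give
p = 1 with a flag; the odds ratio is ad/bc with ∞/undefined flags.

Because the test is discrete, the raw p-value is conservative under the
null; calibration checks therefore use the standard randomized transform
U = P(A > a) + V·P(A = a) (V uniform), which is exactly U(0, 1) under the
null, alongside a one-sided check that the raw p's empirical CDF never
exceeds the uniform by more than a KS band.

The three constructions: (1) within-genome — every SNP that survived the
scan's filters (only tested loci can be association loci) is classified by
significance at 10⁻⁵ and by position inside the merged QTL intervals;
(2) cross-taxa, gene-based — collinear ortholog pairs restricted to one
orthologous chromosome pair, classified by membership of the A gene in the
association region and of the B gene in any merged B interval, with gene
membership decided by midpoint containment (span-overlap is a flag; midpoint
avoids double-counting boundary-straddling genes); (3) cross-taxa,
interval-based — each A interval is projected through the ortholog pairs it
contains (span of their B midpoints on the modal B chromosome) and called
corresponding when the projection overlaps a merged B interval, with the
within/outside split compared against the chance coverage of the projected
gene universe. Batteries of correspondence tests report Benjamini–Hochberg
FDR alongside raw p-values.

## Problem sizes and reproducibility

All randomness flows from named `numpy.random.Generator` streams seeded from
a single integer; same seed, same bytes. The packaged study conditions run
at desk scale: 354 × 11,000 genotypes, 2,000-SNP null panels, 10–20
replicates for recovery and calibration experiments — sizes chosen so the
full analysis reruns in minutes while keeping the estimators in the regimes
the pipeline targets (three-peak PVE near 0.54, repeatability near 0.31,
seeds in the 10⁻⁶–10⁻⁸ range where the hotspot rule is informative).

## Known limitations

Hotspot yield in a single scan at modest planted effects is ~50–60% per run
(and ~75% pooling three environments): when a peak is very strong, all its
r² ≥ 0.5 partners are themselves seeds and the minor band empties — a real
property of the rule, visible here because the synthetic architecture is
fixed. The LD-bin threshold takes the genome size and LD extent verbatim as
inputs. The qtl–qtl correspondence construction assumes each A interval
projects to essentially one B chromosome. The compression search is a simple
doubling grid, not an exhaustive optimisation.
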