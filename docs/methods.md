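# Methods

## Scope and model

`rohaudit` audits ROH islands for technical artefacts. Its inputs are
SNP-array genotypes (PLINK text), per-sample CNV call tables from two
external callers, and phased haplotypes; CNV calling itself (HMM or
segmentation on BAF/LRR) and phasing are external-tool territory and are
consumed, never recomputed. The package's own content is everything
downstream: ROH detection, island calling, CNVR construction, coverage
gaps, artefact classification, the permutation overlap test and
haplotype-block diversity.

All internal coordinates are 0-based half-open (BED convention); PLINK
map positions and CNV-call tables are converted at the I/O boundary, the
single place where conventions meet. A marker at 1-based position p
occupies [p−1, p), so a 1-based inclusive span [s, e] becomes [s−1, e)
and keeps its conventional length e − s + 1.

## ROH detection

For each individual, chromosome and length class, the detector returns
every *maximal* marker window whose heterozygote and missing counts stay
within the class allowances — maximal meaning extendable in neither
direction without a violation. Windows are trimmed so both end markers
are homozygous non-missing calls (heterozygous or missing flanks would
otherwise inflate spans and make maximality ambiguous), and the base-pair
span (last − first marker position + 1) must fall inside the class
bounds. Defaults are the five classes 1–2, 2–4, 4–8, 8–16 and >16 Mb
with heterozygote allowances 1, 2, 4, 8, 16 and missing allowances 4, 8,
16, 32, 64. The scan is O(n) per class via cumulative counts and a
vectorized right-boundary computation; a brute-force all-windows oracle
in the test suite certifies it on random fixtures. Class membership is
decided pre-merge; class calls are then unioned per individual
(book-ended runs coalesced). F_ROH divides the merged total by a genome
length — the bovine autosomal constant 2,511 Mb is exported for
real-chip runs, while pipeline runs on arbitrary maps default to the sum
of observed chromosome spans.

An alternative published approach detects ROH by genotype clustering;
this package deliberately replaces it with the deterministic
maximal-window scan above, because the audit's contribution lies
downstream of ROH calling and the allowance table is the reproducible
part of the upstream method.

## Quality control

Filter order is fixed: (1) samples by missing fraction (>0.10) / call
rate (<0.90), (2) markers by missing fraction (>0.05), (3) markers by a
1-df chi-square Hardy–Weinberg test (p < 0.001). The published
thresholds do not state which entity each applies to; the reading here
(sample filters first, PLINK's mind-then-geno convention) is recorded in
the report header. The chi-square test (not an exact test) was chosen
because it is closed-form and oracle-checkable; monomorphic markers
return p = 1.

## Islands

The per-marker inbreeding level is the proportion of individuals whose
merged ROH cover the marker. The island cutoff is the 99th percentile of
the genome-wide level distribution, computed as a type-7
(linear-interpolation) quantile — the single quantile convention used
throughout the package. Islands are maximal runs of consecutive markers
with level strictly above the cutoff ("passed" the percentile); runs
below `min_markers = 2` are discarded and sub-threshold markers are never
bridged. Both choices are exposed in the configuration.

## CNV regions

Only loss (−1) and gain (+1) calls exist as objects; copy-neutral
segments are never stored. A three-state discretization of segmentation
means at |mean| ≥ 0.3 (inclusive, so the printed threshold itself is
called) is provided for callers that emit means. Cleaning merges
same-sample, same-state neighbours whose gap is shorter than 20% of
their combined length, iterated to a fixed point because a merged,
longer call can absorb further neighbours. Outlier samples are excluded
when their call count exceeds the Tukey fence Q3 + 1.5×IQR (type-7
quartiles); with fewer than four samples the fence is undefined and the
filter passes through with a warning. CNVRs are single-linkage merges of
calls sharing ≥1 bp (book-ended calls stay separate), across samples and
states, labelled gain/loss when one state contributed and both
otherwise; merging across states before labelling is what allows "both"
regions to exist. Consensus regions are pairwise base-pair intersections
of two callers' CNVR sets; when the parents disagree (or either is
"both") the intersection is labelled both.

## Coverage gaps

Intermarker distances are computed per chromosome on the raw chip map.
The gap fence is the Tukey upper bound of the genome-wide distance
distribution; for the real BovineHD map the published value 9.2365 kb is
kept as a documented default constant, since the chip map is not shipped
here. A gap is the marker-free stretch [p, q−1) between a consecutive
pair at distance q − p above the fence. Islands with mean internal IMD
above the fence are flagged even without a mapped gap; an island with
fewer than two markers cannot have a mean IMD and conservatively fails
the check with a warning.

Gaps and mean IMD are derived from the raw (pre-QC) map by default, with
the post-QC map behind a flag. Coverage structure is a property of the
chip design: on a near-uniform map the Tukey fence sits just above the
largest designed spacing, so any QC-dropped marker would otherwise
manufacture a phantom gap at its position and misclassify clean islands.

## Artefact classification and the permutation test

An island's flags are: `loss` / `gain` when it overlaps a CNVR carrying
that state (a "both" region sets both flags), `gap` when it overlaps a
gap interval or its mean IMD exceeds the fence. The artefact verdict is
gap OR loss: deletions mistyped as homozygous and marker-free stretches
both manufacture spurious homozygosity, whereas a copy gain leaves
genotypes diploid-like and does not (a `gain_as_artefact` switch is
provided for the conservative reading, since mistyping can reappear at
very high copy numbers). The coverage summary reports per-label island
counts, summed lengths and percentages of total island coverage, plus an
overall affected row.

The permutation test re-places each chromosome's islands uniformly at
random — island count, lengths and chromosome assignment preserved, all
same-chromosome gaps >1 Mb, by rejection sampling with a budget of
10,000 redraws — and intersects each replicate with the CNVR set
(default: loss and both categories of the consensus set; per-caller runs
via configuration). 10,000 replicates are the default. Besides the
one-sample t-test of H0: mean(ROHR) = ROHD, the empirical p-value
(1 + #{ROHR ≥ ROHD}) / (1 + n) is always reported, because a t-test
against 10,000 replicates of a strongly enriched statistic is degenerate
(p underflows to 0). Placement and intersection are vectorized across
replicates (sorted-start spacing check; cumulative-coverage
interpolation), so the full test runs in well under a second.

## Haplotype diversity

Each island is tiled into consecutive 100-kb blocks from its start; a
tile (including the trailing partial one) is kept only if it contains at
least two markers. Within a block every phased chromosome copy
contributes one haplotype string; copies with missing alleles are
excluded from that block's denominator. From the frequency vector p:
effective number of haplotypes = 1/Σp², expected block heterozygosity
H = 1 − Σp² (so H = 1 − 1/effective_n identically). Category and breed
effects on block statistics are compared by a two-way fixed-effects
ANOVA without interaction (statsmodels OLS + type-II anova); factors
with one level are dropped and recorded, and a zero-variance response
returns p = 1. A Kruskal–Wallis alternative is available for skewed
block statistics. Blocks are island-anchored tiles, not LD-defined
blocks: 100 kb is a conservative upper bound on reported haplotype-block
sizes in cattle. "Markers per block" is reported as the SNP count of the
tile, not per distinct haplotype.

## Synthetic data

The generator produces the complete input set — genotypes, phased
haplotypes, two CNV call files, intensities, truth BED files — for a
study whose ground truth is known:

- **Background**: independent loci in HWE, allele frequencies uniform on
  (0.35, 0.65) — SNP arrays ascertain common variants, and mid-range
  frequencies keep planted structure visible to the HWE filter at its
  nominal false-positive rate. No linkage disequilibrium is simulated:
  the audit statistics depend on planted structure only.
- **Islands**: a shared haplotype (the per-marker major alleles) carried
  by each chromosome copy independently with probability h. Homozygous
  carriers arise at h² (default `island_carrier_fraction = 0.42`, in the
  range of published island cutoffs), and island markers remain exactly
  in HWE because genotypes are random unions of haplotypes.
- **Deletion mistyping**: deletion carriers (default 30% of samples) are
  *recorded* homozygous for their remaining haplotype across the region,
  while the stored phased haplotypes keep the true diploid alleles —
  exactly the mechanism that creates false ROH with high block
  diversity. Intensities for these markers follow the one-copy emission.
- **Walls**: each planted island is flanked by five markers heterozygous
  in every carrier (plus fill samples to an overall heterozygote
  fraction of 0.734, which passes the HWE filter: chi² = 6.5, p ≈ 0.011
  at n = 30). They emulate the polymorphic flanks that terminate real
  ROH; without them the heterozygote allowances let detected ROH leak a
  few markers past the island edge, and planted truth would only be
  recoverable approximately.
- **Gaps**: marker-free stretches (default 250 kb) carved out of a
  planted island, far above the fence.
- **Callers**: caller A drops each truth call with probability 0.1;
  caller B with probability 0.2 and ±2-marker boundary jitter, so the
  consensus logic is genuinely exercised (consensus ⊂ each caller).
- **Intensity emission**: LRR ~ Normal(mu_state, 0.15) with
  mu = (−3.5, −0.55, 0, +0.35, +0.65) for copy states 0–4 — ordered and
  separated by ≥2 sd, the qualitative pattern of array intensities — and
  BAF centred at state-dependent cluster positions (uniform for a double
  deletion, extremes for hemizygous, {0, ½, 1} for diploid,
  {0, ⅓, ⅔, 1} for three copies) with sd 0.03, truncated to [0, 1].

**Default scale.** 3 chromosomes × 160 Mb (cattle-sized autosomes) at ~1
marker/5 kb (~96,000 markers), 30 samples, four planted islands — one
per label: clean, gain-affected, gap artefact, loss artefact — plus five
scattered sub-megabase CNVs. Two constraints fix this geometry. Islands
must span >1 Mb to be detectable by the smallest ROH class, and the
total island extent must stay below 1% of the map so that the
99th-percentile cutoff falls in the background of the level distribution
(otherwise the cutoff lands inside the island levels themselves and the
strict ">" rule truncates them). Four 1.1–1.3-Mb islands therefore need
a ≈480-Mb genome. Off-island CNVs are kept shorter than 1 Mb so their
mistyped runs never reach the smallest ROH class. The whole study
simulates and audits in ~10 s on one core.

**What the defaults do not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and background
autozygosity (real level tracks have a continuous nonzero background, so
real cutoffs are 17–46%, not 0), genotyping error beyond deletion
mistyping, overlapping or nested CNVs of mixed states at the same locus,
phasing error (haplotypes are born phased), and chip-design artefacts
other than coverage gaps.

## Numerical conventions and degenerate inputs

Type-7 quantiles everywhere a quartile or percentile is named; strict
">" at the island cutoff; inclusive "≥" at the segmentation-mean
threshold; book-ended intervals coalesced in ROH merging but *not* in
CNVR construction (≥1 bp overlap required); empirical p-values use the
add-one form. Empty results propagate as empty sections, not errors: a
dataset with no islands produces an empty audit and no permutation
section. All randomness flows through numpy Generators seeded from the
configuration; identical configuration and seed reproduce reports
byte-for-byte.

## Known limitations

- The window-scan ROH detector is not the clustering algorithm some
  commercial suites implement; results agree only insofar as the
  allowance parameterization dominates.
- The permutation null randomizes islands but conditions on the observed
  CNVR set; enrichment statements are therefore one-sided in that
  direction.
- Consensus support counts take the smaller parent's support; per-sample
  consensus bookkeeping would require call-level (not region-level)
  intersection.
- The diversity ANOVA treats blocks as independent observations, as the
  block design intends; within-island correlation is not modelled.
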