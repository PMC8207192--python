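# Methods

This note documents the statistical model, the tunable parameters, the
simulator's scope, and the numerical and design choices behind `m2seq`.

## Model and assumptions

The package maps a recessive, fully penetrant causal mutation segregating in
a selfed M2 population by comparing pooled allele frequencies between a
mutant-phenotype bulk and a wild-type-phenotype bulk.

Per variant locus and bulk, the SNP index is the fraction of non-reference
reads, estimated from the VCF FORMAT/AD allele depths (DP is ignored; the
index needs allele-resolved counts). The delta SNP index is defined
mutant-minus-wild-type, so the causal locus trends to +1; the sign
convention is a package choice — with the opposite order the scan is
mirrored but otherwise identical. ADSI is the absolute value of DSI.

Assumptions inherited from the study design:

* the phenotype is recessive and fully penetrant (an optional
  mutant-survival parameter in the simulator relaxes lethality, not
  penetrance);
* induced mutations are heterozygous in M1 and assigned to a homolog at
  random, which produces the coupling/repulsion phase mixture that
  motivates ADSI over signed DSI;
* bulks are equal-sized pools, so read counts at a locus are approximately
  binomial in the bulk allele frequency;
* variant identity across populations is the exact (chrom, pos, ref, alt)
  key — the strictest reading; position-only matching would merge distinct
  alleles at one site.

## Filtering

Retention requires total depth ≥ `min_depth` (default 6) in **both** bulks,
inclusive. The three background filters then run in fixed order with
first-match-wins statuses, so the per-status counts exactly partition the
input:

1. variants whose key occurs in ≥ 2 populations (among depth-passing
   sites) are flagged STEP1;
2. variants with SNP index > `hi` (default 0.7) in both bulks are STEP2;
3. variants with SNP index < `lo` (default 0.3) in both bulks, or with
   zero alt reads in the mutant bulk, are STEP3.

Comparisons against `hi` and `lo` are strict and evaluated in exact rational
arithmetic on the integer depths (`alt * den > num * tot` with the threshold
as an exact fraction of its decimal representation), so a site at exactly
7/10 is retained under "> 0.7" with no floating-point ambiguity. The
mutant-zero rule is an integer test (`mut_alt_depth == 0`), never a float
tolerance: a single mutant-bulk alt read keeps a repulsion-phase marker,
while a true noncausal-cell chimera variant has none.

Step 1 deliberately runs only across populations of the same progenitor
line; with a single population it is a logged no-op and homozygous
background is left to Step 2, which catches it when private but cannot
replace Step 1 in general (a shared variant that drifts below the 0.7 line
in one bulk escapes Step 2 but not Step 1).

## Genome scan

The fitted curve **is** the moving average: windows of `window_n`
consecutive retained SNVs, shifted one SNV at a time, plotted at the
midpoint of the first and last SNV (integer floor division). No spline or
kernel smoothing is applied. Windows never span chromosome boundaries, and
indels are excluded from curves (they re-enter at screening, where the
candidate may well be an indel).

`window_n` defaults to an automatic rule keyed to the genome-wide retained
SNV count — 10 below 2,000, 20 below 8,000, else 40 — chosen so that
typical retained densities of 1–8 SNVs/Mb on a ~1 Gb genome give tens to
hundreds of windows per chromosome. It is fully overridable.

The candidate region is the maximal contiguous run of windows whose fitted
ADSI is ≥ `region_fraction` (default 0.5) of the global peak, containing the
peak, reported as [first window's first bp, last window's last bp]. Ties on
peak value break toward the widest region, then the lowest
chromosome/position. Every chromosome's peak is also reported, ranked, so
runner-up regions are visible.

Zero-centering replaces each variant's ADSI with |DSI − mean(DSI)|, the mean
taken over retained SNVs genome-wide. It is off by default and
auto-suggested (mode `"auto"`) when |mean DSI| > 0.1 — the signature of
chimeric wild-type-bulk contamination, which scales all wild-type indices by
(1 − n) and shifts the whole DSI distribution positive. Without
contamination the genome mean is ≈ 0 and centering is a no-op.

Candidate screening uses the **per-variant** ADSI (not the windowed value):
mutant-bulk ref depth exactly 0 with ≥ 1 alt read (SNP index exactly 1),
ADSI > 0.5, and a protein-changing functional class (missense, nonsense,
splice, frameshift) when annotations are present; without any annotation in
the region, screening degrades to the numeric criteria with a warning.

## Segregation model

Observed wild-type/mutant counts are tested against expected proportions
1/(4k) mutant and (4k−1)/(4k) wild type for k = 1…3 initial cells with an
uncorrected Pearson chi-square on the two phenotype classes, df = 1, upper
tail. No Yates continuity correction is applied: the uncorrected statistic
reproduces published reference tables of this design at printed precision,
which the corrected statistic does not. The best model maximizes the
p-value, ties breaking toward smaller k (parsimony); when even the best
model has p ≤ 0.05 the report flags that no model fits.

## Simulator

The generator emulates, per population: a progenitor carrying homozygous
background SNVs relative to the reference (one shared set reused across all
populations, plus a private set); per initial cell, a Poisson number of EMS
variants placed uniformly (default 5/Mb on 20 × 50 Mb, 61.4% canonical
C→T/G→A, ~1% single-base deletions), heterozygous with random homolog; one
causal variant (always protein-changing, defining the coupling homolog);
selfing with recombination modeled as a Poisson crossover process at a
uniform 2.5 cM/Mb (Haldane, no interference — no genetic map is assumed);
phenotyping; bulks of 15 + 15; and reads with depth ~ Poisson(35) and alt
counts ~ Binomial(depth, bulk frequency), optional symmetric sequencing
error (default 0, so that oracle tests are exact).

Background densities (200/Mb shared, 5/Mb private) keep the study-like
regime in which background outnumbers mutagenic variants by two orders of
magnitude, with only the private high-index fraction surviving Step 1.

Chimeric contamination replaces `round(n · bulk_size)` wild-type-bulk
progenies with progenies of a noncausal cell (carrying that cell's EMS set
and none of the causal cell's). The count is deterministic — the designed-
experiment reading of "n% of the bulk" — so the wild-type index of
causal-cell variants scales by exactly (bulk_size − round(n·bulk_size)) /
bulk_size before read noise; with 15-progeny bulks that granularity is
1/30, which any check of the (1 − n) scaling must absorb.

What the simulator does **not** model: real read alignment (no FASTQ, no
mapping artifacts), depth heterogeneity beyond Poisson, variant-calling
error modes, non-uniform recombination or crossover interference, mutation
hotspots, and segregation-distorting loci other than the causal one.
Passing simulation tests therefore demonstrates the pipeline's correctness
under the stated generative model, not robustness to alignment- or
caller-specific pathologies in real data.

In the contamination-grid experiment, a mapping is scored successful only
when the causal position lies inside the detected region **and** the region
covers < 95% of its chromosome's windows. When contamination lifts the
whole DSI baseline above the half-peak threshold, the "region" degenerates
to the entire chromosome — a curve with no distinct peak — and counting
that as success would make the comparison between raw and zero-centered
scans meaningless. This distinctness requirement applies only to the grid
experiment; under uncontaminated conditions wide regions reflect genuine
long-range linkage (a 50 Mb chromosome at 2.5 cM/Mb is only 125 cM), not
baseline degeneracy.

## Numerical choices and degenerate inputs

* Indices are double precision; equality-style decisions (index = 0,
  index = 1, strict thresholds) are made on integer depths or exact
  rationals as described above. DSI satisfies
  `dsi = index_mut − index_wt` to 1e−12; the zero-centered mean is 0 to
  1e−9.
* Depth-failing sites carry NaN indices and are excluded from every
  downstream statistic.
* Empty inputs: zero retained SNVs make `zero_center` and region detection
  errors; a chromosome with fewer SNVs than the window yields an empty
  curve with a warning; an empty variant list yields a header-only table.
* Multiallelic VCF records are skipped by default (biallelic-only design),
  optionally split per alt allele; either way the count is logged.
* Output tables have fixed column orders and round-trip losslessly; BED
  export converts the internal 1-based inclusive coordinates to 0-based
  half-open at the boundary.
* Seeds fully determine simulator output, including exported VCF bytes;
  multi-population experiments derive per-population streams from one seed
  via `SeedSequence.spawn`.

## Problem sizes used in the test battery

The simulation studies in the test suite run at the full study conditions
(1 Gb genome, 5 EMS/Mb, 15 + 15 bulks, 35× depth): 50 seeds for
causal-recovery rates, 15 seeds for the repulsion-phase comparison
(repulsion fraction 0.6 on the causal chromosome), and a single-seed
0–90% contamination grid. Unit tests use a down-scaled genome
(4 × 10 Mb at proportionally higher densities) purely to keep individual
examples readable and fast; nothing in the scaled runs feeds the recovery
statistics.

## Known limitations

* The (4k−1):1 model assumes equal seed contribution from each initial
  cell and no gametic selection; real chimeras violate both, which is why
  the best-model report is a diagnosis, not an estimator with uncertainty.
* No confidence envelope is computed for DSI/ADSI curves; the method's
  screening criteria (index = 1, ADSI > 0.5) play that role, and adding
  simulation-based bands would change the method.
* Step 1 requires ≥ 2 populations of the *same* progenitor; applying it
  across unrelated lines would purge real mutations.
* Detected regions on long, moderately recombining chromosomes are wide
  (tens of Mb); the method narrows candidates by screening, not by
  shrinking the interval.
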