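# m2seq

Bulked-segregant mapping of EMS-induced recessive mutations **directly in the
M2 generation**, for plant geneticists who want a candidate gene without
selfing to M3 or outcrossing to the progenitor.

## The problem and the method

A chemically mutagenized (EMS) M1 plant carries thousands of heterozygous
point mutations, one of which causes a visible recessive phenotype in its
selfed M2 progeny. Pooling 15 mutant-phenotype and 15 wild-type-phenotype M2
individuals into two bulks and sequencing each at >30× lets allele
frequencies do the mapping. For each biallelic variant locus the package
computes the **SNP index** of each bulk,

```
SNP index = alt reads / (ref reads + alt reads)
```

the **delta SNP index** `DSI = index_mut − index_wt`, and the **absolute
delta SNP index** `ADSI = |DSI|`. The causal locus is homozygous in every
mutant-bulk individual, so its DSI tends to +1. Because each induced
mutation lands on a random homolog, mutations linked to the causal locus sit
in coupling phase (DSI → +1) or repulsion phase (DSI → −1) at random, and a
windowed mean of signed DSI cancels to zero near the causal locus. The mean
of **ADSI** does not — its genome-wide peak marks the candidate region.

Before the scan, three filters purge everything that is not a mutagenic
marker, using several independent M2 populations of the same progenitor line:

1. **Step 1** — variants observed in ≥2 populations are shared
   progenitor/reference background: removed.
2. **Step 2** — variants with SNP index > 0.7 in *both* bulks are
   population-private homozygous background: removed.
3. **Step 3** — variants with SNP index < 0.3 in both bulks
   (sequencing/alignment noise), or with SNP index exactly 0 in the mutant
   bulk (variants from a noncausal chimera cell), are removed.

Candidate mutations inside the detected region must have SNP index = 1 in
the mutant bulk, per-variant ADSI > 0.5 and a protein-changing annotation.

Two chimera-specific tools complete the method. Observed wild-type:mutant
phenotype counts are tested against the **(4k−1):1** segregation model
(chi-square, df = 1) to estimate the number k of independently mutagenized
initial cells behind the M1 seed (3:1 for one cell, 7:1 for two, 11:1 for
three). And when noncausal-cell progenies contaminate the wild-type bulk —
shifting every DSI positive — **zero-centering** (subtracting the
genome-wide mean DSI before taking absolute values) restores the ADSI scan
even at 90% contamination.

A forward simulator of the whole experiment (EMS mutagenesis → selfing with
Haldane recombination → bulk read sampling) provides ground-truth datasets
for every stage.

## Worked example

Simulate three small populations, run the scan, and test a segregation
table:

```python
from m2seq import M2SeqScan, SegregationTest, SimConfig, simulate_populations

cfg = SimConfig(seed=11, n_chromosomes=4, chrom_length_bp=10_000_000,
                ems_rate_per_mb=20.0, background_shared_per_mb=30.0,
                background_private_per_mb=5.0, n_populations=3)
datasets, truths = simulate_populations(cfg)
results = M2SeqScan(datasets).fit()
print(results.summary())
```

```
M2-seq genome scan
============================================================
Mut01: retained 810/2255 variants, window 10 SNVs
  candidate region Chr02:44,537-9,852,197 (peak ADSI 0.751 at 8,636,935)
  candidate Chr02:4517509 T>C [missense] index_mut=1.00 wt=0.35 ADSI=0.65
  candidate Chr02:8085174 C>T [missense] index_mut=1.00 wt=0.26 ADSI=0.74
  candidate Chr02:8615412 A>C [missense] index_mut=1.00 wt=0.39 ADSI=0.61
  candidate Chr02:8821779 T>A [missense] index_mut=1.00 wt=0.18 ADSI=0.82
  candidate Chr02:9140210 C>G [missense] index_mut=1.00 wt=0.34 ADSI=0.66
...
```

Each population retains ~750 of ~2,200 variants after filtering (the planted
background is purged), detects a candidate region, and screens a handful of
protein-changing candidates with mutant-bulk SNP index 1. The planted causal
mutation of `Mut01` is `Chr02:8821779` — the 0.82-ADSI candidate above.

```python
print(SegregationTest(n_mutant=23, n_wildtype=244, population_id="Mut09").fit().summary())
```

```
Segregation test — Mut09
  mutant: 23   wild type: 244   observed ratio 10.61:1
  k  expected   chi2      p
  1  3:1      38.23     6.28e-10
  2  7:1      3.686     0.0549
  3  11:1      0.02758   0.868 <- best
```

A 10.61:1 ratio rejects the single-cell 3:1 model outright and fits the
three-initial-cell 11:1 model (p = 0.868): the M1 seed was chimeric.

The same pipeline is scriptable from the shell:

```sh
m2seq simulate config.yaml --out sim/
m2seq map --vcf sim/Mut01.vcf --vcf sim/Mut02.vcf --vcf sim/Mut03.vcf \
          --annotations sim/Mut01.annotations.tsv \
          --annotations sim/Mut02.annotations.tsv \
          --annotations sim/Mut03.annotations.tsv --out mapped/
m2seq segregation counts.tsv
m2seq chimera-grid config.yaml --out grid.tsv
```

`map` writes a filter report, per-population variant/curve/candidate tables,
a candidate-region BED, a status-annotated VCF and genome-scan plots.

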