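# mjdhap

Founder-haplotype analysis of Machado-Joseph disease (MJD/SCA3)
chromosomes around the *ATXN3* CAG expansion: pedigree and EM haplotype
phasing, ancestral-lineage classification, case-control
linkage-disequilibrium and Hardy-Weinberg statistics, STR haplotype
networks, and founder-age estimation from flanking microsatellite
diversity — with a synthetic founder simulator so every stage is
testable end to end.

## The scientific problem

MJD is a dominant ataxia caused by an expanded (CAG)n (>51 repeats) in
*ATXN3*. Worldwide, most disease chromosomes sit on one of two ancient
SNP backgrounds, the **Joseph** lineage (T-T-A-C-A-C over the six core
SNPs rs12590497, rs16999141, rs1048755, rs12895357, rs7158733,
rs3092822) and the **Machado** lineage (G-T-G-G-C-A). Whether a
population's MJD chromosomes represent new mutational events or an old
founder can be read from (i) the SNP haplotypes segregating with the
expansion in families, (ii) their over-representation relative to
control chromosomes, and (iii) the diversity that flanking STRs have
accumulated on the shared background.

The package implements that analysis chain for a cohort of 50 Chinese
MJD families (109 patients, 20 SNPs and 7 STRs flanking the repeat,
shipped as packaged fixture tables):

* **Phasing** (`mjdhap.phasing`) — Mendelian segregation with the
  expansion modeled as a biallelic pseudo-marker at the (CAG)n anchor;
  an EM haplotype-frequency estimator for unrelated samples, retaining
  pairs with posterior > 0.6.
* **Lineage classification** (`mjdhap.lineage`) — exact/nearest
  matching against the Joseph and Machado references, divergent sites
  reported per family.
* **Association statistics** (`mjdhap.stats`) — allele counting,
  exact and χ² Hardy-Weinberg tests, 2×2 allele χ² (no continuity
  correction), two-sided Fisher exact tests, and the LD risk statistic
  **δ = (F_d − F_c)/(1 − F_c)** for disease vs control haplotype
  frequencies.
* **STR networks** (`mjdhap.network`) — locus-count and stepwise-sum
  step distances, locus-wise modal (ancestral) haplotypes with
  reported tie-breaks, and union-of-minimum-spanning-trees networks
  exported as GraphML/DOT.
* **Founder dating** (`mjdhap.dating`) — per-generation change
  probability **ε = 1 − (1 − c)(1 − μ)^L**, mean step load λ̂ to the
  ancestral haplotype, **t = λ̂/ε** generations, age = 25·t years,
  with a chromosome-bootstrap SE.
* **Simulation** (`mjdhap.simulate`) — star-genealogy stepwise-mutation
  founder samples and nuclear families with retained phased truth.

## Worked example

```python
from mjdhap import (RateModel, date_all_lineages, load_fixture,
                    delta_statistic, tabulate_table1)

summary = tabulate_table1()
print(summary.n_distinct_haplotypes,          # 13 disease haplotypes
      summary.families_with("rs56268847", "G"))  # 28 families carry G

print(round(delta_statistic(0.482, 0.283).delta, 3))  # 0.278

for est in date_all_lineages(load_fixture("table4"), RateModel(), n_boot=0):
    print(est.lineage, round(est.lambda_hat, 3), round(est.age_years))
```

prints

```
13 28
0.278
A 2.4 15332
B 2.0 12777
D 1.875 11978
G 2.0 12777
```

i.e. thirteen distinct disease haplotypes, 28/50 families carrying the
derived G at rs56268847, a population-attributable-risk δ of 0.278 for
the Joseph core haplotype, and founder ages of roughly 12–15 thousand
years for the four major lineages (λ̂ is the mean number of STR loci a
chromosome has changed relative to the lineage's modal ancestor;
dividing by ε ≈ 0.0039 changes/generation and multiplying by 25
years/generation gives the age).

The same computations are packaged as numbered drivers under
`analysis/` (`01_tabulate_lineages.py` … `05_recovery_simulation.py`),
each writing its tables to `results/`, and as a CLI:

```sh
mjdhap reproduce --out results/reproduce   # every in-table number, labeled
mjdhap date --mu 5.6e-4 --gen-years 25 --out ages.tsv
mjdhap network --lineage D --format dot --out d.dot
```

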