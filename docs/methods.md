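# Methods

This note records the models, conventions and deliberate choices behind
`mjdhap`, in the order the pipeline runs them.

## Data model and fixtures

The marker panel is an ordered physical map of 20 SNPs and 7 STRs
around the *ATXN3* (CAG)n; the anchor index marks where the repeat sits
(between rs10467856 and rs12895357). The published tables ship as plain
TSV fixtures and are transcribed verbatim, including their quirks:

* "Fam 1" appears under both lineage A and lineage D; both rows are
  kept with distinct row ids and no deduplication — the source offers
  no resolution, and we do not guess whether it is a typo or a family
  segregating two disease haplotypes. Consequently per-lineage family
  counts sum to 51 while the cohort is described as 50 families; both
  numbers are reported, and published frequencies (28/50 = 0.56) are
  reproduced against the stated 50.
* Fam 33's (AAAC)n entry "7 (5)" is stored as primary allele 7 with
  the 5 kept as an annotation; all computations use 7.
* Exact physical offsets for (AAAC)n and (GT)n — and for several SNPs
  whose assay names carry no coordinate — are not published; the
  manifest assigns order-preserving placeholder offsets. Nothing
  downstream uses offsets except ordering and anchor placement.

Lineage references: Joseph core-6 = T-T-A-C-A-C; Machado core-6 =
G-T-G-G-C-A (both lineages carry T at rs16999141; the second position
of the six-SNP string is that SNP). Only Joseph has a published 20-SNP
extension, so 20-SNP comparison is Joseph-only — we never invent
reference alleles for a Machado-20.

## Phasing

Segregation phasing fixes a child's allele origins marker by marker
when (a) the child is homozygous, (b) a parent is homozygous, or
(c) the allele is traceable to exactly one parent; anything else is
flagged ambiguous, never guessed. The expansion is a biallelic E/N
pseudo-marker at the anchor derived from each individual's expansion
count (0, 1, or 2 — a homozygous patient carries 2), so "in phase with
the expansion" is an ordinary phase query. Founders are anchored
through their transmissions to carrier children. Mendelian
inconsistencies abort the family's phasing with a located report;
with curated clinical pedigrees, silent correction would hide
genotyping errors. Missing genotypes: segregation skips the marker for
that individual; EM marginalizes over alleles observed at the marker.

The family disease haplotype is the vector co-transmitted with the
expansion across all carriers; carriers must agree at jointly resolved
markers, and disagreement (intra-family recombination) excludes the
family with an explicit error. A family with an expansion homozygote
contributes two disease haplotypes (the patient's two sides, each
merged with the matching parent's transmitted haplotype).

The EM estimator assumes unrelated individuals and Hardy-Weinberg pair
priors (2·f_i·f_j off-diagonal). It enumerates all
observation-compatible haplotype pairs per individual (with a hard cap
against combinatorial blow-up), starts from equal frequencies over the
compatible universe, and is fully deterministic — no random restarts
by default, so the seed field of the config is inert unless restarts
are enabled. The observed-data log-likelihood is non-decreasing across
iterations (asserted in tests). Retention uses strict inequality,
posterior > 0.6: a lone double heterozygote (posterior 0.5/0.5) is
dropped. This estimator is a deliberate simple stand-in for
coalescent-prior Gibbs samplers; it is exact for the small marker sets
used here but does not scale to many loci.

## Association statistics

* Allele counts are 2·hom + het over 2n chromosomes; frequencies are
  computed at full precision and rounded only for display (3 dp).
* Hardy-Weinberg: the default test is the exact conditional test
  (enumerate heterozygote counts given allele counts; two-sided p =
  sum of configurations no more probable than observed), because
  genotype classes as small as 3 make the χ² approximation poor; the
  df = 1 χ² goodness of fit against p², 2pq, q² is exposed alongside.
  The published HWE p-values (e.g. 0.007 for 46/60/3, where χ² gives
  ≈ 0.0015 and the exact test ≈ 0.0035) match neither convention; the
  published convention is unstated, so both of ours are reported and
  no agreement is forced.
* The 2×2 allele χ² uses no continuity correction; Fisher's two-sided
  p uses the "tables at most as probable" convention (scipy's); both
  choices make results bit-reproducible.
* δ = (F_d − F_c)/(1 − F_c) is computed exactly and reported signed.
  Two published rows deserve notes: T-T-G-G-A-C prints 0.003 where the
  formula on the printed frequencies gives −0.004 (F_d < F_c), and
  T-T-A-G-A-C prints 0.298 where the printed frequencies give 0.2985
  (→ 0.299 at 3 dp; their rounding evidently used unprinted digits).
  Both are flagged in the reproduction report, not reproduced.

## STR distances, ancestors, networks

Two step-distance conventions are first-class: `locus_count` (number
of differing loci) and `stepwise_sum` (Σ|Δrepeats|, the
stepwise-mutation step count). `locus_count` is the default for
dating: calibrated on the published lineage tables it lands inside the
published age range, while `stepwise_sum` overshoots by roughly 2–3×
(mean loads 6.9 vs 2.4 for lineage A).

The ancestral haplotype of a lineage is the locus-wise mode. Ties are
broken by the allele minimizing the total per-locus |step| distance to
the sample, then by the smallest allele, and every applied tie-break
is reported (lineage A ties 16/20 at (GT)n → 16; lineage B ties 9/10
at (ATA)n → 9). The locus-wise mode provably minimizes the summed
locus-count distance over haplotypes assembled from observed alleles;
no such optimality is claimed under stepwise-sum, whose per-locus
optimum is the median.

The network is the union of all minimum spanning trees over distinct
haplotypes (Kruskal processed by weight class, keeping every edge that
joins components still separate before its class), so equally
parsimonious connections survive as cycles. Full median-joining (with
inferred intermediate nodes) is not implemented — the published
figures name no algorithm, so topology-level equivalence is not a
goal; node identity is the exact 7-tuple with no repeat binning.

## Founder dating

ε = 1 − (1 − c)·(1 − μ)^L composes the per-locus mutation rate across
the L = 7 STRs; with one locus it reduces to the classical
1 − (1 − c)(1 − μ). Over t generations the expected number of
generations in which a chromosome changes is exactly ε·t, so the mean
observed step load λ̂ dates the founder at t = λ̂/ε.

Defaults — all explicit, logged config values, since the source prints
none: μ = 5.6e-4 per locus per generation (a standard
dinucleotide-repeat rate from the founder-dating literature),
c = 0 (treating the flanking haplotype as effectively non-recombining
on these timescales; an approximation for the distal STRs),
g = 25 years per generation. Age scales as 1/ε, so halving/doubling μ
scales all ages accordingly; sensitivity is one multiplication.

Uncertainty is a nonparametric bootstrap over chromosomes
(1,000 resamples by default, seeded), with the ancestor re-inferred in
every resample so ancestor uncertainty propagates. The published "±"
values' meaning (SD, SE, CI) is unstated; our SE is not claimed to be
the same quantity.

Fidelity to the published ages: with the defaults, lineages A and D
fall inside the published mean ± spread (15,332 vs 16,335 ± 1,966;
11,978 vs 11,837 ± 1,871); lineages B and G compute to ≈ 12,777 years
against published 9,272 ± 1,352 and 9,254 ± 1,411 under every
convention exposed here (either distance mode, either tie-break at the
one ambiguous locus). The published step-counting rule for B and G is
not recoverable from the text; the discrepancy is flagged in the
reproduction report rather than hidden or tuned away. All four ages do
fall inside the published 8,000–17,000-year summary window.

## Synthetic data

The founder simulator is a star genealogy: n chromosomes descend
independently from the founder for t generations; each locus mutates
with probability μ per generation by ±1 repeat (equal probability,
reflecting floor at 1 repeat, single-step only — matching the
single-step network distances); with probability c per generation the
segment downstream of a uniform inter-locus breakpoint is replaced by
a draw from a background pool. Mutation draws precede recombination
draws within a generation; all arithmetic is integer, so seeded runs
are bit-identical across platforms. The star genealogy is exactly the
model under which λ = ε·t holds, which makes recovery experiments
well-posed; shared (coalescent) genealogy, multi-step mutations, and
CAG-instability modeling are deliberately out of scope, so passing
recovery tests validate the estimator under its own assumptions, not
robustness to genealogical correlation in real cohorts.

The family simulator draws founder haplotype pairs from a pool,
transmits one haplotype per parent without intra-panel recombination,
and can seed a disease haplotype in one founder so the expansion
pseudo-marker co-segregates by construction; the phased truth is
retained for round-trip tests.

### Recovery experiment and its metrics

`recovery_experiment` simulates grids of (t, n), reruns the full
ancestor-inference → λ̂ → t̂ pipeline per replicate, and reports per
true t: the median t̂, the relative deviation of that median
(`central_rel_error` = |median(t̂) − t|/t), the per-replicate median
absolute relative error, the median signed relative error, and the
coverage of the bootstrap ±2 SE age interval.

Two metric subtleties, measured at the default study conditions
(t ∈ {100, 300, 500}, n = 10, 200 replicates):

* At t = 100 the expected number of observable changes in a whole
  10-chromosome sample is ≈ 3.9, so t̂ lives on a lattice of spacing
  1/(10ε) ≈ 25.6 generations and the per-replicate |relative error|
  has a floor of ≈ 0.23–0.28 for any estimator, biased or not.
  Accuracy claims are therefore stated on the central estimate
  (|median(t̂) − t|/t, observed ≈ 2%), with the per-replicate spread
  reported alongside as a dispersion measure.
* At larger t the locus-count load saturates (a locus counts once no
  matter how often it mutated, and ±1 walks revisit their origin), so
  E[λ̂] < ε·t once μ·t per locus ≳ 0.1 and t̂ drifts low (≈ −15% at
  t = 300, −18% at t = 500 — still within 25%). The exact generative
  identity E[changed generations] = ε·t is checked on the simulator's
  realized history (Binomial(t, ε) by construction), not on observed
  distances, which would conflate the identity with the saturation
  bias just described.

## Numerical and degenerate-input conventions

Exact HWE uses log-gamma arithmetic with a 1e-9 relative guard for
probability ties (validated against an exact rational-arithmetic
enumeration for every table with n ≤ 20). Monomorphic markers:
exact HWE returns p = 1; χ² returns statistic 0. δ requires F_c < 1.
ε = 0 with λ̂ > 0 raises an explicit "undefined age" error (surfaced
as a nonzero CLI exit). Empty haplotype lists, zero-margin tables,
length mismatches and cyclic pedigrees are rejected with typed errors,
never silently coerced. Bootstrap requires ≥ 2 chromosomes and ≥ 100
resamples.

## Problem sizes

The shipped analyses run on the study-scale fixtures (41 STR
chromosomes, 22 haplotype rows, 109+49 subjects' genotype counts).
Simulation-based checks use n = 10 × 200 replicates for recovery and
n = 2000 chromosomes for the generative identity — sizes chosen so the
Monte-Carlo standard errors quoted above are small relative to the
assertions they support.
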