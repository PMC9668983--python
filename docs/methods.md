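# Methods

`mendelaudit` audits biallelic autosomal SNP-array genotypes for Mendelian
errors (ME) in parent-offspring trios and attributes them to interpretable
causes. This note records the models, rules, parameters and numerical
choices the package implements, and what its synthetic data can and cannot
show about real array data.

## Data model

Genotypes are coded per locus as the number of copies of `allele2`
(0/1/2; -1 missing, any call containing the `0` allele code in a PED
file). A *trio* is an offspring with both parents known **and** genotyped;
duos are excluded from scanning because no sound single-parent rule exists
for attributing the error side. A *family* is the set of trios sharing the
same ordered parental couple (the same sow with a different boar is a
different family). Litter membership is optional side metadata (a
two-column TSV); no litter-level statistic is computed. Interval tracks
are stored 0-based half-open exactly as BED specifies, while MAP/PED
positions are 1-based and converted on read, which keeps overlap
arithmetic unambiguous: a SNP at 1-based position p hits `[start, end)`
iff `start <= p-1 < end`.

## Mendelian-error classification

A trio configuration is inconsistent when no combination of one paternal
and one maternal allele yields the offspring genotype; 12 of the 27
complete configurations are inconsistent (verified exhaustively in the
tests against a brute-force transmission checker). Each inconsistent
(trio, locus) pair is **one** mismatch — the unit is the trio-locus event
regardless of whether one or both child alleles are unexplainable — and is
assigned:

* *member* — child het with both parents homozygous for the same allele →
  `Trio` (unassignable; the violating allele is the one the parents lack);
  child homozygous for k with exactly one parent homozygous for the other
  allele → that parent, violating allele k; child homozygous for k with
  both parents homozygous for the other allele → `Offspring`, violating
  allele k;
* *frequency class* — `A` when the violating allele is the locus major
  allele (frequency computed over all called genotypes in the dataset;
  tie at 0.5 → `allele1`), else `B`;

giving the eight classes `TrioA … OffspringB`. Trios with a missing call
at a locus are skipped there; within a trio a locus yields at most one
event, and the same locus in different trios yields independent events.
Scanning is locus-major, trio-minor, and fully deterministic.

## Locus statistics

Per locus, over all called genotypes: allele frequencies, MAF, observed
heterozygosity Ho, expected heterozygosity He = 2pq (no small-sample
correction — this is what makes a het-free locus with both homozygote
classes give exactly F_IS = 1), and the heterozygote deficiency/excess
index

    F_IS = (He - Ho) / He,

reported missing (never 0) for monomorphic loci, where 0/0 is undefined.

The Hardy-Weinberg test is the exact conditional test on the heterozygote
count: given n individuals and the minor-allele count, the probability of
h heterozygotes is proportional to `n! / (hom_minor! h! hom_major!) 2^h`,
and the two-sided p-value sums the probabilities of all heterozygote
counts no more probable than the observed one (no mid-p correction).
Probabilities are computed with log-gamma accumulation and normalized in
place; a relative tolerance of 1e-12 guards floating-point ties between
equal-probability configurations. Monomorphic samples give p = 1. The
tests validate the implementation against an exact integer-arithmetic
enumeration for every genotype-count triple with n ≤ 50, and against the
1-df chi-square approximation at large n.

Dataset-level error rates follow the replicated-genotypes framework: with
`m_l` loci carrying ≥ 1 mismatch, `m_a` total mismatches and
`nt = n_loci x n_individuals`,

    e_l = m_l / n_loci        e_a = m_a / (2 nt),

where `e_l` uses the whole-panel denominator (mismatch loci over all
retained SNPs), the convention used in the reports this package emulates.
"Unique" loci have inconsistencies in exactly one trio; their count over
the panel is reported as the unique contribution to `e_l`.

## Allele-drop classes

Restricted to mismatch-set loci, with "reproductive" meaning ≥ 1
offspring in the pedigree and missing calls ignored:

* **ADO** (drop-out, the null-allele signature): zero heterozygotes in the
  whole typed population *and* both homozygote classes present among the
  called reproductive individuals. Requiring the second allele to
  segregate among reproducers is what separates ADO from ADI_hom — an
  offspring-only opposite homozygote also produces a het-free locus with
  both homozygote classes, but its allele is novel rather than inherited.
  ADO implies Ho = 0 with He > 0, hence F_IS = 1 exactly, and precludes
  Trio-class events (those need a heterozygous child); the report builder
  asserts this.
* **ADI_het** (drop-in as heterozygote): every called reproductive
  individual homozygous for one same allele, ≥ 1 called non-reproductive
  individual heterozygous.
* **ADI_hom** (drop-in as opposite homozygote): reproducers fixed as
  above, ≥ 1 offspring homozygous for the other allele.

Precedence on pathological inputs is ADO > ADI_het > ADI_hom. A locus with
no called reproducers is classified `none` with a warning.

## Filter evaluation

A scenario enables any subset of {MAF ≤ maf_max, exact-HW p ≤ hw_p_max,
F_IS ≥ fis_min}; a SNP is removed when it fails *any* enabled criterion
(the MAF and HW cuts use ≤, matching the conventional inclusive reading);
undefined F_IS never triggers removal. Reports count SNPs removed and
retained over the whole panel and mismatches whose locus was removed —
direct locus-removal accounting, with no secondary re-scan of trios.
Removal is monotone in every threshold and the combined scenario removes
at least as much as each component. The default grid is MAF ≤ 0.05, HW
p ≤ 1e-3, HW p ≤ 1e-4, F_IS ≥ 0.2, and MAF+HW combined, sorted by
mismatches removed per SNP lost.

## Synthetic data generator

The generator emulates the structure of a livestock trio-QC study; its
defaults are the study conditions used throughout the acceptance tests.

**Pedigree.** 15 founder boars and 28 founder sows form 61 distinct
couples; family sizes are `1 + NegativeBinomial(n=1.3, mean 6.8)`
truncated to [1, 34], targeting a mean of 7.8 offspring per family
(≈ 478 trios among ≈ 520 individuals). 15% of couples recruit one parent
among earlier-generation offspring, giving a multi-generation pedigree.
Family offspring are chunked into litters of `1 + Poisson(4)` capped at
12 (the trailing litter of a family is truncated, so realized litter
means run slightly below the draw mean).

**Genome and gene drop.** 20,000 loci by default (a desk-scale panel;
the audit itself is linear in loci and trios), split evenly over 18
autosomes of 100 Mb with sorted uniform positions. Founder allele-2
frequencies are Uniform(0.01, 0.5); 5% of loci are founder-monomorphic
(the substrate on which drop-in errors become the "new-allele" loci that
the ADI definitions describe). Founders are drawn in HWE; each offspring
receives one uniformly chosen allele per parent, so the true genotypes
contain zero Mendelian errors by construction.

**Observation layer.** Four mechanisms corrupt the true calls in a fixed
order (null, CNV, ADI, base); a cell altered by one mechanism is skipped
by later ones, so the truth table attributes every observed-vs-true
discrepancy to exactly one mechanism.

* *Null alleles* (1.2% of polymorphic loci; null frequency r = 0.25). The
  null is a non-amplifying sub-lineage of allele2, transmitted through the
  pedigree like any allele, which keeps the biallelic true genotype well
  defined. A visible/null genotype is called homozygous for the visible
  allele; null/null is missing. The locus's compromised chemistry also
  makes *visible* heterozygotes lose one allele (uniformly chosen) with
  probability `dropout` (default 0.7 — mostly-penetrant partial nulls, so
  null loci show strong but not total heterozygote deficiency). At
  dropout = 1 no heterozygote call survives while both homozygote classes
  do: the exact ADO signature, F_IS = 1. At dropout = 0 the
  called-heterozygote proportion is exactly `2pq/(1-r^2)` for visible
  frequencies p, q — the closed form the acceptance suite verifies against
  the simulation. The expected F_IS induced at a null locus is
  `1 - (1-d)(1-r)^2·2pq/He ≈ 0.4` already at d = 0, far above the 0.2
  filter threshold, which is why the F_IS filter recovers nearly all
  null-driven mismatches.
* *CNV miscalls*: 60 segments (lognormal lengths around 500 kb), each
  carried by ~1% of individuals; inside a carried segment each SNP of a
  carrier is miscalled with probability 0.4, independent of genotype. The
  corrupted value is kind-dependent — duplication (76.3% of segments) →
  spurious heterozygote, heterozygous deletion (16.5%) → a heterozygote
  loses one allele, homozygous deletion (7.2%) → missing. Duplication
  dominance is what concentrates CNV-driven events in the Trio classes: a
  spurious het child between same-homozygote parents is a Trio event,
  while a spurious het parent is almost always consistent.
* *Allele drop-in*: with probability 2e-4 per offspring genotype, the
  call is replaced by one containing the locus-minor (at monomorphic loci,
  population-absent) allele — heterozygous, or opposite-homozygous with
  probability 0.05. The hom fraction is set well above the rarity seen in
  real data so that the rare ADI_hom mechanism is actually represented
  (≈ 3-5 loci) in a 20,000-locus run; at a realistic fraction its expected
  count at this scale is below one locus and the mechanism could never be
  exercised. Injections target offspring only, matching the
  offspring-centric ADI definitions.
* *Base errors*: 1e-5 per genotype, uniform flip to another call — a
  floor of non-systematic errors (the TrioA-like background).

SINE/LINE tracks are emitted as fixed BED intervals co-located with 30%
of the CNV segments plus 150 random background intervals each, so the
class-by-feature contingency table can show the CNV/repeat covariation of
Trio-class errors.

All randomness flows through one `numpy.random.Generator` with a
documented draw order, so a seed makes every stage bit-reproducible.

**What the generator does not emulate.** Intensity-level (LRR/BAF) signal,
linkage disequilibrium and recombination (loci are independent),
selection and inbreeding dynamics, platform-specific cluster-calling
artifacts, and genotype-call-rate structure beyond the mechanisms above.
Passing recovery tests therefore show that the *audit logic* is correct
under known mechanisms at realistic scale — not that these mechanisms
exhaust the error causes of any particular real array dataset.

## Reported tables

The structure summary reports individuals, trios, families, litters,
loci, mismatch loci and mismatches plus the derived means (mismatches per
individual = total/trios; sites per autosome = loci/autosomes; offspring
per family = trios/families; offspring per litter = trios/litters) and
`e_l`, `e_a`, unique contribution. The per-class table reports loci,
mismatches and their fraction of the total, the mean mismatches per
*affected* offspring individual (class mismatches over distinct offspring
carrying that class — the concentration statistic that separates the
offspring classes, which pile up in few animals, from TrioB, which is
spread thin), the mean number of distinct families per class locus, mean
and SD of F_IS over class loci, and the fraction of class mismatches at
ADO/ADI_het/ADI_hom loci. Every number is recomputable from the emitted
event and locus TSVs.

## Known limitations

* Duos and half-sib structures contribute no events; error rates are
  conditional on complete trios.
* The member-assignment table for homozygous-child inconsistencies places
  the error on the contradicted parent; when the offspring call itself is
  wrong this attribution is a convention, not an inference.
* `classify_drop` depends on the reproductive flags of the pedigree
  actually supplied; with a truncated pedigree, recruited parents may be
  misread as non-reproductive offspring and shift ADI classifications.
* The exact HW test is two-sided by probability mass; one-sided
  heterozygote-deficiency tests would be more powerful against null
  alleles specifically, but the two-sided form matches the conventional
  QC pipelines this package audits.
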