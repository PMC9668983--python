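# mendelaudit

Mendelian-error audit for SNP-array parent-offspring trio data.

When a correctly recorded trio shows a genotype the parents cannot have
transmitted, the call is wrong far more often than the pedigree (de novo
rates are ~1e-8 per locus; array Mendelian-error rates run from 1e-3 to
0.15). Those errors are not one phenomenon: null and partial-null alleles
silence heterozygotes and bias whole loci, copy-number variants and
repeat elements (SINEs/LINEs) distort calls for some trio members only,
and a residue of miscalls is simply random. These causes leave different
fingerprints, and they call for different quality filters. `mendelaudit`
is for anyone running family-based genotype QC — livestock, pedigreed
wildlife or human trio panels — who wants to know *why* their Mendelian
errors occur before deciding what to remove.

## What it computes

For genotypes + pedigree in PLINK text PED/MAP:

* **Error detection and classing.** Every inconsistent (trio, locus) pair
  becomes one event, assigned to a member — Father, Mother, Offspring, or
  Trio when no member can be blamed (a heterozygous child between
  identical homozygous parents) — and to the violating allele's frequency
  class (A = major, B = minor): eight classes, TrioA … OffspringB.
* **Allele-drop classes.** Mismatch loci are screened for the null-allele
  signature (ADO: both homozygote classes segregating, zero heterozygotes,
  F_IS = 1) and the two drop-in patterns (ADI_het / ADI_hom: reproducers
  fixed for one allele, offspring carrying a "new" one).
* **Locus statistics.** MAF, observed/expected heterozygosity,
  F_IS = (He − Ho)/He with He = 2pq, and the exact conditional
  Hardy-Weinberg test on the heterozygote count; dataset error rates
  e_l = m_l/n_loci and e_a = m_a/(2·n_loci·n_individuals).
* **Feature overlap.** BED tracks of CNV calls and SINE/LINE annotations
  intersected with mismatch loci, cross-tabulated by error class.
* **Filter trade-offs.** For any grid of MAF / HW-p / F_IS thresholds,
  how many SNPs and how many mismatches each scenario would remove.
* **Synthetic data.** A seeded generator producing a multi-family
  pedigree, Mendelian gene drop, and an observation layer with null
  alleles, CNV miscalls, allele drop-ins and baseline errors — with a
  truth table attributing every corrupted call to exactly one mechanism.

See `docs/methods.md` for the models and rules in full.

## Worked example

Simulate a study-scale dataset (61 families, ~500 animals, 20,000 SNPs,
all error mechanisms at their defaults) and audit it:

```sh
mendelaudit simulate --seed 1 --out sim/
mendelaudit audit --ped sim/sim.ped --map sim/sim.map \
    --cnv-bed sim/cnv.bed --sine-bed sim/sine.bed --line-bed sim/line.bed \
    --litters sim/litters.tsv --out report/
```

or equivalently in Python:

```python
import mendelaudit as ma

ds = ma.simulate_dataset(ma.SimConfig(seed=1))
res = ma.audit(ds.observed, ds.sim_pedigree.pedigree,
               litters=ds.sim_pedigree.litters,
               tracks=[ds.tracks["CNV"], ds.tracks["SINE"], ds.tracks["LINE"]])
print(res.structure)
print(res.class_table)
print(res.filter_reports)
```

The structure summary for this run:

```
n_individuals = 510    n_trios = 467    n_families = 61    n_loci = 20000
n_me_loci = 1253       n_mismatches = 36118
e_l = 0.0627           e_a = 1.77e-3    unique_contribution = 0.048
mean_me_per_individual = 77.3           family_size_spearman_r = 0.994
```

6.3% of loci carry at least one mismatch (`e_l`), and family mismatch
counts track family size almost perfectly — bigger families give more
chances to catch an error. The per-class table splits the 36,118
mismatches by cause signature:

```
            n_loci  n_mismatches  frac_mismatches  mean_f_is
TrioA          162           546            0.015      0.689
TrioB         1083          2087            0.058      0.131
FatherA        211          7702            0.213      0.795
FatherB        240          7170            0.199      0.697
MotherA        217          8066            0.223      0.776
MotherB        237          6685            0.185      0.707
OffspringA     168          1470            0.041      0.804
OffspringB     247          2392            0.066      0.677
```

The parental classes gather 82% of mismatches on few loci with strong
heterozygote deficiency — the null-allele fingerprint — while TrioB
involves the most loci but few mismatches each (drop-ins and CNV-driven
miscalls). The filter grid quantifies the clean-up options:

```
scenario         snps_removed  frac_snps  mismatches_removed  frac_mismatches
fis0.2                    451      0.023               34940            0.967
hw1e-4                    733      0.037               34940            0.967
hw1e-3                   1341      0.067               34945            0.968
maf0.05+hw1e-3           4248      0.212               35297            0.977
maf0.05                  2921      0.146                 374            0.010
```

The heterozygote-deficiency filter (F_IS ≥ 0.2) removes 96.7% of the
mismatches at the cost of 2.3% of the panel — the best trade-off by an
order of magnitude — whereas the conventional MAF cut sacrifices 14.6% of
the SNPs to remove 1% of the mismatches. The ranking, not the exact
percentages, is the reproducible message: it follows from null alleles
dominating the mismatch mass.

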