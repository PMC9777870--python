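# dasekit

Differential allele-specific expression (DASE) analysis between
phenotypically contrasting groups.

## The problem

At a heterozygous, transcribed SNP, the two alleles of one individual can be
expressed at unequal levels — allele-specific expression (ASE) — which points
to *cis*-regulatory variation. When the *degree* of allelic imbalance differs
between individuals at the two extremes of a quantitative trait, the SNP
marks a region where the same *cis*-regulatory variation plausibly affects
both expression and phenotype. dasekit implements this differential-ASE
analysis for populations with estimated breeding values (the typical
livestock setting, e.g. half-sib cattle designs), from group construction
through statistical testing to integration with regulatory feature tracks.

## What it does

1. **Contrasting groups** (`group_selection`): animals are ranked by their
   genomic estimated breeding value (GEBV) for a trait; the top and bottom
   *N* form the High and Low groups under a sire-diversity cap (at most
   `max_per_sire` progeny of one sire per group, so half-sib families do not
   masquerade as group effects). Separation is verified with a pooled
   two-sample Student's *t*-test and the trait relationships are summarised
   as a Pearson correlogram.
2. **Testability filters** (`ase_counts`): from GATK-ASEReadCounter-style
   allelic count tables, a sample qualifies at a SNP iff it is in a
   contrasting group, heterozygous there, and has ≥ 10 ref+alt reads; a SNP
   is testable for a trait iff ≥ 3 samples qualify in each group.
3. **The DASE test** (`dase_model`), two engines:
   - `glm` — a negative-binomial log-linear model on the duplicated-sample
     count matrix (each sample contributes a ref row and an alt row),

     log μ = β₀ + β_G·[High] + γ_{g,s} + δ_Low·[alt, Low] + δ_High·[alt, High]

     with per-SNP dispersion profiled on a Cox–Reid-adjusted likelihood.
     Wald tests give p_high (δ_High = 0), p_low (δ_Low = 0) and p_diff
     (δ_High = δ_Low).
   - `betabin` — per group *g*, alt_i ~ BetaBinomial(n_i, π_g, ρ) with a
     shared overdispersion ρ; likelihood-ratio tests of π_High = ½,
     π_Low = ½ and π_High = π_Low.

   The log2 fold-change contrasts the *magnitude* of imbalance:
   log2FC = (|δ_High| − |δ_Low|)/ln 2 (resp. |log2 odds π_High| −
   |log2 odds π_Low|); positive values mean more imbalance in the High
   group, negative in the Low group. p_diff is Benjamini–Hochberg-adjusted
   within each trait; calls use FDR ≤ 0.05.
4. **Integration** (`integration`): ±200 kb windows around DASE SNPs are
   intersected with BED feature tracks (aseQTL / *cis*-eQTL / methylation /
   chromatin-state intervals, QTL lists); enrichment is assessed by a
   permutation test that re-places the query features uniformly within their
   chromosomes, preserving lengths (p = (1 + #{perm ≥ obs})/(n_perm + 1)).
5. **Reporting** (`reporting`): per-trait tallies, Manhattan-plot-ready
   tables, and JSON run manifests (input digests, thresholds, seeds,
   versions) for byte-identical replay.
6. **Synthetic data** (`synthetic_data`): generates half-sib populations,
   GEBVs with a sire variance component, heterozygous SNP panels, and
   overdispersed allelic counts with *known* group-dependent imbalance, so
   every stage is testable offline against ground truth.

## Worked example

```python
from dasekit import SimConfig, run_pipeline

cfg = SimConfig(n_animals=120, n_sires=30, traits=("WBSF0",), n_snps=500,
                het_prob=0.4, dase_fraction=0.1, pi_shift=0.3, seed=11)
run = run_pipeline(cfg, engine="glm", n_per_group=15, max_per_sire=2)

g = run.groups["WBSF0"]
print(f"groups: {len(g.high)} High / {len(g.low)} Low, separation p = {g.t_pvalue:.3g}")
print(run.summary[["trait", "n_tests", "n_significant", "n_direction_high",
                   "n_direction_low", "empirical_power", "empirical_fdp"]].to_string(index=False))
print(run.results.nsmallest(3, "fdr")[["snp_id", "p_high", "p_low", "p_diff",
                                       "fdr", "log2fc", "direction"]].to_string(index=False))
```

prints

```
groups: 15 High / 15 Low, separation p = 7e-14
trait  n_tests  n_significant  n_direction_high  n_direction_low  empirical_power  empirical_fdp
WBSF0      478             34                16               18         0.790698            0.0
  snp_id       p_high        p_low       p_diff      fdr    log2fc direction
snp00065 5.747249e-08 5.665274e-03 4.969136e-08 0.000024  1.430174      High
snp00099 1.426095e-08 7.147183e-01 2.069974e-07 0.000049  2.310313      High
snp00095 3.656191e-01 2.659720e-07 5.243578e-06 0.000501 -2.532603       Low
```

Of the 500 simulated SNPs, 478 pass the testability filters; 34 are called
DASE at FDR ≤ 0.05, split between SNPs whose imbalance is larger in the High
group (positive log2FC) and in the Low group (negative). Audited against the
generator's truth labels, the calls recover 79% of the injected signals with
no false discoveries in this run. `snp00095` shows the classic one-sided
pattern: strong imbalance within the Low group (p_low ≈ 3·10⁻⁷), none in the
High group, hence a negative log2FC.

The same stages are exposed as a CLI:

```sh
dase-kit simulate --n-animals 120 --n-sires 30 --traits WBSF0 --seed 11 \
    --n-per-group 15 --max-per-sire 2 --outdir sim/
dase-kit select-groups --gebv sim/gebv.tsv --pedigree sim/pedigree.tsv \
    --trait WBSF0 --n-per-group 15 --out groups.tsv
dase-kit test --counts sim/ase_counts.tsv --groups groups.tsv --engine glm --out res.tsv
dase-kit report --results res.tsv --out-prefix report
```

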