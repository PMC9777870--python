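# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Contrasting-group selection

Animals are ranked by GEBV for one trait. The High group is filled by a
greedy scan from the top: an animal is taken unless its sire already has
`max_per_sire` members in that group, in which case the scan moves to the
next-ranked animal. The Low group is then filled symmetrically from the
bottom, excluding animals already allocated to High (the two groups must be
disjoint even under heavy ties). GEBV ties are broken by ascending animal id
so the output is invariant to input row order. When either group cannot be
filled, selection fails loudly, reporting how many slots could be filled —
it never silently returns smaller groups.

`max_per_sire` defaults to 1, the strict reading of "no two progeny of one
sire in the same contrasting group"; it is configurable because looser caps
are common when sire panels are small relative to `n_per_group`.

Separation is verified with the classical pooled-variance two-sample
*t*-test (Welch's variant behind a flag). Degenerate zero-variance inputs
use the convention p = 1 for identical means and p = 0 (flagged) otherwise.
Trait–trait relationships are summarised by pairwise-complete Pearson
correlations; pairs with fewer than 3 complete observations or a constant
trait are reported as missing, never coerced to zero.

## Testability filters

A sample qualifies at a SNP iff it belongs to a contrasting group, has a
count record there (ASEReadCounter emits only heterozygous sites, so record
presence encodes heterozygosity), and has refCount + altCount ≥ `min_depth`
(default 10). A (SNP, trait) is testable iff at least `min_animals`
(default 3) samples qualify in High **and** in Low. The depth rule is
applied to ref+alt, not to a total that includes other bases, because only
the ref/alt columns enter the model. Filtering is monotone (raising either
threshold never enlarges the testable set) and idempotent; both properties
are asserted in the test suite.

## The duplicated-sample count design

Each included sample contributes two observations, one per allele. The
design has an intercept, a High-group indicator, sample effects nested in
group (first sample of each group is the reference level) and two
allele-within-group terms δ_Low, δ_High. Because every sample appears as its
own factor level, library-size normalisation is unnecessary — the sample
effect absorbs depth. For n samples the design has n + 2 estimable
coefficients and 2n observations, leaving n − 2 residual degrees of freedom.

## GLM engine

Counts are modelled as negative binomial (NB2) with log link. Per SNP the
dispersion α is profiled on a grid of 18 log-spaced values spanning the
Poisson limit (α = 10⁻⁹) to α = 4, maximising the Cox–Reid adjusted profile
likelihood (the −½ log det(XᵀWX) correction that compensates the downward
bias of plug-in ML dispersion in small samples; the same adjustment the
standard RNA-seq count-model packages use). Coefficients are fit by IRLS at
each grid point with warm starts; a method-of-moments dispersion is the
fallback for pathological fits. Wald statistics for δ_High, δ_Low and the
contrast δ_High − δ_Low are referred to a *t* distribution with the residual
degrees of freedom (n − 2): with the 3–20 samples per group this analysis
typically retains, the normal reference is visibly anticonservative while
the *t* reference holds the 5% level (measured by the acceptance checks on
2000 null SNPs at 6 samples/group).

A group with all-zero counts for one allele puts the allele coefficient at
−∞; such SNPs are flagged `boundary`, marked unconverged, and excluded from
FDR strata rather than assigned an arbitrary p-value. No pseudocounts are
added anywhere.

Batched fitting: SNPs retaining the same number of qualifying samples per
group share one design matrix, so IRLS, the dispersion grid and the Wald
covariances are evaluated for thousands of SNPs simultaneously as stacked
linear solves. This is purely an implementation detail — the single-SNP and
batched paths produce the same fits — but it is what makes the
5,000-SNP × 20-replicate FDR study run in about a minute.

## Beta-binomial engine

Per group g, alt_i ~ BetaBinomial(n_i, π_g, ρ) with ρ shared between groups
(one overdispersion per SNP, as for the GLM's α). The likelihood is
maximised with L-BFGS-B over (π_High, π_Low, ρ) with π ∈ [10⁻⁴, 1 − 10⁻⁴]
and ρ ∈ [10⁻⁶, 0.95], from moment starting values and two ρ starts (0.02,
0.15). The exact ρ = 0 profile (pure binomial, closed-form π̂) is always
evaluated as well; when it wins, the fit is reported at the boundary with a
flag. The three tests are likelihood-ratio tests of π_High = ½, π_Low = ½
and π_High = π_Low.

Reference distribution: the 1-df LRT is referred to F(1, n − 2) (the
*t*²-analogue with the two-sample residual df) rather than χ²(1). With a
handful of samples the estimated ρ makes the χ² reference anticonservative
(measured rejection ≈ 0.07–0.08 at nominal 0.05 with 6 + 6 samples), while
F(1, n − 2) holds the 5% level and converges to χ²(1) as n grows. The cost
is conservatism deep in the tail (rejection below nominal at α = 0.01 for
very small n); since downstream FDR control only suffers from
*anti*conservatism, this is the right side to err on.

## log2 fold-change and direction

The reported log2FC contrasts the *magnitude* of allelic imbalance between
groups: (|δ_High| − |δ_Low|)/ln 2 for the GLM, |log2 odds π_High| −
|log2 odds π_Low| for the beta-binomial. Positive values mean the imbalance
is larger in the High group, negative in the Low group, matching the
direction classification (High / Low / undirected at exactly 0). A signed
contrast δ_High − δ_Low would conflate *which allele* is favoured with *how
imbalanced* each group is: a High group skewed toward the reference allele
and a balanced Low group would get a negative sign despite the imbalance
being larger in High. p_diff still tests the signed difference of the
allele effects; log2FC is a summary, not the test statistic. Swapping group
labels negates log2FC exactly (beta-binomial) or to numerical tolerance
(GLM).

## Multiple testing

Benjamini–Hochberg is applied to p_diff within each trait across all its
tested SNPs; unconverged tests are excluded from the strata and keep
fdr = NaN. A trait × gene stratification is available behind the
`per_gene` flag; pooled-within-trait is the default because it is the only
unambiguous reading of per-phenotype correction. The within-group p-values
are reported so users who want "ASE in exactly one group" can post-filter on
nominal p_high/p_low; the significance call itself uses only the
between-group FDR.

## Interval integration

SNP tables are 1-based throughout; interval tracks are BED-style 0-based
half-open; `snp_to_interval`/`window_around` are the only conversion points.
A ±`width` window (default 200 kb, an LD-scale proxy) around each SNP is
clamped to chromosome bounds. Overlap requires ≥ 1 shared base; touching
intervals do not overlap. Strand is ignored.

The permutation test randomises the *query* set (the smaller,
hypothesis-bearing DASE-derived set), re-placing each feature uniformly
within its own chromosome with its length preserved; overlaps among placed
features are permitted and assembly gaps are not masked. The statistic is
the number of query features hitting ≥ 1 reference feature;
p = (1 + #{perm ≥ obs})/(n_perm + 1), so p is never 0 and its floor is
1/(n_perm + 1). z uses the permutation mean and SD and is NaN when the
permutation distribution is degenerate.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a tuning
dial. Defaults: 190 animals from 34 sires; GEBVs are sire effect + residual
(Gaussian, SDs 0.5 and 1.0, giving half-sib intraclass correlation 0.2 —
enough to exercise the sire cap); read depths are zero-truncated
gamma–Poisson (negative binomial, mean 50, size 5 — RNA-seq-like
overdispersion; a zero-depth site carries no allelic information);
alternate-allele counts are beta-binomial with baseline π = 0.5, ρ = 0.02
(placeholder values — no per-SNP depth or overdispersion estimates exist to
calibrate against); 30% heterozygosity per SNP × animal; 10% of SNPs truly
DASE with an additive shift of 0.25 applied to one randomly designated
contrasting group of one randomly assigned trait (tying each true signal to
a single trait keeps the truth table free of conflicting π values for
animals sitting in groups of several traits). All randomness flows from one
master seed through named substreams per stage, so regenerating one stage
never perturbs another and fixed seeds give bit-identical tables.

What the generator does *not* emulate: linkage disequilibrium and phasing,
mapping bias beyond a π offset, read-level artefacts (no FASTQ/BAM), gene
structure (SNP positions are uniform, not clustered in exons), and
covariance between traits' true effects. Passing tests therefore demonstrate
the statistics behave correctly under the assumed count model — not
robustness to alignment artefacts or LD structure in real data.

## Problem sizes of the packaged studies

The calibration studies run at: 2,000 null SNPs per engine (6 samples/group,
depth 50, ρ = 0.02); 500 replicates per power point (10/group, depth 100);
5,000 SNPs × 20 replicates for FDR control (10% true, shift 0.25, the
standard 10-read/3-animal filters applied); 50 grid-oracle instances
(50 × 50 × 20 grid over π_High × π_Low × ρ); 100 random track pairs against
the all-pairs overlap oracle; 100 replicate permutation tests at
n_perm = 200; and a 2,000-SNP, 190-animal, 3-trait full pipeline run. These
sizes give binomial standard errors comfortably inside the asserted bands
while keeping a full run of the suite plus acceptance script in the
single-digit minutes on one CPU.

## Known limitations

- No cross-SNP dispersion shrinkage by default (each SNP's test is
  self-contained); a shared-dispersion batch is the natural extension for
  very small groups.
- The GLM's Wald tests ignore uncertainty in the profiled dispersion (as is
  conventional); the CR adjustment plus *t* reference compensate empirically
  at the calibrated sizes, and the deep tail is conservative rather than
  inflated.
- Extreme fits where one group expresses a single allele are flagged rather
  than assigned a finite fold-change; consumers should treat `boundary`
  SNPs separately.
- The permutation null does not mask assembly gaps or low-mappability
  regions; with real genomes, enrichment against a gap-rich reference will
  be anticonservative unless the caller pre-filters the genome-size table.
- Per-gene FDR stratification assumes the SNP→gene map is unique per SNP;
  SNPs overlapping several genes are stratified by the joined gene label.
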