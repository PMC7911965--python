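# Methods

## Problem formulation

Given L samples genotyped at N SNPs (minor-allele dosage 0/1/2) with binary
case-control status, a K-order epistasis candidate is a set S of K distinct
SNP indices. The detector minimises two functions of the 3ᴷ × 2 contingency
table cross-tabulating the joint genotype at S against phenotype:

* **K2 score.** The classic Bayesian-network scoring criterion for a node
  (phenotype) with parent set S. We report its negative natural logarithm,
  Σᵢ [ln((nᵢ+1)!) − ln(n_i,control!) − ln(n_i,case!)] for J = 2, computed
  with `scipy.special.gammaln` so no factorial is ever materialised. The
  log base is a monotone rescaling and cannot change dominance
  relations; empty table rows contribute exactly 0, and the score is 0 iff
  the table is empty. Agreement with exact big-integer factorial
  arithmetic is tested to 1e-9 relative.
* **Gini impurity.** Σᵢ (nᵢ/n)(1 − Σⱼ (n_ij/nᵢ)²) ∈ [0, 0.5] for two
  classes; 0 iff every non-empty genotype cell is phenotype-pure.

Both scores are invariant to locus order within a combination and to
genotype relabelling at a locus, so a combination is identified by its
sorted locus tuple everywhere deduplication matters. Samples missing any of
the K genotypes are excluded per combination (pairwise-complete); the
simulator never generates missingness, so this only affects real data.

## Pareto screening and fitness

With both objectives minimised, a dominates b iff a is ≤ b in both
coordinates and < in at least one; exact ties in both leave the pair
mutually nondominated (duplicate objective points can therefore co-exist in
a front and are resolved by chromosome-level deduplication instead).
Selection fitness is domination-count based: dominated members get 1,
nondominated members 2 + 2·d where d is the number of members they
dominate. The published pseudocode accumulates credit in input order and
stops at the first dominated victim, which makes it order-dependent when
domination chains exist; the rule used here is its order-independent
closure (it reproduces the pseudocode whenever victims are credited at
their initial value) and preserves the intended monotone pressure. The
fitness properties — 1 iff dominated, invariance to input order — are
property-tested.

## Search

Each of `num` (default 60) independent restarts evolves `ps` = 50
chromosomes for `maxtimes` = 100 generations:

1. score the population (memoised across the whole fit, so revisits are
   dictionary lookups);
2. archive the generation's nondominated members;
3. roulette-select 50 parents with probability fᵢ/Σf;
4. pair parents sequentially; with probability Pc = 0.6 apply one-point
   crossover at cut point round(u·K) ∈ {0..K};
5. with probability Pm = 0.01 per child, replace the locus at position
   ceil(u·K) with ceil(v·N) (u, v drawn from U(0,1), open at 0);
6. repair: offspring with duplicate loci trigger up to `retry_budget` = 10
   redraws of the offending draw, then the parent passes through; a final
   sweep replaces residual duplicate chromosomes with fresh random ones.

Children wholly replace parents (generational GA); elitism comes from the
cross-generation archive rather than re-injection, which matches a design
in which each generation "outputs" its candidates. Each run's archive is
reduced to its own nondominated subset; the archives of all runs are
merged, deduplicated canonically, and Pareto-screened once more. That final
nondominated set — the elite set — is the detection result, sorted by
(K2, Gini, loci) so output files are byte-stable.

`maxtimes` has no published value; 100 generations is the package default
and is CLI-overridable. Randomness: the master seed spawns one `numpy`
`SeedSequence` child per restart, so restarts are independent,
reproducible, and prefix-stable (raising `num` reuses the earlier streams,
which makes the elite set monotone in restarts — a tested invariant).

## Disease-model simulator

Each dataset embeds one K=2 penetrance model f(g₁,g₂) under
Hardy-Weinberg equilibrium with equal MAFs at both functional loci.
Population summaries are prevalence K* = Σ p(g)f(g) and heritability
h² = Σ p(g)(f(g)−K*)² / (K*(1−K*)).

* **DME1/DME2/DME3** (marginal-effect architectures): disease odds are
  α(1+θ)^x(g) with exponent pattern x = g₁·g₂ (multiplicative),
  1[g₁≥1 ∧ g₂≥1] (threshold), and (g₁+g₂) mod 2 (a fixed XOR-checkerboard
  standing in for the "concrete" model), and penetrance
  f = odds/(1+odds). The odds scale is the standard two-locus interaction
  parameterisation and keeps f inside (0,1) for any effect size; on the raw
  penetrance scale the multiplicative architecture saturates at very small
  h² because its rare double-homozygote cell hits the f ≤ 1 cap first. For
  given θ, α is solved by bisection from the prevalence constraint
  (prevalence is strictly increasing in α); θ is then solved by bisection to
  match h². Calibration round-trips to 1e-6 or better; architectures that
  cannot express a requested h² at the given MAF (e.g. threshold models at
  MAF 0.05 saturate near h² ≈ 0.038 at prevalence 0.2) raise an
  infeasibility error rather than silently under-delivering.
* **DNME** (no marginal effects): a random deviation table is projected
  onto the linear subspace where every HWE-weighted row and column mean is
  zero — so each single-locus marginal penetrance equals the prevalence
  exactly — then scaled to the requested h²; tables leaving [0,1] are
  rejected and redrawn.

Case genotypes at the functional loci are drawn proportional to p(g)f(g),
controls proportional to p(g)(1−f(g)); the remaining SNPs are independent
HWE noise with per-SNP MAFs uniform on [0.05, 0.5]. Defaults not otherwise
fixed: prevalence 0.2, DME heritability 0.05, equal case/control counts.
The generator emulates array-genotyped common variants with a single
embedded interaction; it has **no** linkage disequilibrium, covariates,
population structure, genotyping error or missingness, so passing tests
demonstrate detector behaviour under clean, well-calibrated signals, not
robustness to real-data confounding.

## Quality control and post-hoc analysis

Samples with call rate < 0.95 are dropped first, then SNPs failing call
rate < 0.95, MAF < 0.05, HWE goodness-of-fit p < 0.05 (1-df chi-square in
controls only, standard practice), or the single-SNP association rule. The
association rule's direction is configurable: the default `keep_below`
retains SNPs with association p < 0.05 — i.e. it pre-enriches the search
panel with marginally associated markers, the reading consistent with a
~3.6% survival rate on array-scale data — and the CLI logs the active mode
loudly; `drop_below` gives the conservative opposite. Pairwise chi-square
tests drop empty genotype rows and adapt the degrees of freedom; no Yates
correction. Retained pairs (joint p < 0.001 by default) export as a SIF
edge list plus a node-degree / −log₁₀p attribute table.

## Evaluation

Power is the fraction of replicate datasets whose elite set contains the
embedded pair as an exact set match (a near-miss sharing one SNP counts as
a miss — partial credit is deliberately not given). Recall, precision and
F-measure are micro-averaged from pooled TP/FP/FN counts (one possible TP
per dataset); undefined ratios are reported as undefined rather than 0.
The acceptance experiment runs 30 replicates of the threshold-model
setting (MAF 0.1, h² 0.05, prevalence 0.2, 400 cases + 400 controls, 100
SNPs) with the default GA parameters — a desk-scale rendition of a
100-replicate study; at ~4.5 s per replicate on one CPU, larger replicate
counts scale linearly via `power_experiment(replicates=...)`.

## Numerical and testing notes

* All counting is vectorised (`bincount` over mixed-radix cell indices);
  the ln(k!) table is precomputed once per dataset.
* Determinism: given (dataset, config, seed) the elite TSV is
  byte-identical across runs; float formatting uses `%.12g`.
* The null-calibration check deserves a caveat: with h² = 0 the simulator
  produces genuinely phenotype-independent genotypes, and chi-square
  p-values on *independent* SNP pairs have close to nominal size (tested:
  rejection rate at the 5% level within ±0.025 over 2,500 independent
  pairs). A KS uniformity test applied to all C(100,2) = 4,950 p-values of
  a single scan, however, rejects routinely — each SNP participates in 99
  pairs, so those p-values are strongly dependent and the iid KS null does
  not hold. The acceptance suite keeps the single-scan KS check in its
  strict form (and it fails for this structural reason); the
  independent-pairs diagnostic is the meaningful null check.
* Hypothesis-based property tests run derandomised so repeated test runs
  explore identical example sequences.
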