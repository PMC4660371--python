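# Methods

## Demographic model and drift units

A demography is a rooted directed acyclic graph of populations. Tree
branches carry genetic drift, parameterized either directly as
`d ∈ [0, 1)` or as a duration in years; durations convert to drift through
`d = 1 − exp(−t / (g · 2·Ne))`, the diffusion-limit loss of heterozygosity
for a Wright–Fisher population of diploid effective size `Ne` and
generation time `g` years. Admixture events replace a node's frequency by
`α·p_A + (1−α)·p_B` from two source nodes. Defaults are `Ne = 10,000` and
`g = 29` years; both are plain model fields, and split times are only
identifiable given both (drift measures `t / (2·Ne·g)` and nothing finer).

The `jones2015` preset fixes the deep structure at: outgroup split 100 kya;
WHG vs (CHG, EF) 45 kya; CHG vs EF 25 kya; EHG branching from the WHG line
20 kya; within-WHG (Bichon/Loschbour) and within-CHG (Kotias/Satsurblia)
splits 17 kya; Yamnaya an even (α = 0.5) mixture of CHG- and EHG-related
sources branching off 5 kya. The 45/25 kya splits and the even Yamnaya
mixture are the quantities the inference machinery is meant to recover;
the remaining times (100, 20, 17, 5 kya) are package defaults chosen as
round, phylogenetically consistent values, not inferences — all are
editable in the YAML model config. An optional basal-Eurasian lineage can
contribute 20% of EF ancestry (`basal_eurasian=True`); it is off by
default because no proportion is established for it. Two modern diploid
populations (ModernCaucasus on the CHG branch, ModernNorth on the WHG
branch) give the PCA and affinity analyses modern reference panels.

## Simulator and exact moment engine

Frequencies evolve by the Balding–Nichols Beta transition
`p' ~ Beta(p(1−d)/d, (1−p)(1−d)/d)`, mean-preserving with conditional
variance `d·p(1−p)`; the boundaries 0 and 1 are absorbing, and `d = 0`
copies the parent. The root frequency is Uniform(0.05, 0.95) by default
(its moments are closed-form: `E[p] = 1/2`, `E[p²] = 0.3175`), with a Beta
option.

Because the transition matches the first two moments exactly, expected
f-statistics follow from a deterministic recursion over the graph in
topological order: drift updates `E[p²] ← E[p²] + d(E[p] − E[p²])` and
leaves first and cross moments unchanged; children of a split share the
parent's `E[p²]` as their cross moment; admixture combines moments
linearly (first, cross) and bilinearly (own second moment) in α. All
f-statistics are then linear functionals of the moment table. This engine
is simultaneously the simulator's oracle (simulated statistics converge to
it at Monte-Carlo rate) and the forward model for split-time fitting.
Expected f4 is exactly linear in admixture proportions, which underwrites
the f4-ratio estimator.

The simulator works at the level of population allele frequencies and
independent SNPs: it does not generate sequence-level coalescent histories
or linkage disequilibrium (planted ROH structure excepted). Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's assumptions, not robustness to LD, ascertainment bias or
post-mortem damage in real panels; the 5 cM block jackknife is carried
through regardless so that the code paths match real-data practice.

## Allele counting and bias corrections

Population frequencies are estimated by counting chromosomes: a diploid
sample contributes its dosage out of 2; a pseudo-haploid sample (one
random allele duplicated to a homozygous call) contributes dosage/2 out of
1 — its duplicated allele is a single observation. Per-SNP unbiased terms:

- f2: `(p̂A − p̂B)² − ĥA/(nA−1) − ĥB/(nB−1)` with `ĥ = p̂(1−p̂)`
- f3: `(p̂C − p̂A)(p̂C − p̂B) − ĥC/(nC−1)`
- f4/D numerator: `(p̂W − p̂X)(p̂Y − p̂Z)` (already unbiased)

The corrections remove the sampling variance `p(1−p)/n` of the estimated
frequencies and are exact for binomial sampling, which holds for both
diploid draws and pseudo-haploid single-allele draws. They require
`n ≥ 2` chromosomes in the corrected population; this is why the preset
samples two pseudo-haploid individuals per ancient population. For f3
targets containing pseudo-haploid samples, within-individual
heterozygosity is uninformative (they carry none by construction);
`inbreed_mode=True` accepts such targets and estimates heterozygosity
purely from allele counts across haploid chromosomes. A SNP enters a
statistic only when every population in that statistic has data there
(complete cases per statistic).

D is the f4 numerator divided by `(p̂W + p̂X − 2p̂Wp̂X)(p̂Y + p̂Z − 2p̂Yp̂Z)`
summed over SNPs, and is jackknifed as a ratio (leave-block-out
recomputation of the full ratio, not linearization); the same applies to
the f4-ratio.

## Block jackknife

Standard errors use the weighted delete-one block jackknife for unequal
block sizes (block weight = number of contributing SNPs): with `g` blocks,
totals `θ̂`, leave-one-out values `θ_(−j)` and `h_j = n/m_j`,

```
τ_j = h_j θ̂ − (h_j − 1) θ_(−j)
θ̇  = g θ̂ − Σ_j (1 − m_j/n) θ_(−j)
Var = (1/g) Σ_j (τ_j − θ̇)² / (h_j − 1)
```

which reduces to the textbook jackknife variance for equal blocks. Blocks
are half-open 5 cM windows of the genetic map, restarting at each
chromosome; simulated panels use a uniform 1 cM/Mb map over 30
chromosomes of 100 Mb (≈ 600 blocks). At least two non-empty blocks are
required for an SE. Two-sided `|Z| > 3` is used throughout for
significance, with no multiple-testing correction.

## Decision procedures

**Topology test.** For three populations and an outgroup, the pair with
the largest outgroup-f3 (most shared drift) is the inferred clade. The
verdict is decisive only when the winner beats both alternatives with a
difference Z above 3, where the difference of the two f3s is jackknifed
per SNP on the joint complete-data mask (correlated statistics, so
differencing before resampling is essential).

**Clade test.** `D(outgroup, probe; A, B)` over a probe set; any |Z| > 3
rejects the clade.

**Affinity ranking.** Outgroup-f3(outgroup; modern, ancient) per modern
population, ranked descending.

**Admixture scan.** `f3(X, Y; target)` over all unordered candidate pairs,
ranked ascending; pairs with Z < −3 are flagged as admixture evidence.

**f4-ratio.** `α = f4(O, X; B, M) / f4(O, X; B, A)` for a target M mixed
between A- and B-related sources, X attached on A's lineage. In the preset
application A = Kotias, X = Satsurblia (both CHG), B = EHG, M = Yamnaya.
The denominator's Z is reported so callers can flag unreliable ratios
(|Z| < 3).

## Split-time fitting

The fitter is a deterministic method-of-moments replacement for coalescent
MCMC genealogy samplers: it minimizes
`Σ_i [(obs_i − E_i(t)) / SE_i]²` over a chosen set of free node times,
with expectations from the moment engine, using bounded least squares
(SciPy trust-region reflective, times in [0, 300] kya). Observations are
all pairwise bias-corrected f2 statistics among sampled populations (28
for the preset), with jackknife SEs as weights. Parent/child ordering is
maintained by clamping negative branch durations at zero plus a penalty
residual proportional to the violation. The optimizer starts from a
generic topology-depth-scaled point (80 kya × 0.65^depth), not from the
generating times. A post-fit probe nudges each parameter by 5%; a
parameter that leaves the objective unchanged marks the fit
non-identifiable. Ne, generation time, the topology and admixture
proportions are fixed inputs, never fitted.

At 200k SNPs under the preset conditions the fitter recovers the 45 kya
and 25 kya splits with relative errors of a few percent (the acceptance
script reports the 5-seed medians); the replicate count and panel size
were chosen as the smallest configuration at which jackknife noise is
clearly below the 15% tolerance used in testing.

## Pseudo-haploid calling and panel handling

The caller consumes per-SNP base counts (base quality filtering is assumed
done upstream). Sites with any observed base outside the SNP's two panel
alleles are discarded (the strictest reading of a triallelic filter:
applied to observed pileup bases against the panel annotation); at
retained sites one base is drawn with probability proportional to its
count and duplicated into a homozygous dosage; zero-depth sites are
missing.

Merging an ancient panel onto a modern reference intersects SNP ids and
then drops, in order: non-autosomal SNPs; modern populations with fewer
than 4 individuals; SNPs with zero minor allele frequency across retained
modern samples; SNPs whose ancient allele pair does not match the modern
pair. Allele-order swaps are recoded (dosage flipped); anything else is
dropped rather than strand-flipped, since A/T and C/G flips are
undecidable without external frequencies. A per-filter removal report is
returned.

LD pruning slides a window (default 200 SNPs, step 25) and greedily
removes, from the worst-correlated pair above the r² threshold, the member
with the lower minor allele frequency (ties: the later position) —
deterministic and sample-order invariant. Pairwise-complete samples are
used for r² under missingness. Two profiles ship: `admixture`
(200/25/0.5) and `pca` (200/25/0.2).

The EIGENSTRAT writer emits the standard geno/snp/ind triplet (genetic
positions in Morgans in the file, cM in memory). Because plain EIGENSTRAT
has no ploidy field, the ind-file population label carries a `:PH`/`:DIP`
suffix so round-trips preserve ploidy; files without the tag read as
diploid.

Molecular sex uses R_y = n_Y/(n_X + n_Y) with a normal-approximation 95%
CI and the conventional thresholds 0.016 (XX) and 0.075 (XY), both
exposed as arguments; intervals straddling the window are called
indeterminate.

## PCA projection

SNPs are centred by mean dosage μ and scaled by `sqrt(p(1−p))`, `p = μ/2`,
estimated from the modern fitting panel only (no Bayesian shrinkage of
the frequency estimate — a documented divergence from smartpca); missing
entries contribute zero after centring. Components come from the SVD of
the standardized matrix, with no outlier-removal iterations. Signs are
fixed by making each component's largest-magnitude loading positive.
Projection of an incomplete sample solves ordinary least squares on its
observed SNPs, which reduces to the exact score for complete data and
requires at least as many observed SNPs as components.

## ROH detection

Defaults: window 50 SNPs, at most 1 heterozygote per homozygous window,
≥ 25 SNPs and ≥ 500 kb per reported run, runs split at > 100 kb physical
gaps; a SNP is in a run when > 5% of its covering windows are homozygous.
These are an interpretation of common PLINK practice, all exposed in
`RohParams`. Summaries bin total length per sample with the short/long
boundary at 1.6 Mb and a consanguinity marker at 4 Mb. Chromosomes with
fewer SNPs than one window yield no calls. The planted-segment fixture
generator places SNPs uniformly (default 1 SNP / 10 kb), makes a SNP
heterozygous with probability `het_density/snp_per_bp` outside segments
(default 30% at `het_density = 3e-5`/bp) and `error_het_rate` inside;
detection recovers ≥ 90% of planted length at these densities, with edge
losses of roughly one window width and occasional sub-minimum tails next
to genotyping-error heterozygotes.

## Determinism and problem sizes

Every stochastic function takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical outputs.
Default analysis scales — 100k SNPs for statistic-level checks, 200k × 5
seeds for split-time fitting, 20 seeds at 20k SNPs for null calibrations —
were chosen as the smallest sizes at which |Z| > 3 effects and the stated
tolerances are comfortably resolved; all are arguments, not constants.

## Known limitations

- No linkage disequilibrium, mutation, ascertainment or damage modelling
  in the simulator; jackknife blocks are therefore conservative on
  synthetic data.
- Ancient samples are simulated at the present (sampling-date drift
  shortening is absorbed into the configured branch times).
- The split-time fitter assumes the topology and admixture proportions;
  it does not search graph space, and misspecified Ne rescales all times.
- merge does not strand-flip; pseudo-haploid panels cannot enter ROH or
  PCA fitting (by design).
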