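# Methods

This note documents the statistical models implemented in `aimpanel`, the
defaults and numerical conventions chosen where the methodology leaves
room, and what the synthetic-data generator does and does not emulate.

## Genotype data model

Genotypes are diploid, multi-allelic and unphased: per (individual, locus)
an unordered pair of integer allele codes, with missingness all-or-nothing
at the pair level. Allele codes are opaque integers — typically
fragment-size-like values — and no repeat-unit arithmetic is ever applied:
marker informativeness is measured purely by allele-frequency divergence,
not repeat structure. The on-disk missing code defaults to −9 (the
convention of the clustering-software ecosystem this format interoperates
with) and is configurable per dialect.

## Weir–Cockerham theta

For each locus and allele u, with r populations of (per-locus,
non-missing) sample sizes n_i, sample allele frequencies p̃_i and observed
per-allele heterozygote frequencies h̃_i (fraction of individuals carrying
exactly one copy of u):

    n̄  = Σ n_i / r
    n_c = (r n̄ − Σ n_i² / (r n̄)) / (r − 1)
    p̄  = Σ n_i p̃_i / (r n̄)
    s²  = Σ n_i (p̃_i − p̄)² / ((r − 1) n̄)
    h̄  = Σ n_i h̃_i / (r n̄)

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2

theta is always a ratio of sums: over alleles within a locus (θ_l) and
over loci and alleles for the multi-locus estimate — never a mean of
per-locus ratios. Conventions:

- **Negative estimates are reported as-is.** The moment estimator is
  unbiased but not range-constrained; clamping to [0, 1] would bias
  small-divergence comparisons. The parameter, not the estimate, lives in
  [0, 1].
- **Missing data** enter through per-locus, per-population non-missing
  sample sizes, so n_i varies across loci.
- **Monomorphic loci** (within the population set being compared) have
  zero denominator; they are flagged NaN per-locus and excluded from the
  sums. In pairwise comparisons this exclusion is pair-specific.
- Populations with no data at a locus are dropped from that locus; a locus
  needs ≥ 2 informative populations and n̄ > 1 to contribute.

## Admixture model and Gibbs sampler

The generative model: cluster k carries allele frequencies p_{k,l,·} with
a symmetric Dirichlet(λ) prior per locus (λ = 1 by default, a uniform
prior); individual i has ancestry q_i ~ Dirichlet(α); every gene copy
independently draws a cluster of origin z ~ Categorical(q_i) and then its
allele from p_{z,l,·}. Inference is unsupervised — population labels never
enter the sampler — with the Gibbs sweep:

1. z | P, Q: each copy resampled with P(z=k) ∝ q_{i,k} p_{k,l,j}.
2. P | z: p_{k,l,·} ~ Dirichlet(λ + n_{k,l,·}) from current assignment
   counts.
3. Q | z, α: q_i ~ Dirichlet(α + m_i) from per-individual counts.
4. α | Q: Metropolis step per cluster (or one shared step), symmetric
   normal proposal (default sd 0.025), uniform prior on (0, 10] with
   out-of-range proposals auto-rejected. "Separate α per cluster" is the
   default, allowing asymmetric admixture.

Missing genotypes are masked out of every count and the likelihood; they
are never imputed. The model score is

    lnP(D) = mean(log L) − var(log L) / 2

over kept post-burn-in samples, the standard approximation used by the
delta-K criterion downstream. Initialization: assignments uniform at
random, α = 1, then P and Q drawn once from their full conditionals.
Defaults are desk-scale (burn-in 5,000 / 5,000 kept sweeps, thinning 1);
production-scale chains (hundreds of thousands of sweeps) are purely a
config change. Runs are bit-reproducible per seed; the α update consumes
its generator in a fixed (proposal, acceptance-uniform) order per cluster
to keep that true.

Numerical guards: Dirichlet draws are realized as normalized gamma
variates with draws floored at 1e−300 before normalization, so log q never
hits −inf in the α update; a non-finite data log-likelihood aborts the run
with diagnostics rather than propagating.

## Cluster anchoring

Clusters are named after reference groups *after* inference: cluster k
gets the reference population with the largest mean membership in it.
Exact ties break to the lexicographically smallest group name and are
flagged. Two clusters may map to one group (the group's proportions are
then summed when reporting by ancestry), and the map is only meaningful
when references are present.

## Delta-K

With replicate lnP(D) values at each K of a contiguous sweep:
L′(K) = mean L(K) − mean L(K−1), |L″(K)| = |L′(K+1) − L′(K)|, and
ΔK = |L″(K)| / sd L(K) (sample sd, ddof 1). best_K is the argmax over
interior K; exact ties break toward the larger K (flagged), reading "the
uppermost K that can be clearly resolved" as preferring more structure on
ties. A sweep whose interior ΔK values are all exactly zero (perfectly
linear means) is reported unresolved with best_K = None. Zero replicate sd
at an interior K makes ΔK undefined there (flagged) without failing the
rest of the table. Sweeps may start at K = 1; that endpoint only serves as
the left neighbor of K = 2. Replicate seeds are master_seed + CRC32 of
"(K, replicate)", reduced mod 2³¹ and recorded in the sweep.

## Alignment of replicates

Similarity between two membership matrices is G = 1 − ‖Qa−Qb‖_F / √(2N)
(1 iff equal; 0 for disjoint one-hot rows). The first run is the
reference; each other run is permuted by the column order maximizing G —
exhaustive over K! permutations for K ≤ 8, otherwise the Hungarian
assignment on the column cross-product cost, which maximizes the same
objective. The heavier all-pairs search modes of dedicated alignment tools
are deliberately omitted: averaging same-K replicates only needs alignment
to one reference.

## False-SNP PCA

Each (locus, allele) pair becomes a binary presence/absence column
(dosage 0/1/2 available behind a flag for sensitivity checks). A missing
call masks the whole locus block for that individual; masked entries are
imputed to the column mean after which columns are mean-centered.
Optionally each column is scaled by √(p̂(1−p̂)) with p̂ the column
frequency, dropping monomorphic columns. Coordinates and eigenvalues come
from the SVD of the centered matrix (equivalently the spectral
decomposition of the individual × individual covariance, ddof 1), and
variance fractions are eigenvalues over the trace, so they sum to 1 over
all axes.

## Panel selection

Candidates are loci with global per-locus theta at or above a threshold
(inclusive), sorted descending. Stepwise reduction to target sizes retains
the top-N by global theta recomputed on the current panel at each step, so
panels are nested and sizes exact. Ties in theta break lexicographically
by locus name. Top-N-by-theta is the documented, reproducible default for
reduction; nothing in the cascade precludes substituting a user-supplied
ranking (e.g. one that also weighs assay practicality or pairwise
divergence).

## Synthetic data generator

Balding–Nichols in its multi-allelic Dirichlet form: ancestral frequencies
p_anc(l,·) ~ Dirichlet(γ,…,γ) with γ = 1 by default, and population
frequencies P(k,l,·) ~ Dirichlet(p_anc(l,·)·(1−F_k)/F_k), so F_k is the
expected fixation index of population k against the ancestral pool
(Var p = p(1−p)·F in the scalar reduction). Individuals are generated from
the same admixture model the sampler inverts: per gene copy, ancestry from
q_i, allele from that population's frequencies; missingness is
locus-level, independent at a configurable rate (default 0 — missingness
is opt-in, not a baked-in assumption). References carry one-hot q; cohorts
draw q from a fixed vector or a Dirichlet law and carry a self-declared
label that need not match genetic ancestry. Allele codes are emitted as
fragment-size-like integers (100 + 2·index) purely for realistic I/O.

The default preset mirrors the scale of a continental ancestry panel:
5 populations, 36 loci × 10 alleles, F = 0.2, 50 references per
population. Desk-scale study conditions used by the test and acceptance
suites: F_st calibration at F = 0.15 with 2 × 100 individuals over 36
loci (20 seeds); admixture recovery and the K sweep on 3 populations at
F = 0.25 with 50 references each plus 30 uniformly admixed queries; cohort
reporting on 2 populations at F = 0.2 with a Dirichlet(8, 2) cohort of 60
(mean ancestry 0.8/0.2) and one planted individual declared in the wrong
group.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: stepwise mutation and homoplasy of real
microsatellites, linkage between loci, genealogical (coalescent) noise,
genotyping artifacts such as allelic dropout or binning errors, and
non-Dirichlet ancestry laws in real cohorts. Results on synthetic data
certify the estimators invert their own generative assumptions, not that
those assumptions hold in any particular repository cohort.

## Cohort reporting

Group summaries report mean, sample sd, median, quartiles and 10th/90th
percentiles of each ancestry's proportion per declared group. Group
comparisons use Welch's unequal-variance two-sample t-test on the
per-individual proportions of one named ancestry; two zero-variance groups
with equal means return (t, p) = (0, 1) by convention. Discordance flags
fire when an individual's dominant inferred ancestry reaches a cutoff
(default 0.95) *and* differs from the ancestry its declared group maps to
under a user-supplied mapping — groups without a mapping are never
flagged. Proportions are always reported on the [0, 1] scale.

The pipeline driver analyzes references and queries jointly in one
unsupervised run at the selected K, anchors cluster labels from the
references afterwards, and derives every stage's randomness from one
recorded master seed, so a full run is bit-reproducible.

## Known limitations

- The sampler implements the basic admixture model only: no linkage model,
  no correlated-allele-frequency prior, no supervised/prior-population
  mode. Closely related populations (pairwise theta of a few percent) may
  merge into one cluster at desk-scale chain lengths.
- lnP(D)'s mean−½·variance form is a rough marginal-likelihood surrogate;
  it is used only through ΔK, never interpreted absolutely.
- Convergence is certified only by seed-replicate agreement; no formal
  diagnostics are computed.
- Column-mean imputation in PCA shrinks missing individuals toward the
  centroid; at high missingness this attenuates structure.
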