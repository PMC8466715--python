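# Methods

## Model overview

`haplarch` infers diploid local ancestry — the unordered pair of source
populations (p,q) of an individual's two haplotypes in each genomic
segment — and global ancestry proportions, from unphased genotypes. The
pipeline has two probabilistic layers:

* a **haplotype layer**: per genomic window, a localized
  haplotype-cluster model (leveled DAG) built from a phased background
  cohort, whose nodes are annotated with per-population occupancy
  probabilities from a labeled, unphased reference panel;
* an **ancestry layer**: a genome-wide hidden Markov model over
  unordered population pairs, with per-window-group emission
  likelihoods computed from the haplotype layer.

All probabilities of the haplotype layer are computed by a diploid
forward–backward whose hidden state is the *ordered* pair of DAG nodes
occupied by the two haplotypes; allele pairs at each SNP are constrained
to sum to the observed dosage (and summed over all four pairs where the
dosage is missing, which is how missing data and downsampling are
marginalised). Unordered quantities are obtained by symmetrisation; the
phase-symmetric combination
P_d(u,v|p,q) = ½(P_d(u|p)P_d(v|q) + P_d(u|q)P_d(v|p)) already accounts
for the exchangeability of the two haplotypes.

## Cluster-model construction

The model is built left to right: a single root holds all background
haplotypes; at each SNP every node splits by the observed allele (edge
probability = count fraction), and nodes at the new level are merged
when their empirical continuation distributions over the next
`min(merge_horizon, remaining)` SNPs differ by at most `merge_tolerance`
in total-variation distance. Candidate pairs are tested in descending
node-size order and merging is transitive (distributions are recomputed
and re-tested after every merge). Defaults `merge_horizon=3`,
`merge_tolerance=0.15` give the coarse-to-fine clustering the method
needs; `merge_tolerance=0` merges only exactly identical continuations,
which provably yields at least as many nodes as any positive tolerance
(tested), and for windows no longer than `merge_horizon+1` SNPs
reproduces the empirical haplotype distribution exactly (tested at D=4).

**Edge flooring.** A test haplotype absent from the background cohort
must not receive zero likelihood, so after construction each node's
unobserved allele receives a floored edge of probability `0.5/N`
(N = background haplotype count) before renormalisation. The floored
edge points at the most-populated node of the next level reachable with
that allele from any node, or back to the node's own child when the
training column is monomorphic. This choice (floor value and
destination) is a design decision of this package; downstream annotation
averaging and emission ratios require strictly positive support.

**Level convention.** Level d (0…D−1) is the state occupied just before
emitting the allele of the window's d-th SNP; level D is terminal and is
never annotated. This gives exactly one annotation row per SNP.

## Annotation

P_d(u|p) is the average, over all (downsampled) panel genotypes of
population p, of the diploid node marginal P_d(u|x) = Σ_v P_d(u,v|x).
Each panel genotype is replicated `downsample_reps` times (default 100)
with every SNP independently masked to missing with probability
`missing_rate` (default 0.2) — independent Bernoulli masking is our
concrete reading of "random downsampling". The effective count n_p
counts replicates, not individuals, and only the downsampled replicates
are averaged (the unmasked original is just the `missing_rate=0` special
case). Annotations from two panels over the same models merge by
count-weighted averaging, which can introduce new populations without
retraining.

## Emission likelihoods

Per window, P_d(t_w|u,v) = P_d(t_w,u,v)/P_d(u,v), where the pair prior
P_d(u,v) = P_d(u)P_d(v) comes from propagating the model forward with
unit emissions; node pairs with prior below 1e−300 are excluded. The
per-SNP population-pair values are averaged *unweighted* over the D SNPs
of the window. Implementation detail: the per-level value factorises as
aₚᵀ M a_q with M the posterior/prior ratio matrix and aₚ the annotation
column, so emissions for all pairs of a window cost one K×n matrix
sandwich per level, batched over test individuals. Everything is carried
as log-likelihood scaled by log P(t_w); per-group emissions are the sum
of member-window log emissions (a group shares one ancestry state, so
member windows are conditionally independent given the pair) and are
max-normalised, which adds a per-group constant that cannot change HMM
posteriors or Viterbi paths. The 5 SNPs shared by overlapping windows
enter both windows' emissions; no correction is applied.

## The ancestry HMM

States are the K(K+1)/2 unordered pairs. Transitions between adjacent
groups: stay with probability 1−τ; otherwise exactly one slot switches,
the new pair drawn with probability π_{p′,q′}/Z_{p,q} where Z sums π
over the pairs reachable by a single-slot change (multiset intersection
of size one — this excludes both the self pair and double switches such
as (p,p)→(q,q)). Chromosomes are independent; each starts from π.

**Parameter learning.** π (initialised uniform) and τ (initialised 0.01)
are updated with exactly 10 Baum–Welch iterations and no convergence
stop — a free τ tends to overfit toward many spurious ancestry switches,
and the fixed iteration count is the guard. The M-steps are exact for
this parameterisation:

* τ ← expected single-slot switches / within-chromosome adjacencies,
  clamped to [1e−6, 0.5];
* π maximises Q(π) = Σ_s c_s log π_s − Σ_s m_s log Z_s(π), with c the
  chromosome-start plus switch-target expectations and m the switch-out
  expectations, by an MM inner loop (tangent upper bound on each log Z_s,
  separable surrogate solved exactly on the simplex with a floor of
  `pi_floor=1e−6` per entry).

Because both steps are constrained maximisations started from the
current parameters, the data log-likelihood is non-decreasing across
iterations (a property the test suite checks on random instances).
A simpler occupancy-averaging π update was considered and rejected: it
is not an ascent step for this kernel and measurably decreases the
likelihood on random instances. The floor keeps every Z_s positive.

Global point estimates use the Viterbi path (ties broken toward the
lexicographically smallest pair, for determinism), with each group
weighted by its genetic length in cM and each slot of the pair counting
half. Credible intervals are equal-tailed empirical quantiles of the
same proportion over paths drawn by forward-filter/backward-sampling;
they condition on the fitted (π, τ) and reflect path uncertainty only,
so they are narrower than full-posterior intervals. The stationary
marginal π_p = Σ_q π_{p,q}/2-share is exposed as a diagnostic but is not
the reported estimate.

## Synthetic data

The simulator emulates the study design at desk scale:

* **Founder populations.** Ancestral frequencies uniform on (0.05,
  0.95); population frequencies Balding–Nichols (Beta with spread set by
  Fst), clamped to [0.01, 0.99]. Haplotypes are drawn in linkage
  equilibrium within populations: cluster models then derive their
  signal purely from allele-frequency differentiation, which exercises
  every algorithmic contract. Real-data features *not* emulated:
  background LD, mutation, genotyping error, realistic recombination-map
  heterogeneity — so passing benchmarks demonstrate the machinery is
  correct under the model's own assumptions, not field accuracy on array
  data.
* **Pedigrees.** A 2^G-founder pedigree with one descendant; each
  meiosis draws Poisson(L/100) crossovers per chromosome, uniform on the
  cM scale, no interference. Ancestry labels travel with the segments,
  so per-SNP truth is exact. Group-level truth is the label pair at the
  group's midpoint SNP (deterministic; groups are short relative to the
  segments of the G ≤ 4 pedigrees used). Global truth weights each SNP
  by its half-interval cM share.
* **Benchmarks.** `single_origin` (plain population samples), `paired`
  (one minority founder among 2^G, expected minority fraction 1/2^G,
  alternating which population is the minority), `three_way` (founder
  slots filled by largest-remainder rounding of explicit weights).

## Problem sizes and numerical choices

The recovery benchmarks in the test suite and `scripts/acceptance.py`
use K=2, Fst=0.2, 8,000 SNPs over two chromosomes at 0.05 cM spacing
(400 cM total), 200 background haplotypes, 50 panel members per
population, and 4 annotation downsampling replicates — a desk-scale
setting of the replicate count chosen because panels of 50 are already
well-averaged; the package default remains 100. Windows are 80 SNPs
overlapping by 5, groups of 4 (≈ 27 groups of ≈ 15 cM).

Other numerics: all window chains run with per-level scaling; emissions
floor at the smallest positive normal double before taking logs; the
Viterbi recursion takes the first (lexicographically smallest) argmax;
the model bundle stores probabilities as 64-bit floats in an `.npz`
archive with a JSON header and round-trips bit-identically; per-window
and per-individual RNG streams are spawned from one master seed so
results are independent of execution order.

## Known limitations

* Unphased output only: the method reports unordered pairs, not which
  haplotype carries which ancestry.
* Credible intervals condition on (π, τ) and understate uncertainty.
* τ is a single genome-wide scalar per individual.
* Group-midpoint truth labels slightly blur evaluation for segments
  shorter than a group.
* Linkage-equilibrium founders make the synthetic benchmarks easier
  than real cohorts with strong background LD.
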