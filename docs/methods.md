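# Methods

## Model

`kinphase` phases one parent s' of an F1 cross using only genotype data:
full ploidy-k genotypes for both parents and per-variant allele depths for p
progeny. All information flows through Mendelian transmission. A progeny of
two ploidy-k parents receives a uniformly random k/2-subset of each parent's
haplotypes, independently per parent (double reduction is not modelled).

For two variants i, j that are heterozygous in s', orient each site so that
dosages count the *minority* allele — the rarer of the two alleles among the
parents' 2k allele calls (ties keep REF as majority so runs are
reproducible). Simplex-nulliplex variants (dosage 1 in s', 0 in s'') carry a
single marker copy whose transmission can be traced; they are the default
variant class. The joint distribution of inherited minority dosages
(n_i, n_j) in a progeny depends on whether the markers share an s' haplotype:

* same haplotype: L_=(0,0) = L_=(1,1) = 1/2, splits are impossible;
* different haplotypes: L_≠(0,0) = L_≠(1,1) = (k/2−1)/(2(k−1)),
  L_≠(0,1) = L_≠(1,0) = k/(4(k−1)).

These closed forms are verified in-package against an exhaustive gamete
enumeration (all C(k, k/2) choices), with probabilities kept as exact
rationals so the two paths agree bit-for-bit. For simplex-simplex and
duplex-nulliplex pairs no closed form is published; the same enumeration is
the production path. The "same" hypothesis for dosage ≥ 2 marker sets is
defined as *sharing at least one haplotype*, with marker placements weighted
by their combinatorial multiplicity inside each hypothesis; the second
parent's placements are marginalized uniformly (it is uninformative about
s' co-location, and its marginal transmission is hypothesis-independent).
This hypothesis split is a design choice of this package.

Low coverage makes progeny genotypes unreliable, so depths are explained
directly: P(D | G=g) is Binomial(D(0)+D(1), g/k) evaluated at the minority
count, and the pair likelihood sums over genotype pairs weighted by the
priors, restricted per variant class to the genotype combinations the class
permits. The edge score is the log-likelihood ratio over the panel plus the
placement prior log(1/(k−1)) (two uniformly placed markers share one of k
haplotypes with probability 1/k). Scores use natural logs; the clustering
decisions depend only on signs and ordering, so the base is immaterial.

Recombination is deliberately left out of the priors: within a scoring
window (< 1% of a chromosome) crossovers affect few progeny, and modelling
them would require local recombination rates. The simulator can still
generate crossovers to probe this robustness.

## Numerical choices

* All probability arithmetic is in log space; sums of probabilities use
  log-sum-exp. Products over hundreds of progeny would underflow doubles.
* A progeny with zero coverage at either variant of a pair contributes
  exactly 0 (its pair likelihood reduces to a hypothesis-independent
  marginal); such samples are skipped rather than accumulated, keeping the
  all-zero-coverage score at exactly ln(1/(k−1)).
* One progeny's log-likelihood-ratio contribution is clamped to ±50 nats.
  At k=2 a sample with minority reads at both variants has likelihood
  exactly 0 under the "different haplotypes" hypothesis; unbounded single-
  sample evidence is unrealistic for data with any residual error rate.
* A sample whose depths have likelihood 0 under *both* hypotheses is
  skipped and counted (`ScoreGraph.n_unexplained_samples`).

## Sparse scoring pattern

Within a window of W intermediate phasable variants (default W = 1500,
distances counted in variant ranks, not base pairs), offsets follow four
phases: stride 1 for ⌈W/24⌉ offsets, stride 3 until ⌈W/12⌉ offsets in
total, stride 7 for the next ⌈W/24⌉, then stride 13 to the window edge.
At W = 1500 this yields exactly 250 partners per direction — one scored
pair in six. The pattern is truncated (not re-anchored) at chromosome ends.
Unscored pairs have implicit score 0 and no influence on clustering.

## Cluster editing

The partition minimizes cut positive weight plus kept negative weight
(equivalently maximizes within-cluster weight). The heuristic runs greedy
agglomeration (merge the pair of clusters with the largest positive
connecting weight) plus three pivot constructions as starting points, then
refines each with alternating sweeps of best-gain single-vertex moves and
whole-cluster merges; the lowest-cost result wins, with ties broken toward
more, smaller clusters (unjustified merges create switch errors; splits
only cost phased variants). Every accepted move strictly decreases cost, so
each run descends monotonically; sweep orders are fixed or seeded, making
the result reproducible. An exhaustive set-partition search (n ≤ 12) serves
as the optimality oracle: on random 8-vertex instances the heuristic's cost
is within 5% of optimal on ≥ 95% of instances.

## Interval scheduling

Each cluster c_i becomes a job spanning [min(c_i), max(c_i)] with profit
w_i = |c_i|. Two clusters may share a haplotype only if their intervals are
disjoint *and* separated by at least W variants — closer clusters were
connected by scored (or deliberately unscored negative) pairs, so placing
them together is unsupported. The selection maximizes Σ w_i over assigned
clusters subject to at most one haplotype per cluster and no conflicting
pair on a haplotype, solved as a 0/1 ILP with HiGHS. Conflicts of
W-inflated intervals form an interval graph, so the pairwise conflict
constraints are emitted as equivalent per-point clique constraints (one per
interval start and haplotype), which keeps the model small without changing
the feasible set; optimality is cross-checked against a brute-force oracle.
Haplotype labels are arbitrary under permutation, so they are canonicalized
by greedy recoloring in start-index order (lowest free label first). All
phased variants of a chromosome are emitted as a single phase set.

For a duplex variant the pair score localizes one marker copy; the second
copy is placed on the highest free haplotype slot deterministically. This
mirrors the observation that duplex-nulliplex variants trade completeness
for genotype accuracy.

## Evaluation metrics

* **Hamming rate (HR):** minimum over global haplotype-label permutations
  of the fraction of mismatching (haplotype, site) cells.
* **Switch error rate (SER):** dynamic program whose state at each site is
  a permutation matching predicted to true haplotypes consistent with the
  alleles there; the transition cost is the number of strands re-paired.
  The minimal total is normalized by k·(S−1). At k=2 this reduces to the
  classical diploid switch error. Sites with mismatching genotypes are
  excluded (switches are undefined there); fewer than two comparable sites
  give rate 0 by convention.
* **Wrong genotype rate (WGR):** fraction of phased sites whose predicted
  dosage differs from the truth.

All metrics are computed over predicted-phased sites only, matching the
sparse-output philosophy: the method prefers accuracy over completeness.

## Simulator

The generator emulates the targeted study design: a tetraploid cross with
~100 progeny at ~6x coverage, simplex-nulliplex markers placed uniformly on
s' haplotypes. Defaults: k = 4, m = 1000 variants, p = 100 progeny,
coverage ~ Poisson(6) per progeny-site (the standard shotgun model; only
the mean is specified by the study design), class mix 100% simplex-
nulliplex, recombination off, parental genotype errors off. Optional knobs:
class fractions (simplex-simplex, duplex-nulliplex, and an uninformative
"other" class emitted as dosage (2,1)), a per-interval crossover rate
(implemented as replacing one currently inherited s' haplotype by a
non-inherited one, which is what changes transmitted dosage), and a
parental dosage-error rate (±1, clipped) emulating genotype shifts from
low-coverage calling — with errors on, the emitted genotypes deviate from
the truth haplotypes by construction.

What the simulator does *not* model: read mapping bias, multiallelic sites,
linked coverage fluctuations, contamination or pedigree errors, and
double reduction. Passing tests therefore demonstrate correctness of the
inference machinery under the stated Mendelian model, not robustness to
every artifact of real sequencing data.

## Problem sizes used in the checks

The statistical checks run at deliberately modest sizes chosen to exercise
the claims: transmission frequencies at 20,000 gametes (3 Monte-Carlo
standard errors), end-to-end recovery at m = 1000 markers, p = 100, 6x over
three seeds (mean HR < 5%, SER < 2%, > 70% phased), and the panel-size
degradation trend at m = 300 over panels of 15/30/60/150 progeny with five
seeds each. Oracle comparisons use 100 random 8-vertex cluster-editing
instances and 10 random scheduling instances with ≤ 10 clusters.

## Known limitations

* Transmission priors assume autopolyploid ploidy-k meiosis with uniform
  gamete subsets; allopolyploids or preferential pairing violate this.
* Clusters are assigned one haplotype each, so dosage ≥ 2 variants are only
  partially localized.
* The scheduler's ≥ W separation rule means dense conflicting clusters are
  dropped rather than locally re-phased; completeness suffers where
  clustering is fragmented.
* Phase connectivity across assigned clusters on the same haplotype relies
  on the scheduling model, not on direct evidence spanning the gap.
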