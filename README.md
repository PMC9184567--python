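# kinphase

Genetic phasing of a polyploid parent from parental genotypes and low-depth
allele counts in a large F1 progeny panel.

Reconstructing the k haplotype sequences of a polyploid genome (e.g.
tetraploid potato, k = 4) is hard from reads alone. In a breeding context,
however, a deep-sequenced parent often comes with hundreds of progeny
sequenced at low depth (~6x). `kinphase` exploits Mendelian segregation in
such a panel: each progeny inherits k/2 of each parent's haplotypes, so the
joint transmission of two marker alleles tells us whether they sit on the
same parental haplotype. The package is aimed at plant-breeding and
population-genetics workflows that have a multi-sample VCF with two parents
and a progeny panel and want a sparse, high-confidence phasing of one
parent.

## Method

Let s' be the parent to phase and s'' the other parent, with dosages
G<sub>s,i</sub> ∈ {0..k} counting the minority allele (the rarer allele
among the two parents). The pipeline:

1. **Variant selection.** Keep biallelic variants heterozygous in s'.
   *Simplex-nulliplex* variants (G<sub>s'</sub>=1, G<sub>s''</sub>=0) carry a
   single traceable marker copy and are phased by default; simplex-simplex
   (1,1) and duplex-nulliplex (2,0) can be added.
2. **Bayesian pair scoring.** For markers i, j on haplotypes h_i, h_j of s',
   closed-form transmission priors L<sub>=</sub>(n_i, n_j) and
   L<sub>≠</sub>(n_i, n_j) give the probability that a progeny inherits
   (n_i, n_j) minority copies when h_i = h_j and h_i ≠ h_j respectively
   (e.g. L<sub>=</sub>(1,1) = 1/2, L<sub>≠</sub>(1,1) = (k/2−1)/(2(k−1))).
   Observed allele depths D enter through a binomial model
   P(D | G=g) = B<sub>pmf</sub>(D(0)+D(1), D(1), g/k), and the edge score is
   the log-likelihood ratio over all p progeny:
   w(i,j) = Σ<sub>s</sub> log P(D<sub>s</sub> | h_i=h_j) −
   Σ<sub>s</sub> log P(D<sub>s</sub> | h_i≠h_j) + log(1/(k−1)).
3. **Sparse scoring window.** Pairs are scored only within a window of
   W = 1500 intermediate phasable variants, thinned by a stride pattern
   (strides 1, 3, 7, 13) that scores one in six window pairs on average —
   250 partners per variant and direction at the default W.
4. **Cluster editing.** The scored graph is partitioned by weighted cluster
   editing (cost = positive edges cut + negative edges kept), using a
   local-search heuristic validated against an exhaustive oracle.
5. **Interval scheduling.** Clusters occupy intervals in variant space; a
   0/1 ILP selects a maximum-weight subset assignable to the k haplotypes
   such that clusters sharing a haplotype are ≥ W variants apart (weighted
   interval scheduling on k identical machines).

Accuracy is reported as switch error rate (SER), Hamming rate (HR) and
wrong genotype rate (WGR). A built-in simulator generates full crosses with
known haplotypes, so every stage is testable end to end.

## Worked example

```bash
# simulate a tetraploid cross: 150 simplex-nulliplex markers, 40 progeny at 6x
kinphase simulate --out-vcf sim.vcf --out-truth sim.truth.tsv \
    --variants 150 --progeny 40 --seed 5

# phase parent P1 using the progeny panel
kinphase phase --vcf sim.vcf --parent P1 --other-parent P2 \
    --progeny "$(python -c 'print(",".join(f"F{i+1:03d}" for i in range(40)))')" \
    --output phased.vcf --seed 1

# compare against the simulated truth
kinphase evaluate --vcf phased.vcf --truth sim.truth.tsv \
    --parent P1 --other-parent P2
```

The phase step logs

```
[phase] chr1: 150 phasable, 4 clusters, objective 150, phased fraction 1.000
```

i.e. cluster editing found exactly the four haplotype groups, and the
scheduler assigned all 150 markers. The evaluation prints

```
Phased  SER (%) WGR (%) HR (%)
150     0.00    0.00    0.00
```

meaning every phased marker landed on its true haplotype: no switches
between consecutive sites (SER), no dosage deviations (WGR), and no allele
placed on a wrong haplotype under the best label matching (HR).

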