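# Methods

`wgdloss` models how a whole-genome duplication (WGD) resolves: which
ancestral loci keep both copies, which lose one, from which parental
subgenome, and when on the species phylogeny.  This note documents the
model, the algorithms, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Pillars and double-conserved synteny

A *pillar* is one ancestral pre-WGD locus.  It is anchored by a gene of an
unduplicated outgroup genome and carries up to two homolog slots (the two
post-WGD *tracks*) per polyploid genome.  Pillars are built from a
filtered homology table; the default acceptance thresholds are an E-value
of at most 1e-8, amino-acid identity strictly above 60%, an alignment
covering at least 65% of the genes' mean length, and nonsynonymous
divergence strictly below 0.6.  Where an anchor has more than two
surviving homologs, the two assigned are the ones that maximise syntenic
support — adjacency to the genes assigned to neighbouring pillars —
found by a greedy assignment with hill-climbing refinement; ties break to
the lexicographically smallest gene id so runs are reproducible.
Per-genome pillar sets are merged on their anchors; a merged pillar is
retained only when every genome contributes a homolog and every assigned
homolog has at least one intact syntenic neighbour, a deliberately
conservative rule.

## Ancestral order by simulated annealing

Because the descendant genomes are rearranged, the pillar order of the
pre-WGD genome must be estimated.  An order is scored per genome and
track by walking consecutive *filled* slots: the synteny score counts
links whose two genes are contig-adjacent (orientation is ignored
throughout), and breakpoints are the complementary count, so
score + breakpoints always equals the number of evaluable links.  A break
whose link spans empty slots is attributed to the first junction it
crosses; with that convention the S1-style synteny file (`<->` both
tracks intact, `|` one broken, `X` both broken) reconciles exactly with
the breakpoint count (`|` counting 1, `X` counting 2).

The annealer minimises total breakpoints (strategy `naive`), optionally
from a greedy initialisation that chains pillars sharing many gene
adjacencies (`greedy`); `global_break` first maximises the number of
junctions with no break in any genome before switching to total-break
minimisation; `restricted` counts breaks only in a named genome pair,
which removes the bias toward placing rearrangements on the branch
shared by the two-species clade.  The schedule is geometric cooling
(T <- 0.95 T) from T = 2 with 100 x n_pillars proposals per temperature
(swap / reinsert / segment-reversal in equal parts), stopping after three
temperatures without an acceptance.  The schedule is a standard choice;
correctness is guarded by an exhaustive-search oracle on six-pillar
instances, where annealing attains the global optimum.

## The six-state loss model

States: U (undifferentiated duplicate), F (fixed duplicate), C1/C2
(converging states committed to keeping the subgenome-1 or subgenome-2
copy), S1/S2 (single copy, subgenome-1 or -2 gene surviving).  Rates, in
units of the base loss rate (so branch lengths are expected relative loss
intensities, the "alpha t" of the branch):

| transition | rate | meaning |
|---|---|---|
| U -> S1 | 1 | loss of the subgenome-2 copy (base rate) |
| U -> S2 | eps1 | loss of the subgenome-1 copy |
| U -> F | gamma | duplicate fixation |
| U -> C1 | delta | convergent-loss commitment to subgenome 1 |
| U -> C2 | delta * eps2 | commitment to subgenome 2 |
| Ck -> Sk | eta * (1 + eps1) | convergent loss completes |

F, S1, S2 are absorbing.  Constraining eps1, eps2 to (0, 1] pins
subgenome 1 as the less fractionated parent and breaks the label-swap
symmetry.  eta = 1 makes the total loss rate out of a converging state
equal the total loss rate out of U; with the eta * (1 + eps1) scaling that
equality is exact whatever the bias.  The algebra of the generator is a
design decision of this package: the published state diagram names the
states and parameters but not the rates, and all internal oracles are
self-consistent with this convention.

The model lattice spans WGD-n (no process), single additions WGD-b / -f /
-c, pairs, WGD-bcf, and the refinements WGD-bc^n f (no bias on C entry),
WGD-b2cf (separate eps for C entry) and WGD-bc^nbn f (additionally
eta = 1).  Model names are normalised so `WGD-bc_nbn_f` and
`WGD-bc^nbn^f` are the same model.

## Hidden subgenome tracking

Which physical track of a genome carries which subgenome is unknown and
changes along the genome wherever a rearrangement broke double-conserved
synteny.  Per genome a hidden bit tracks that assignment; along the
pillar order each genome's bit flips independently with probability
theta (a single global parameter), and the initial configuration is
uniform over all 2^n bit vectors.  A pillar's emission under a
configuration is the Felsenstein-pruning likelihood of its per-genome
copy states: a duplicated genome contributes (1,1,1,1,0,0); a single-copy
genome contributes an indicator on S1 or S2 according to the surviving
track and the genome's bit.  The root — the WGD event itself — is in
state U with probability one, matching the simulation protocol, and an
explicit root branch (unifurcating root) carries the shared loss period
to the first speciation.

The forward pass is exact; the per-genome flip structure factorises the
2^n x 2^n transition into n symmetric 2x2 operators, giving
O(n 2^n) work per pillar (a numba kernel with per-pillar scaling).
Forward-backward posteriors give, per pillar, the probability of each of
the 2^n orthology configurations; the reported confidence is the
posterior mass of the maximum-a-posteriori configuration relative to the
2^n - 1 alternatives.

## Fitting, tests and loss accounting

Free parameters (the model's free rates, optionally theta, optionally
log-parameterised branch lengths) are estimated by bounded L-BFGS-B from
three seeded starts (the first at the model's own values); bounds are
gamma, delta in [0, 50], eps in [1e-3, 1], eta in [1e-3, 50], theta in
[1e-6, 0.5], branch lengths in [1e-4, 10] on the log scale.  Fits with
zero free parameters short-circuit to a single likelihood evaluation.
Non-convergence is flagged on the result, never silent.  Likelihood-ratio
tests clamp the statistic at zero and use the upper chi-square tail;
note that freed *rate* parameters sit on a boundary under their null
(gamma, delta at 0; eps at 1), where the asymptotic null is the
0.5 chi2_0 + 0.5 chi2_1 mixture and the chi2_1 p-value is conservative.
The calibration suite therefore checks uniformity on an interior
parameter (eta = 1).

Expected per-branch losses marginalise, over tracking configurations
weighted by their posteriors, the edge posterior that the parent node is
still duplicated (U/F/C1/C2) while the child node is S1 or S2, summed
over pillars.  Entering S2 is the loss of the subgenome-1 (less
fractionated) copy, and vice versa.  Multiple hidden events within one
branch are not resolved: a loss is attributed to the branch on which the
endpoint states differ.

Gene-fate classification uses a posterior threshold of 0.85 (the
published confidence cut): `RootLosses` are single-copy pillars whose
state at the end of the root branch is single with posterior at or above
the threshold; `TipLosses` are single-copy pillars whose state at the
focal leaf's parent is still duplicated with the same confidence.  The
two conditions are mutually exclusive for any threshold above 0.5.

## The biased-fractionation test

A bias parameter fitted to unbiased data drifts below 1 because it
absorbs stochastic variation in loss patterns, so the test builds the
null distribution explicitly: fit WGD-f (fixation, no bias); simulate
replicates at its maximum-likelihood estimates, branch lengths and theta
included, re-using the data's synteny scaffold; fit WGD-bf to each
replicate (gamma and eps free, theta and branch lengths held at the
WGD-f estimates); and report the add-one Monte-Carlo tail probability
(1 + #{eps_null <= eps_obs}) / (n_ok + 1).  Failed replicate fits are
logged and excluded from the denominator.  The add-one form guarantees a
positive p and is the standard Monte-Carlo convention.  On smaller
datasets a null replicate's constrained MLE can sit exactly at eps = 1.

## Downstream statistics

Proportion contrasts use the 2x2 chi-square with the Yates continuity
correction (each |O - E| reduced by 0.5, floored at zero) — the variant
that reproduces all of the published zebrafish table p-values at their
printed precision — with an uncorrected option available.
Benjamini-Hochberg step-up adjustment controls the FDR across a family
(stages, anatomical locations).  Degenerate 2x2 tables (a zero margin)
return p = 1 with a warning.  Per-stage tests are 2x2 against all other
analysed genes; a flag drops zygote-expressed genes, whose strong
ohnolog deficit would otherwise leak into later-stage contrasts.

The metabolic network has reactions as nodes and an edge wherever two
reactions share a non-currency metabolite; currency metabolites (13 by
default in the generator) induce no edges.  Gene statistics (degree,
clustering coefficient, and betweenness as a raw count of shortest paths
through a node, not the normalised pair fraction) are means over the
reactions a gene maps to; unmapped genes are excluded and logged.  For
inference, ohnolog pairs are merged into single entities (union of the
two genes' reactions) before the label randomisation, preserving the
duplication structure; the p-value is two-sided on the absolute mean
difference, add-one over permutations.  Merging makes the entity values
non-exchangeable (pair averages have smaller variance), which renders
the randomisation conservative — never anticonservative — so the
uniformity calibration uses unmerged labels.

## The synthetic-data generator

`simulate_dataset` evolves every pillar from state U down the tree by
exact stochastic simulation (Gillespie), so the truth table records
every transition with its branch and time — needed to validate the
expected-loss accounting, not just endpoint states.  Tracking bits start
uniform per genome and flip between adjacent pillars with probability
theta; a flip severs both physical contigs, as a rearrangement would.
Contigs otherwise follow the configured ancestral contig lengths.  Gene
ids encode genome, pillar and subgenome (`sp03_p00017_s2`), making truth
joins trivial.  `replicate_from_template` re-simulates losses and flips
on a template's scaffold: contigs also end at the template's break
junctions (the left contig absorbing re-introduced duplicates), which is
how the bias test's null genomes retain the real data's block structure.
The default test tree has eight leaves in a two-clade shape (a two-leaf
clade and a six-leaf ladder) under an explicit root branch, all branch
lengths 0.3.

The generator emulates the loss process and the synteny-break process
that the inference machinery models, plus annotation tables with
configurable planted effects (expression-cluster rates default to the
observed zebrafish proportions — maternal 0.03 vs 0.04, pre-MBT 0.11 vs
0.17, zygotic 0.06 vs 0.05; essentiality 0.062 vs 0.145 among phenotyped
genes; a 150-reaction network over 60 ordinary and 13 currency
metabolites, with an optional degree-biased assignment of ohnolog
products).  It does **not** emulate: homology-search noise (every
homolog hit is clean and passes the filters), small-scale duplication,
gene-family fusion/fission, rearrangement operators beyond tracking
flips, sequence evolution or Ka values, or lineage-specific loss-rate
variation.  Green tests on synthetic data therefore demonstrate the
correctness of the algorithms under the model's own assumptions, not
robustness to annotation error or model misspecification in real
genomes.

## Problem sizes used in the test and acceptance runs

The statistical properties are checked at sizes chosen to make each
claim meaningful while keeping the default suite quick on one CPU:
exact-oracle equivalences at up to 3 pillars x 3 genomes (forward),
3 leaves (pruning) and 6 pillars (annealing vs exhaustive search);
bias-parameter recovery over 20 simulations of 5000 pillars on a 4-leaf
tree (median absolute error of eps1 below 0.05); bias-test power at
eps1 = 0.6 with 2000 pillars and 50 null simulations, and type-I rate
over 20 trials of 1000 unbiased pillars; LRT calibration over 200
replicates of 600 pillars on a 3-leaf tree; randomisation-test
calibration over 200 trials with 199 permutations.  Heavy calibration
loops fix branch lengths at their known values and use a single
optimiser start; the full three-start, branch-length-fitting
configuration is the library default.

## Known limitations

* A single global theta; no per-genome or per-region flip rates.
* Breakpoints are counted, not mapped to inversion/transposition events.
* Loss attribution cannot resolve multiple hidden events per branch.
* The eps <= 1 identifiability constraint means genuinely unbiased data
  fit eps at the boundary, and chi2-based LRTs on boundary parameters
  are conservative (use the simulation-based bias test instead).
* `build_pillars` is a heuristic (greedy + hill-climbing): it matches
  brute force on small instances and recovers simulated truth on clean
  data, but offers no optimality guarantee on adversarial inputs.
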