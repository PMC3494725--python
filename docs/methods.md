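# Methods

This note documents the models, reconstructions, parameter choices and
numerical conventions behind `coevoppi`, and what the synthetic-data tests
do and do not demonstrate.

## Problem setting

Proteins that function in the same macromolecular complex are under shared
selective pressure: losing one partner removes the selective benefit of
keeping the other (correlated gene loss), and changes in one partner's
evolutionary rate tend to be echoed by the other (correlated divergence).
The package turns these two signals into pair features — profile-based
association measures and tree-comparison statistics — and lets a
supervised ensemble learn how to weigh them against a gold standard of
known co-complexed pairs. The target regime is a single proteome compared
against on the order of a hundred related genomes, with a severe class
imbalance (<1% positive pairs).

## Tree features

**Patristic matrices.** Each gene tree is reduced to the matrix of
leaf-to-leaf path-length sums. Trees are treated as unrooted throughout:
patristic distances and agreement-subtree sizes do not depend on root
placement, so any rooting present in an input newick is carried along but
ignored by every metric. Missing branch lengths are defaulted to 0.0 with
a warning, which keeps path sums defined while flagging dubious input.

**mirror.** Pearson correlation of the strictly-upper-triangle entries of
the two matrices restricted to their common species, requiring at least 7
common species. Zero-variance inputs (e.g. star-like trees) make the
feature *missing*, never 0 — a deliberate convention: 0 would be a strong
statement ("uncorrelated evolution") that the data cannot support.

**tol-mirror.** The species-tree correction is applied as a residual
`r = d − s·t` with a single scaling factor `s = mean(d)/mean(t)` computed
on the common-species restriction (each protein matrix gets its own `s`).
The original correction protocol is cited in the literature but not
restated in a reproducible form; mean-ratio rescaling is the simplest
clock-consistent choice that removes the shared speciation signal exactly
when a protein evolves clock-like (residuals vanish identically for
`d ∝ t`, which the tests pin down). Residual means are exactly zero, so
the correction is idempotent. When both residual matrices are degenerate
(both proteins exactly proportional to the ToL) the feature is missing.

**Congruence index.** Topological similarity is the size of the maximum
agreement subtree (MAST): the largest leaf subset on which both unrooted
restricted topologies are identical (branch lengths ignored). The
implementation is exact, using the identity

    UMAST(T1, T2) = max over common leaves x of
                    1 + RMAST(T1 rooted at x with x removed,
                              T2 rooted at x with x removed)

with the standard rooted-MAST dynamic programme over node pairs. Fully
binary restrictions run through a numba kernel whose per-permutation cost
is O(k · n1 · n2); multifurcating inputs take a general Python route whose
internal-node step solves a maximum-weight bipartite matching (Hungarian
algorithm). Both routes agree with an exhaustive subset-enumeration oracle
on random tree pairs up to 12 leaves; multifurcations are compared as-is,
with no random resolution.

The published congruence index uses a closed-form null expectation for the
MAST size that is not reproduced here; instead the null is Monte-Carlo:
leaf labels of the second tree are shuffled (both topologies fixed, 999
permutations by default, minimum 100, seeded), and

    I_cong  = observed MAST / mean(null MAST)
    p-value = (1 + #{null ≥ observed}) / (n_permutations + 1)

The add-one estimator makes the p-value conservative and bounded below by
1/(n+1). Because the MAST statistic is discrete the p-values are
superuniform rather than exactly uniform; the calibration test therefore
smooths them with the standard randomized-p construction before applying
the Kolmogorov–Smirnov uniformity check. The feature slot carries the
index value; the p-value is logged, since a learner can use the index's
full dynamic range while the p-value saturates at its floor for any
clearly congruent pair.

**Validity bound.** All pairwise tree features (and the per-protein ones
against the ToL) require ≥ 7 common species — the smallest tree size for
which the congruence index was designed — and signal "not computable"
below it. The feature assembly converts that signal into a missing mask
and continues; one failed slot never contaminates the others.

## Profile features

The 2×2 contingency table (a = both present, b = A only, c = B only,
d = neither, N total) feeds 16 quality measures. Their printed formulas
were not recoverable from the source material, so each was reconstructed
from the measure's literature definition (direction A→B, with
P(A) = n_A/N etc.):

| measure | formula |
|---|---|
| confidence | a / n_A |
| recall | a / n_B |
| lift | a·N / (n_A·n_B) |
| dice | 2a / (n_A + n_B) |
| pearson (φ) | (ad − bc) / √(n_A·n_B·(N−n_A)·(N−n_B)) |
| GI (PMI) | log₂(a·N / (n_A·n_B)) |
| IQC (Cohen's κ) | (p_o − p_e)/(1 − p_e), p_o = (a+d)/N |
| confidenceCentered | confidence − P(B) |
| leastContradiction | (a − b) / n_B |
| jaccard | a / (n_A + n_B − a) |
| loevinger | (confidence − P(B)) / (1 − P(B)) |
| tec | 1 − b/a |
| LAP (Laplace) | (a + 1) / (n_A + 2) |
| GAN (Ganascia) | (a − b) / n_A |
| Zhang | (P(AB) − P(A)P(B)) / max(P(AB)(1−P(B)), P(B)(P(A)−P(AB))) |
| Pearl | P(A)·\|confidence − P(B)\| |

The nine asymmetric measures (centered confidence through Pearl, plus
jaccard for layout symmetry even though it is mathematically symmetric)
are emitted in both directions; confidence and recall are each other's
reversal and appear once each, giving 25 slots, plus n_A, n_B, n_AB as raw
count features (28 total). Every reconstruction is pinned by an exact
independence-null property (whenever a = n_A·n_B/N, lift = 1 and
φ = κ = PMI = centered confidence = Loevinger = Zhang = Pearl = 0) and by
a second scripted evaluation on 10⁴ random tables. "tec" carries no
citation in the source and is implemented as the example–counter-example
rate 1 − b/a. Note that Loevinger's index is bounded above by 1 but
unbounded below; constants in smoothed measures (e.g. the Laplace +1/+2)
follow the standard definitions and may differ from the original authors'
code. Undefined denominators produce missing values, serialized as the
literal `NA`.

## Ensemble and score fusion

The classifier bank follows the classic rule/decision-tree ensemble recipe
(weka's JRIP, PART, J48 and RandomForest plus a bagged version of each),
represented here by scikit-learn learners honouring the same contract — probabilistic binary classifiers, deterministic given
their seed: a depth-3 decision tree (compact rule list), an
entropy-criterion tree with leaf-size pruning (partial tree), a full
entropy tree, a 50-tree random forest, and generic bootstrap bagging
(10 bags) of each. The ensemble layer is agnostic to the bank's
composition; no attempt is made to reproduce weka-exact outputs.

Cross-validation is stratified 3-fold, repeated 30 times by default: per
class, shuffled members are dealt round-robin from a random starting fold,
so per-fold class proportions are within one example of exact. Every pair
is scored exactly once per repetition by models never trained on it
(verified structurally with a memorizing classifier). A classifier failure
aborts only its repetition. Missing feature values are median-imputed per
training fold; the imputation never sees test rows.

The published score-fusion and P_neg formulas are not recoverable from the
source; the reconstruction here — vote-partitioned confidence sums
normalized by the bank size, score = S_pos − S_neg, P_neg = mean(1 − P_c)
— is the most consequential reconstruction in the package. It satisfies
the documented qualitative behaviour (unanimous confident positives score
near 1; unanimous but marginal positives score much lower; the score is
antisymmetric under P_c → 1 − P_c), and a vote tie at exactly 0.5 counts
as positive. One known consequence: for unanimously-negative pairs P_neg
lies in (0.5, 1], so filter thresholds α ≤ 0.5 are maximally stringent —
a graded effect of smaller α values would require a different P_neg
definition, which the available description does not determine.

The aggregated score table reports, per pair, the mean/sd of the combined
score over repetitions, the modal positive-vote count, the mean P_neg, and
a filter verdict computed from those aggregates (kept iff the modal vote
count is positive or mean P_neg ≤ α).

## Evaluation

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counted ½; tied scores form a single ROC step so the
trapezoidal area equals this value to machine precision (checked against
brute-force counting up to n = 200). Precision@k/recall@k rank ties by the
canonical (lexicographically sorted) pair identity so curves are
deterministic. Repetition curves are averaged pointwise on a fixed
1001-point FPR grid; because "mean of per-repetition AUCs" and "AUC of the
mean curve" differ in general, both are reported.

## Synthetic data generator

One Yule (pure-birth) species tree (ultrametric; exponential inter-event
times, Exp(n·λ) stem before the present, so mean depth grows like
(H_n − 1)/λ) defines the genome panel. Per protein, every branch of the
species tree can carry a loss event (probability `loss_rate`, default
0.05) that removes the clade below it; the gene tree is the species tree
pruned to the surviving species with branch lengths multiplied by
per-branch lognormal rate factors (log-sd `rate_noise`, default 0.3); the
profile is the survival indicator. For an interacting pair, loss events
are shared with probability `rho_loss` (implemented as shared events at
rate ρ·loss_rate plus private events at rate (1−ρ)·loss_rate, keeping the
marginal per-branch loss probability at loss_rate to second order) and a
fraction `rate_coupling` of the log-rate variance is shared. Defaults
(ρ = 0.9, coupling 0.8) correspond to strong coevolution; 115 genomes and
a ~0.8% positive fraction echo the curated complex-membership regime the
method targets. Draws whose proteins would fail the pipeline's ≥7-species
rules are resampled (bounded retries), so requested pair counts are
delivered.

Deliberate simplifications: no gene duplication, no horizontal transfer,
no sequence-level evolution, and each simulated pair introduces two fresh
proteins, so the pair graph is a disjoint matching rather than the dense
graph of a real proteome (no shared proteins across pairs, no transitive
complex structure, no homology-induced redundancy). Passing end-to-end
tests therefore demonstrate that the pipeline recovers planted coevolution
signal of the kind it models — not that real proteomes carry signal of
that strength, nor that the feature set is robust to duplication or
transfer.

## Problem sizes used in the validation suite

End-to-end parameter recovery uses 1,000 pairs (100 positive — a 10%
positive fraction chosen for test power, unlike the production default),
30 genomes, 100 congruence permutations and 2 CV repetitions; with strong
coupling the combined score must reach AUC ≥ 0.85 and be within 0.02 of
every single classifier's AUC, and with zero coupling land in
[0.45, 0.55]. Oracle suites run exact-MAST agreement on 50 random pairs
(8–12 leaves), quality-measure agreement on 10⁴ random tables, and filter
properties on 10⁴ random confidence tables. The acceptance script draws
1,000 replicates of 200 examples (20 positives) with label-independent
uniform scores and reports their mean AUC.

## Known limitations

- The score fusion, P_neg and Table-4 formulas are literature-based
  reconstructions (flagged above), not transcriptions of the original
  code; constants may differ.
- MAST is exact but its cost grows quickly; beyond ~40-leaf common
  restrictions the permutation null dominates run time (the default 999
  permutations can be lowered to 100 for large scans).
- The α filter has no graded effect below α ≈ 0.5 under the implemented
  P_neg (see above).
- The simulator's independence between pairs means classifier performance
  estimates carry no correction for the correlated-pair structure of real
  interactomes.
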