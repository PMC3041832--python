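# Methods

## Estimation model

All predictors in this package are maximum expected gain (MEG) estimators
on constrained binary spaces.  A predictive space Y is a subset of
{0, 1}ⁿ cut out by componentwise constraints: one-to-one, non-crossing
aligned pairs for alignments; single-partner, nested, min-loop-respecting
base pairs for secondary structures; displayable bipartition sets for
trees.  Given a distribution P(θ) on the space, the γ-centroid estimator
maximizes the expectation of the pointwise gain γ·TP + TN.  Three facts
organize the whole implementation, and each is enforced empirically by the
test suite rather than assumed:

1. **Reduction.**  The MEG estimator for the general four-weight gain
   α₁·TP + α₂·TN − α₃·FP − α₄·FN has the same argmax as the γ-centroid
   with γ = (α₁+α₄)/(α₂+α₃).  (Tested on hundreds of seeded random
   (α, distribution) pairs by exhaustive evaluation.)
2. **Decomposition.**  The prediction-dependent part of the expected gain
   is Σ_{i∈y} [(γ+1)·p_i − 1] over the marginals p_i.  The additive
   constant is never computed anywhere in the package; every objective the
   code reports is this first term, which is sufficient for all argmax
   comparisons and is what the DP tables accumulate.
3. **Consensus.**  For γ ≤ 1 the collection {i : p_i > 1/(γ+1)} is a valid
   member of each space handled here (the cutoff is ≥ 1/2, and two
   conflicting components cannot both carry marginal probability above
   1/2), and it attains the DP optimum.  Cutoff comparisons are strict:
   components exactly at the threshold contribute zero gain and are
   excluded, giving a deterministic, minimal prediction.

## Probability engines

The marginals consumed by the decoders are computed exactly, in log space
(logsumexp accumulation throughout; probability checks at 1e-9):

* **Pair HMM** (aligned-base posteriors): a symmetric three-state model
  (M/X/Y) with explicit start handling; the start distribution is reused
  as the end weights.  This end convention is a package choice, not a
  modeling claim.  Posteriors are computed by forward-backward; summing
  the M-state posterior marginalizes over gap orderings, yielding a
  distribution over alignments proper.  Defaults (match self-transition
  0.9, gap open 0.05 per side, gap extend 0.3, uniform emissions) live in
  `src/gcentroid/data/pairhmm_default.yaml`, not in code.
* **Miyazawa model**: P(θ) ∝ exp(S(θ)/T) with a substitution score per
  aligned pair (default +2 match / −1 mismatch) and a per-unaligned-residue
  gap score (default −1), T = 1.  The partition recursion conditions on
  whether and where the current x-residue is matched, evaluated with a
  running scan, so each alignment-as-pair-set is counted exactly once in
  O(mn); marginals use the forward/reverse split at each candidate pair.
* **Structure Boltzmann model**: P(θ) ∝ exp(score(θ)/T) with an additive
  per-pair score (defaults GC = 3, AU = 2, GU = 1, all other combinations
  disallowed; T = 1; min_loop = 3).  Base-pairing marginals come from
  inside-outside on the unambiguous grammar
  Z(i,j) = Z(i+1,j) + Σ_k w(i,k)·Z(i+1,k−1)·Z(k+1,j).  A full
  nearest-neighbor energy model is deliberately out of scope: every
  downstream estimator operates on the marginals alone, and externally
  computed matrices can be loaded from TSV when realism matters.

Alphabets are handled case-insensitively with T/U unified for RNA;
unknown residues emit uniformly.

## Decoders

* Alignment: three-way Needleman-Wunsch-style recursion over rewards
  (γ+1)p − 1; traceback prefers diagonal > up > left on ties.  A generic
  pointwise-reward engine also realizes the Holmes/ProbCons decoder
  (reward p) and the AMA decoder (reward 2p with gap-factor-weighted gap
  rewards).
* Folding: Nussinov-style interval recursion with cases i-unpaired,
  j-unpaired, pair (i,j), bifurcation — tried in exactly that order at
  traceback, so outputs are reproducible.  Pairs with non-positive reward
  are never introduced, making the DP and threshold views coincide.
  min_loop is enforced at prediction time even if the probability engine
  used a different value; offending matrix entries are ignored with a
  warning.
* Comparison decoders (MEA-style structure gain with pair reward 2γp and
  unpaired reward q_i; AMA) are provided only to demonstrate their bias
  against γ·TP + TN; they share the interval/lattice DP machinery.

## Representative and homolog-supported estimators

A prediction representing N sequences maximizes the homogeneous gain —
the single-sequence gain summed over members — whose expectation under
the product distribution equals N times the γ-centroid objective under
the *averaged* marginal matrix in column coordinates.  Per-sequence
probabilities are computed on degapped sequences and mapped into columns;
a row contributes 0 wherever it has a gap; averages are uniform over rows
(weighted averaging is a deliberate non-feature of the default path).
The averaging normalizes by the total number of rows N, not by the number
of non-gap rows per column pair; the mapped-evaluation convention this
implies is exactly what the product-space brute-force test checks.

PCT uses Z = {x, y} ∪ homologs with identity self-match matrices, so the
empty-homolog case reduces bit-exactly to the direct estimator.
Homolog-supported folding transports each homolog's base-pair matrix
through the match matrices (P·p·Pᵀ restricted to the upper triangle) and
averages with the target's own matrix.  Both are factorized
approximations to an intractable marginalization and can, with
inconsistent *external* inputs, break the marginal-matrix invariants:
violations above 1e-6 are errors, smaller ones are clipped with a
warning, and before any γ ≤ 1 shortcut output the code asserts both the
matrix invariants and space membership of the collected set.

## Trees

Trees are consumed, never sampled: the input is a Newick sample (one tree
per line, branch lengths ignored).  Bipartitions are canonicalized as the
side excluding the alphabetically first taxon; trivial single-taxon
splits are excluded everywhere (they are common to all trees on the same
taxa and cancel in every distance).  The γ ≤ 1 consensus collects splits
with frequency > 1/(γ+1) ≥ 1/2 — automatically pairwise compatible, and
laminar after canonical orientation — and assembles the unique
multifurcating tree displaying exactly them.  γ > 1 is refused: no
efficient search of tree space is available for it, and the package does
not pretend otherwise.

## Synthetic data

Test matrices are always marginals of an actual random distribution over
the enumerated space (uniform, Boltzmann-weighted with Gaussian scores of
scale 1.5, or sparse-support variants), never i.i.d. entries, so the
structural preconditions of the consensus results genuinely hold.  Tree
samples are random binary topologies by sequential leaf attachment with
internal edges contracted at probability 0.3, mimicking multifurcating
posterior samples.  What these fixtures do *not* emulate: realistic
evolutionary correlation between sequences, Turner-model energy
landscapes, or MCMC autocorrelation in tree samples — passing tests
certify the estimator algebra and the exactness of the dynamic programs,
not biological accuracy of the default score models.

## Numerical choices and problem sizes

Enumeration guards: alignments up to length 8 per side, structures up to
length 14 — full oracle suites run in seconds.  Oracle ties break to the
first member in lexicographic order of sorted index sets; DP/oracle
equivalence is always asserted on objective value, not on the argmax
itself.  Log-partition values remain finite at sequence length 500 for
all three engines (asserted).  Oracle comparisons use 1e-9; bit-exact
identities (consensus vs DP at γ ≤ 1, reduction laws) use 0 or 1e-12.
The test suite checks DP-vs-oracle equivalence on structures up to
L = 12 (sparse support keeps the oracle fast) and alignments up to 5×5;
the acceptance script re-measures 150 such instances (structures up to
L = 9, alignments up to 5×5), 100 reduction
instances, 30 consensus instances, engine checks on six enumerable
sequences, and an 11-tree, 5-taxon consensus — sizes chosen so the whole
script completes in seconds while every space involved is still exactly
enumerable.

## Known limitations

Pseudoknots are excluded by the structure space itself.  No affine-gap
scoring exists in the decoders (gap structure enters only through the
probability model).  The structural-alignment (Sankoff-model) estimator
family and automatic γ selection by expected MCC/F-score are out of
scope; expected-MCC-type objectives involve ratios of counts and do not
decompose over marginals, which is precisely the computational advantage
the γ-centroid family keeps.
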