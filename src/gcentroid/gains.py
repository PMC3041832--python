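"""Gain-function algebra for maximum-expected-gain estimation.

The general four-weight gain on a binary space is

    G(theta, y) = a1*TP + a2*TN - a3*FP - a4*FN,

which reduces (same argmax) to the gamma-centroid gain

    G_gamma(theta, y) = gamma*TP + TN    with  gamma = (a1 + a4) / (a2 + a3).

The expected gamma-centroid gain decomposes over the marginalized
probabilities p_i = P(theta_i = 1) as

    E[G_gamma] = sum_{i: y_i = 1} [(gamma + 1) p_i - 1]  +  const(theta),

so a component is worth predicting exactly when p_i > 1/(gamma + 1), and for
gamma <= 1 the componentwise collection (consensus estimator) is guaranteed
to stay inside the predictive space.  The additive constant is never
computed here; all objective comparisons are on the prediction-dependent
first term only.

Two comparison gains from the literature are included for bias analysis:
the Do et al. MEA-style structure gain (pair reward 2*gamma*p, unpaired
reward q) and the alignment-metric-accuracy (AMA) gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .matrices import BasePairProbMatrix, MatchProbMatrix
from .spaces import BinaryPrediction, MarginalVector

__all__ = [
    "GainSpec",
    "gamma_from_alphas",
    "threshold",
    "centroid_objective",
    "consensus_estimate",
    "mea_do_objective",
    "ama_objective",
]


@dataclass
class GainSpec:
    """Either a four-weight gain (alpha mode) or a gamma-centroid gain."""

    alpha: tuple | None = None
    gamma: float | None = None

    def __post_init__(self):
        if (self.alpha is None) == (self.gamma is None):
            raise ValueError("specify exactly one of alpha or gamma")
        if self.alpha is not None:
            if len(self.alpha) != 4 or any(a < 0 for a in self.alpha):
                raise ValueError("alpha must be four nonnegative weights")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def mode(self) -> str:
        return "alpha" if self.alpha is not None else "gamma"

    def evaluate(self, theta: BinaryPrediction, y: BinaryPrediction) -> float:
        if theta.dimension != y.dimension:
            raise ValueError("dimension mismatch between theta and y")
        tp = len(theta.on_indices & y.on_indices)
        fp = len(y.on_indices) - tp
        fn = len(theta.on_indices) - tp
        tn = theta.dimension - tp - fp - fn
        if self.alpha is not None:
            a1, a2, a3, a4 = self.alpha
            return a1 * tp + a2 * tn - a3 * fp - a4 * fn
        return self.gamma * tp + tn


def gamma_from_alphas(gain: GainSpec) -> float:
    """The gamma whose centroid gain shares the four-weight gain's argmax."""
    if gain.mode != "alpha":
        raise ValueError("gamma_from_alphas needs an alpha-mode GainSpec")
    a1, a2, a3, a4 = gain.alpha
    if a2 + a3 == 0:
        raise ValueError("alpha2 + alpha3 must be positive to reduce to gamma")
    return (a1 + a4) / (a2 + a3)


def threshold(gamma: float) -> float:
    """Marginal-probability cutoff 1/(gamma+1) above which a component
    contributes positive expected gain."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 1.0 / (gamma + 1.0)


def centroid_objective(pred: BinaryPrediction, p, gamma: float) -> float:
    """Prediction-dependent term of the expected gamma-centroid gain:
    sum over predicted components of (gamma+1)*p_i - 1."""
    getter = p.__getitem__ if isinstance(p, MarginalVector) else (
        lambda idx: p.get(idx, 0.0)
    )
    return math.fsum((gamma + 1.0) * getter(idx) - 1.0 for idx in pred.on_indices)


def consensus_estimate(p: MarginalVector, gamma: float, space) -> BinaryPrediction:
    """Componentwise collection {i : p_i > 1/(gamma+1)}, valid for gamma <= 1.

    The cutoff comparison is strict; components exactly at the cutoff
    contribute zero gain and are excluded.  The result is validated against
    the space — a violation signals marginals inconsistent with it.
    """
    if not 0 < gamma <= 1:
        raise ValueError("consensus estimator requires 0 < gamma <= 1")
    cut = threshold(gamma)
    on = frozenset(idx for idx, prob in p.items() if prob > cut)
    pred = BinaryPrediction(on, p.dimension)
    if not pred.validate(space):
        raise ValueError(
            "consensus collection violates the predictive space; the "
            "marginals cannot come from a distribution on it"
        )
    return pred


def mea_do_objective(
    pred: BinaryPrediction, p: BasePairProbMatrix, gamma: float
) -> float:
    """Expected MEA-style structure gain of Do et al. (comparison only):
    2*gamma*sum of predicted pair probabilities plus the unpaired
    probability q_i of every position left unpaired."""
    q = p.unpaired_probs()
    paired = set()
    total = 0.0
    for i, j in pred.on_indices:
        total += 2.0 * gamma * p[i, j]
        paired.add(i)
        paired.add(j)
    total += math.fsum(q[i] for i in range(p.length) if i not in paired)
    return total


def ama_objective(
    pred: BinaryPrediction, p: MatchProbMatrix, gap_factor: float
) -> float:
    """Expected alignment-metric-accuracy gain (comparison only):
    2 per expected correctly aligned pair plus gap_factor per expected
    correctly gapped position."""
    qx, qy = p.gap_probs()
    aligned_x = {i for i, _ in pred.on_indices}
    aligned_y = {j for _, j in pred.on_indices}
    total = math.fsum(2.0 * p[i, j] for i, j in pred.on_indices)
    total += gap_factor * math.fsum(
        qx[i] for i in range(p.len_x) if i not in aligned_x
    )
    total += gap_factor * math.fsum(
        qy[j] for j in range(p.len_y) if j not in aligned_y
    )
    return total
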