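"""Shared fixtures and independent brute-force oracles.

The oracles here never call the dynamic-programming code paths they are
used to check: they enumerate spaces, paths or Boltzmann ensembles
directly.
"""

import math

import numpy as np
import pytest

from gcentroid.spaces import AlignmentSpaceSpec, StructureSpaceSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def brute_pairhmm_posterior(x, y, params):
    """Match posteriors by enumerating every gapped path of the pair HMM."""
    m, n = len(x), len(y)
    results, total = {}, 0.0

    def rec(i, j, state, prob, pairs):
        nonlocal total
        if i == m and j == n:
            w = prob * params.init[state]  # end weights reuse init
            total += w
            for pr in pairs:
                results[pr] = results.get(pr, 0.0) + w
            return
        for s2 in "MXY":
            t = params.trans[state].get(s2, 0.0)
            if t == 0.0:
                continue
            if s2 == "M" and i < m and j < n:
                rec(i + 1, j + 1, s2, prob * t * params.em_match(x[i], y[j]),
                    pairs + [(i, j)])
            elif s2 == "X" and i < m:
                rec(i + 1, j, s2, prob * t * params.em_gap("X", x[i]), pairs)
            elif s2 == "Y" and j < n:
                rec(i, j + 1, s2, prob * t * params.em_gap("Y", y[j]), pairs)

    if m > 0 and n > 0:
        rec(1, 1, "M", params.init["M"] * params.em_match(x[0], y[0]), [(0, 0)])
    if m > 0:
        rec(1, 0, "X", params.init["X"] * params.em_gap("X", x[0]), [])
    if n > 0:
        rec(0, 1, "Y", params.init["Y"] * params.em_gap("Y", y[0]), [])
    if total == 0.0:
        raise ValueError("zero total likelihood in oracle")
    return {k: v / total for k, v in results.items()}


def brute_miyazawa_marginals(x, y, model):
    """Aligned-pair marginals by Boltzmann enumeration of the alignment space."""
    space = AlignmentSpaceSpec(len(x), len(y))
    Z, marg = 0.0, {}
    for member in space.members():
        pairs = sorted(member.on_indices)
        score = sum(model.s(x[i], y[j]) for i, j in pairs)
        score += model.gap_score * (len(x) + len(y) - 2 * len(pairs))
        w = math.exp(score / model.temperature)
        Z += w
        for pr in pairs:
            marg[pr] = marg.get(pr, 0.0) + w
    return {k: v / Z for k, v in marg.items()}


def brute_boltzmann_bpp(x, model):
    """Base-pair marginals by Boltzmann enumeration of the structure space."""
    space = StructureSpaceSpec(len(x), model.min_loop)
    Z, marg = 0.0, {}
    for member in space.members():
        pairs = sorted(member.on_indices)
        lw = 0.0
        ok = True
        for i, j in pairs:
            if (x[i], x[j]) not in model.pair_scores:
                ok = False
                break
            lw += model.pair_scores[(x[i], x[j])]
        if not ok:
            continue
        w = math.exp(lw / model.temperature)
        Z += w
        for pr in pairs:
            marg[pr] = marg.get(pr, 0.0) + w
    return {k: v / Z for k, v in marg.items()}


def expected_gain(dist, y, gain):
    """Exact expectation of a gain over an enumerated distribution."""
    g = gain.evaluate if hasattr(gain, "evaluate") else gain
    return math.fsum(p * g(th, y) for th, p in zip(dist.members, dist.probs))
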