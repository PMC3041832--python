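"""Probability engines producing the marginal matrices the estimators consume.

Three engines are provided, all exact and all computed in log space:

* :func:`pairhmm_match_probs` — posterior aligned-base probabilities under a
  three-state pair HMM (match M, gap-in-y X, gap-in-x Y), by the
  forward-backward algorithm.  The HMM distributes mass over gapped paths;
  summing path posteriors for the M state at (i, j) marginalizes the gap
  patterns away and yields a distribution over the alignment space proper.
* :func:`miyazawa_match_probs` — exact marginals of the Boltzmann
  distribution P(theta) ∝ exp(S(theta)/T) over the alignment space, where
  S is a substitution score summed over aligned pairs plus a per-residue
  gap score.  The partition-function recursion conditions on the rightmost
  aligned pair so each alignment (as a set of pairs) is counted exactly
  once.
* :func:`boltzmann_basepair_probs` — exact base-pairing marginals of
  P(theta) ∝ exp(score(theta)/T) over the structure space, score additive
  over pairs, by an inside-outside algorithm on the unambiguous
  Nussinov-style grammar  Z(i,j) = Z(i+1,j) + sum_k w(i,k) Z(i+1,k-1) Z(k+1,j).

The per-pair additive structure score (defaults GC=3, AU=2, GU=1, others
disallowed, T=1) is deliberately simple: every estimator downstream operates
on the marginals alone, and externally computed matrices can be loaded for
realism through :func:`gcentroid.matrices.load_matrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.special import logsumexp

from .matrices import BasePairProbMatrix, MatchProbMatrix

__all__ = [
    "PairHMMParams",
    "MiyazawaModel",
    "RnaScoreModel",
    "pairhmm_match_probs",
    "miyazawa_match_probs",
    "boltzmann_basepair_probs",
    "normalize_seq",
]

NEG_INF = -math.inf
_STATES = ("M", "X", "Y")


def normalize_seq(seq: str, rna: bool = True) -> str:
    """Uppercase; unify T->U for RNA alphabets (U->T for DNA)."""
    seq = seq.upper()
    return seq.replace("T", "U") if rna else seq.replace("U", "T")


# ---------------------------------------------------------------------------
# pair HMM


@dataclass
class PairHMMParams:
    """Three-state pair HMM.  Emission tables may be None, meaning uniform
    over the alphabet; unknown residues always emit uniformly.  The start
    distribution doubles as the end weights (explicit start/end handling)."""

    alphabet: str
    init: dict
    trans: dict
    emit_match: dict | None = None
    emit_gap_x: dict | None = None
    emit_gap_y: dict | None = None

    def __post_init__(self):
        if abs(sum(self.init.values()) - 1.0) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")
        for s in _STATES:
            row = self.trans.get(s, {})
            if abs(sum(row.values()) - 1.0) > 1e-12:
                raise ValueError(f"transitions out of state {s} must sum to 1")
        for table, arity in (
            (self.emit_match, 2),
            (self.emit_gap_x, 1),
            (self.emit_gap_y, 1),
        ):
            if table is not None and abs(math.fsum(table.values()) - 1.0) > 1e-9:
                raise ValueError("emission table must sum to 1")

    @classmethod
    def default(cls) -> "PairHMMParams":
        text = (
            resources.files("gcentroid").joinpath("data/pairhmm_default.yaml")
        ).read_text()
        cfg = yaml.safe_load(text)
        return cls(alphabet=cfg["alphabet"], init=cfg["init"], trans=cfg["trans"])

    # emission lookups; fall back to uniform for unknown residues
    def em_match(self, a: str, b: str) -> float:
        if self.emit_match is None:
            return 1.0 / len(self.alphabet) ** 2
        if a not in self.alphabet or b not in self.alphabet:
            return 1.0 / len(self.alphabet) ** 2
        return self.emit_match.get((a, b), 0.0)

    def em_gap(self, state: str, a: str) -> float:
        table = self.emit_gap_x if state == "X" else self.emit_gap_y
        if table is None or a not in self.alphabet:
            return 1.0 / len(self.alphabet)
        return table.get(a, 0.0)


def _log(x: float) -> float:
    return math.log(x) if x > 0 else NEG_INF


def pairhmm_match_probs(
    x: str, y: str, params: PairHMMParams | None = None
) -> MatchProbMatrix:
    """Posterior probability that x_i aligns to y_j, by forward-backward."""
    if params is None:
        params = PairHMMParams.default()
    x = normalize_seq(x, rna="U" in params.alphabet)
    y = normalize_seq(y, rna="U" in params.alphabet)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("pair HMM requires two non-empty sequences")

    linit = {s: _log(params.init.get(s, 0.0)) for s in _STATES}
    ltr = {
        s: {t: _log(params.trans.get(s, {}).get(t, 0.0)) for t in _STATES}
        for s in _STATES
    }
    lend = linit  # end weights reuse the start distribution

    lem_m = np.full((m + 1, n + 1), NEG_INF)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            lem_m[i, j] = _log(params.em_match(x[i - 1], y[j - 1]))
    lem_x = np.array([NEG_INF] + [_log(params.em_gap("X", a)) for a in x])
    lem_y = np.array([NEG_INF] + [_log(params.em_gap("Y", b)) for b in y])

    S = {"M": 0, "X": 1, "Y": 2}
    F = np.full((3, m + 1, n + 1), NEG_INF)

    def incoming(i, j, target):
        """log sum of (state at (i,j)) -> target transition mass."""
        if i == 0 and j == 0:
            return linit[target]
        vals = [F[S[s], i, j] + ltr[s][target] for s in _STATES]
        return logsumexp(vals)

    for i in range(m + 1):
        for j in range(n + 1):
            if i >= 1 and j >= 1:
                F[0, i, j] = incoming(i - 1, j - 1, "M") + lem_m[i, j]
            if i >= 1:
                F[1, i, j] = incoming(i - 1, j, "X") + lem_x[i]
            if j >= 1:
                F[2, i, j] = incoming(i, j - 1, "Y") + lem_y[j]

    lZ = logsumexp([F[S[s], m, n] + lend[s] for s in _STATES])
    if lZ == NEG_INF:
        raise ValueError(
            "total pair HMM likelihood is zero: the emission tables leave "
            "no admissible path (emission gap)"
        )

    B = np.full((3, m + 1, n + 1), NEG_INF)
    for s in _STATES:
        B[S[s], m, n] = lend[s]
    for i in range(m, -1, -1):
        for j in range(n, -1, -1):
            if i == m and j == n:
                continue
            for s in _STATES:
                vals = []
                if i + 1 <= m and j + 1 <= n:
                    vals.append(ltr[s]["M"] + lem_m[i + 1, j + 1] + B[0, i + 1, j + 1])
                if i + 1 <= m:
                    vals.append(ltr[s]["X"] + lem_x[i + 1] + B[1, i + 1, j])
                if j + 1 <= n:
                    vals.append(ltr[s]["Y"] + lem_y[j + 1] + B[2, i, j + 1])
                B[S[s], i, j] = logsumexp(vals) if vals else NEG_INF

    post = np.zeros((m, n))
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = F[0, i, j] + B[0, i, j] - lZ
            post[i - 1, j - 1] = math.exp(v) if v > -700 else 0.0
    return MatchProbMatrix(post)


def pairhmm_log_likelihood(x: str, y: str, params: PairHMMParams | None = None):
    """Log total likelihood (partition value) of the pair HMM; exposed for
    numerical-stability checks."""
    if params is None:
        params = PairHMMParams.default()
    # reuse the forward pass cheaply by calling the full routine on short
    # inputs; for long inputs run forward only
    x = normalize_seq(x, rna="U" in params.alphabet)
    y = normalize_seq(y, rna="U" in params.alphabet)
    m, n = len(x), len(y)
    linit = {s: _log(params.init.get(s, 0.0)) for s in _STATES}
    ltr = {
        s: {t: _log(params.trans.get(s, {}).get(t, 0.0)) for t in _STATES}
        for s in _STATES
    }
    lem_x = np.array([NEG_INF] + [_log(params.em_gap("X", a)) for a in x])
    lem_y = np.array([NEG_INF] + [_log(params.em_gap("Y", b)) for b in y])
    F = np.full((3, m + 1, n + 1), NEG_INF)
    S = {"M": 0, "X": 1, "Y": 2}
    for i in range(m + 1):
        for j in range(n + 1):
            if i >= 1 and j >= 1:
                prev = (
                    linit["M"]
                    if (i - 1, j - 1) == (0, 0)
                    else logsumexp([F[S[s], i - 1, j - 1] + ltr[s]["M"] for s in _STATES])
                )
                F[0, i, j] = prev + _log(params.em_match(x[i - 1], y[j - 1]))
            if i >= 1:
                prev = (
                    linit["X"]
                    if (i - 1, j) == (0, 0)
                    else logsumexp([F[S[s], i - 1, j] + ltr[s]["X"] for s in _STATES])
                )
                F[1, i, j] = prev + lem_x[i]
            if j >= 1:
                prev = (
                    linit["Y"]
                    if (i, j - 1) == (0, 0)
                    else logsumexp([F[S[s], i, j - 1] + ltr[s]["Y"] for s in _STATES])
                )
                F[2, i, j] = prev + lem_y[j]
    return logsumexp([F[S[s], m, n] + linit[s] for s in _STATES])


# ---------------------------------------------------------------------------
# Miyazawa model


@dataclass
class MiyazawaModel:
    """Boltzmann alignment model: P(theta) ∝ exp(S(theta)/T) with
    S = sum of substitution scores over aligned pairs + gap_score per
    unaligned residue."""

    scores: dict = field(default_factory=dict)
    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_score: float = -1.0
    temperature: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def s(self, a: str, b: str) -> float:
        if (a, b) in self.scores:
            return self.scores[(a, b)]
        if (b, a) in self.scores:
            return self.scores[(b, a)]
        return self.match_score if a == b else self.mismatch_score


def _miyazawa_partition(x: str, y: str, model: MiyazawaModel) -> np.ndarray:
    """lZ[i, j]: log partition over alignments of x[:i] and y[:j].

    Unambiguous recursion conditioning on whether x_i is aligned and, if so,
    to which y_l; evaluated with a running scan so the whole table is
    O(m n).  Weight per unaligned residue is exp(gap/T)."""
    m, n = len(x), len(y)
    T = model.temperature
    lg = model.gap_score / T
    lm = np.full((m + 1, n + 1), NEG_INF)
    for i in range(1, m + 1):
        for l in range(1, n + 1):
            lm[i, l] = model.s(x[i - 1], y[l - 1]) / T
    lZ = np.full((m + 1, n + 1), NEG_INF)
    lZ[0, :] = np.arange(n + 1) * lg
    lZ[:, 0] = np.arange(m + 1) * lg
    for i in range(1, m + 1):
        run = NEG_INF  # logsum over l<=j of lm[i,l] + lZ[i-1,l-1] + (j-l)*lg
        for j in range(1, n + 1):
            run = np.logaddexp(run + lg, lm[i, j] + lZ[i - 1, j - 1])
            lZ[i, j] = np.logaddexp(lg + lZ[i - 1, j], run)
    return lZ


def miyazawa_partition_logZ(x: str, y: str, model: MiyazawaModel | None = None):
    model = model or MiyazawaModel()
    return _miyazawa_partition(x, y, model)[len(x), len(y)]


def miyazawa_match_probs(
    x: str, y: str, model: MiyazawaModel | None = None
) -> MatchProbMatrix:
    """Exact aligned-pair marginals of the Miyazawa Boltzmann distribution.

    p(i, j) = Zpre(i, j) * exp(s(x_i, y_j)/T) * Zsuf(i+1, j+1) / Z, since an
    alignment containing the pair splits uniquely at it."""
    model = model or MiyazawaModel()
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("sequences must be non-empty")
    T = model.temperature
    fwd = _miyazawa_partition(x, y, model)
    bwd_rev = _miyazawa_partition(x[::-1], y[::-1], model)
    lZ = fwd[m, n]
    post = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            v = (
                fwd[i, j]
                + model.s(x[i], y[j]) / T
                + bwd_rev[m - i - 1, n - j - 1]
                - lZ
            )
            post[i, j] = math.exp(v) if v > -700 else 0.0
    return MatchProbMatrix(post)


# ---------------------------------------------------------------------------
# Boltzmann structure model


@dataclass
class RnaScoreModel:
    """Per-pair additive Boltzmann score over the structure space.

    Watson-Crick and wobble pairs get positive scores; every other residue
    combination is disallowed (probability zero downstream)."""

    pair_scores: dict = field(
        default_factory=lambda: {
            ("G", "C"): 3.0,
            ("C", "G"): 3.0,
            ("A", "U"): 2.0,
            ("U", "A"): 2.0,
            ("G", "U"): 1.0,
            ("U", "G"): 1.0,
        }
    )
    temperature: float = 1.0
    min_loop: int = 3

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def log_weight(self, a: str, b: str) -> float:
        if (a, b) not in self.pair_scores:
            return NEG_INF
        return self.pair_scores[(a, b)] / self.temperature


def _lse(arr) -> float:
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        return NEG_INF
    hi = arr.max()
    if hi == NEG_INF:
        return NEG_INF
    return hi + math.log(np.exp(arr - hi).sum())


def _structure_inside(lw: np.ndarray, min_loop: int) -> np.ndarray:
    """Inside table of the unambiguous grammar; lZ[i][j] over interval i..j,
    with empty intervals contributing log 1 = 0."""
    L = lw.shape[0]
    lZ = np.zeros((L + 2, L + 2))  # padded; empty intervals = 0

    def z(i, j):
        return 0.0 if i > j else lZ[i, j]

    for span in range(0, L):
        for i in range(0, L - span):
            j = i + span
            terms = [z(i + 1, j)]
            for k in range(i + min_loop + 1, j + 1):
                if lw[i, k] == NEG_INF:
                    continue
                terms.append(lw[i, k] + z(i + 1, k - 1) + z(k + 1, j))
            lZ[i, j] = _lse(terms)
    return lZ


def boltzmann_partition_logZ(x: str, model: RnaScoreModel | None = None) -> float:
    model = model or RnaScoreModel()
    x = normalize_seq(x, rna=True)
    L = len(x)
    lw = np.full((L, L), NEG_INF)
    for i in range(L):
        for j in range(i + model.min_loop + 1, L):
            lw[i, j] = model.log_weight(x[i], x[j])
    return _structure_inside(lw, model.min_loop)[0, L - 1] if L else 0.0


def boltzmann_basepair_probs(
    x: str, model: RnaScoreModel | None = None
) -> BasePairProbMatrix:
    """Exact base-pairing marginals by inside-outside on the Nussinov-style
    grammar.

    The outside table O(i, j) accumulates the derivation weight of every
    context in which the interval nonterminal Z(i, j) occurs; the pair
    (i, k) is produced exactly once per structure, so

        p(i, k) = w(i,k) Z(i+1,k-1) * sum_{j>=k} O(i,j) Z(k+1,j) / Z.
    """
    model = model or RnaScoreModel()
    x = normalize_seq(x, rna=True)
    L = len(x)
    ml = model.min_loop
    lw = np.full((L, L), NEG_INF)
    for i in range(L):
        for j in range(i + ml + 1, L):
            lw[i, j] = model.log_weight(x[i], x[j])
    values = np.zeros((L, L))
    if L == 0 or np.all(lw == NEG_INF):
        return BasePairProbMatrix(values)

    lZ = _structure_inside(lw, ml)

    def z(i, j):
        return 0.0 if i > j else lZ[i, j]

    lO = np.full((L, L), NEG_INF)
    lO[0, L - 1] = 0.0
    # dependencies all have strictly larger span: iterate spans descending
    for span in range(L - 2, -1, -1):
        for i in range(0, L - span):
            j = i + span
            terms = []
            # child of the "i-1 unpaired" case of Z(i-1, j)
            if i >= 1:
                terms.append(lO[i - 1, j])
            # left child of pair (i-1, j+1) in Z(i-1, j'), j' >= j+1
            if i >= 1 and j + 1 < L and lw[i - 1, j + 1] != NEG_INF:
                for jp in range(j + 1, L):
                    terms.append(lO[i - 1, jp] + lw[i - 1, j + 1] + z(j + 2, jp))
            # right child of pair (a, i-1) in Z(a, j), a <= i-2
            if i >= 2:
                for a in range(0, i - 1):
                    if lw[a, i - 1] == NEG_INF:
                        continue
                    terms.append(lO[a, j] + lw[a, i - 1] + z(a + 1, i - 2))
            lO[i, j] = _lse(terms)

    lZtot = lZ[0, L - 1]
    for i in range(L):
        for k in range(i + ml + 1, L):
            if lw[i, k] == NEG_INF:
                continue
            ctx = _lse([lO[i, j] + z(k + 1, j) for j in range(k, L)])
            v = lw[i, k] + z(i + 1, k - 1) + ctx - lZtot
            values[i, k] = math.exp(v) if v > -700 else 0.0
    return BasePairProbMatrix(values)
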