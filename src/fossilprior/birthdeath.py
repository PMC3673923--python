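"""Transition probabilities of the homogeneous linear birth-death process.

For a process with per-lineage birth rate p and death rate q (per Ma), write
r = p - q and define the classical auxiliary quantities

    alpha(t) = q (e^{rt} - 1) / (p e^{rt} - q)     (extinction probability of
                                                    one lineage by time t)
    beta(t)  = p (e^{rt} - 1) / (p e^{rt} - q)

with the equal-rates limit alpha = beta = pt / (1 + pt).  The transition
probability from a lineages to n lineages after time t is

    P(0 | a) = alpha^a
    P(n | a) = sum_{j=1}^{min(a,n)} C(a,j) C(n-1,j-1)
               alpha^{a-j} beta^{n-j} [(1-alpha)(1-beta)]^j      (n >= 1)

Everything is computed in log space (log-binomials via log-gamma, the j-sum
via log-sum-exp) because lineage counts reach the hundreds in the missing-
history likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

#: |p - q| * t below this uses the equal-rates closed form.
EPS_EQUAL_RATES = 1e-10

#: Tail rule for open-ended sums over lineage counts: stop once this many
#: consecutive terms each contribute less than TAIL_REL of the running total.
TAIL_RUN = 5
TAIL_REL = 1e-12

_LOG_EXPM1_SWITCH = 30.0  # above this, expm1(x) overflows usefully; use asymptotics


def _log_expm1(x: float) -> float:
    """log(e^x - 1) for x > 0 without overflow."""
    if x > _LOG_EXPM1_SWITCH:
        return x + math.log1p(-math.exp(-x))
    return math.log(math.expm1(x))


@dataclass(frozen=True)
class BDParams:
    """Birth and death rates per lineage per Ma."""

    birth: float
    death: float

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be non-negative")

    @property
    def r(self) -> float:
        """Net diversification rate."""
        return self.birth - self.death

    def log_alpha_beta(self, t: float) -> tuple[float, float, float, float]:
        """(log alpha, log beta, log(1-alpha), log(1-beta)) at time t >= 0."""
        if t < 0:
            raise ValueError("t must be non-negative")
        p, q = self.birth, self.death
        if t == 0 or (p == 0 and q == 0):
            return -np.inf, -np.inf, 0.0, 0.0
        r = p - q
        if abs(r) * t < EPS_EQUAL_RATES:
            # equal-rates limit with the mean rate; relative cancellation in
            # the general form is O(|r| t) here
            x = 0.5 * (p + q) * t
            if x == 0:
                return -np.inf, -np.inf, 0.0, 0.0
            la = lb = math.log(x) - math.log1p(x)
            l1 = -math.log1p(x)
            return la, lb, l1, l1
        rt = r * t
        if r > 0:
            log_em1 = _log_expm1(rt)
            if rt > _LOG_EXPM1_SWITCH:
                log_den = math.log(p) + rt + math.log1p(-(q / p) * math.exp(-rt))
            else:
                log_den = math.log(p * math.expm1(rt) + r)
            la = (math.log(q) + log_em1 - log_den) if q > 0 else -np.inf
            lb = math.log(p) + log_em1 - log_den
            l1a = math.log(r) + rt - log_den
            l1b = math.log(r) - log_den
            return la, lb, l1a, l1b
        # r < 0: work with u = e^{rt} in (0, 1); denominator q - p u > 0
        log_neg_em1 = math.log(-math.expm1(rt))
        log_den = math.log(q - p * math.exp(rt))
        la = math.log(q) + log_neg_em1 - log_den
        lb = (math.log(p) + log_neg_em1 - log_den) if p > 0 else -np.inf
        l1a = math.log(-r) + rt - log_den
        l1b = math.log(-r) - log_den
        return la, lb, l1a, l1b


def bd_alpha_beta(params: BDParams, t: float) -> tuple[float, float]:
    """(alpha, beta) at time t."""
    la, lb, _, _ = params.log_alpha_beta(t)
    return math.exp(la), math.exp(lb)


def _xlog(coef, log_val):
    """coef * log_val with the convention 0 * (-inf) = 0."""
    coef = np.asarray(coef, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(coef == 0, 0.0, coef * log_val)
    return out


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_counts(a: int, n: int) -> None:
    if a < 1 or a != int(a):
        raise ValueError(f"starting count a must be a positive integer, got {a}")
    if n < 0 or n != int(n):
        raise ValueError(f"ending count n must be a non-negative integer, got {n}")


def log_prob_transition(a: int, n: int, params: BDParams, t: float) -> float:
    """log P(a -> n, t)."""
    _validate_counts(a, n)
    la, lb, l1a, l1b = params.log_alpha_beta(t)
    if n == 0:
        return a * la
    j = np.arange(1, min(a, n) + 1)
    terms = (
        _log_binom(a, j)
        + _log_binom(n - 1, j - 1)
        + _xlog(a - j, la)
        + _xlog(n - j, lb)
        + j * (l1a + l1b)
    )
    return float(logsumexp(terms))


def prob_transition(a: int, n: int, params: BDParams, t: float) -> float:
    """P(a -> n, t): probability of starting with a lineages and ending with n."""
    return math.exp(log_prob_transition(a, n, params, t))


def prob_extinction(a: int, params: BDParams, t: float) -> float:
    """Probability all a independent lineages are extinct by time t: alpha^a."""
    _validate_counts(a, 0)
    la, _, _, _ = params.log_alpha_beta(t)
    return math.exp(a * la)


def prob_survival(a: int, params: BDParams, t: float) -> float:
    """1 - alpha^a, the complement of complete extinction."""
    _validate_counts(a, 0)
    la, _, _, _ = params.log_alpha_beta(t)
    return -math.expm1(a * la)


# ---------------------------------------------------------------------------
# Vectorised forms used by the likelihood and the invariants


def log_prob_from_one(a: np.ndarray, params: BDParams, t: float) -> np.ndarray:
    """log P(1 -> a, t) for an integer array a >= 1.

    The single-ancestor case is geometric: (1-alpha)(1-beta) beta^{a-1}.
    """
    a = np.asarray(a)
    la, lb, l1a, l1b = params.log_alpha_beta(t)
    return l1a + l1b + _xlog(a - 1, lb)


def log_prob_transition_to(a: np.ndarray, n: int, params: BDParams, t: float) -> np.ndarray:
    """log P(a_i -> n, t) for an array of starting counts a_i >= 1."""
    a = np.asarray(a)
    out = np.empty(a.shape, dtype=float)
    la, lb, l1a, l1b = params.log_alpha_beta(t)
    for i, ai in enumerate(a.ravel()):
        if n == 0:
            out.ravel()[i] = ai * la
            continue
        j = np.arange(1, min(int(ai), n) + 1)
        terms = (
            _log_binom(ai, j)
            + _log_binom(n - 1, j - 1)
            + _xlog(ai - j, la)
            + _xlog(n - j, lb)
            + j * (l1a + l1b)
        )
        out.ravel()[i] = logsumexp(terms)
    return out


def log_prob_transition_from(a: int, n: np.ndarray, params: BDParams, t: float,
                             chunk: int = 4096) -> np.ndarray:
    """log P(a -> n_i, t) for an array of ending counts n_i >= 0."""
    _validate_counts(a, 0)
    n = np.asarray(n)
    la, lb, l1a, l1b = params.log_alpha_beta(t)
    out = np.empty(n.shape, dtype=float)
    flat = n.ravel()
    res = out.ravel()
    for lo in range(0, flat.size, chunk):
        blk = flat[lo : lo + chunk]
        jmax = max(min(a, int(blk.max())), 1)
        j = np.arange(1, jmax + 1)
        with np.errstate(invalid="ignore"):
            terms = (
                _log_binom(a, j)[None, :]
                + _log_binom(np.maximum(blk[:, None] - 1, 0), j[None, :] - 1)
                + _xlog(a - j, la)[None, :]
                + _xlog(np.maximum(blk[:, None] - j[None, :], 0), lb)
                + (j * (l1a + l1b))[None, :]
            )
            terms = np.where(
                j[None, :] <= np.minimum(a, blk)[:, None], terms, -np.inf
            )
        res[lo : lo + blk.size] = logsumexp(terms, axis=1)
        zero = blk == 0
        if zero.any():
            res[lo : lo + blk.size][zero] = a * la
    return out


def truncated_normalization(a: int, params: BDParams, t: float,
                            rel: float = TAIL_REL, run: int = TAIL_RUN,
                            max_n: int = 10_000_000) -> tuple[float, int]:
    """Sum P(a -> n, t) over n = 0, 1, 2, ... under the tail rule.

    Returns (total, n_reached).  Used by the normalization invariant; the sum
    should approach 1 as the tail rule lets it extend.
    """
    total = prob_extinction(a, params, t)
    n_hi = 0
    block = 256
    small_run = 0
    while n_hi < max_n:
        ns = np.arange(n_hi + 1, n_hi + block + 1)
        probs = np.exp(log_prob_transition_from(a, ns, params, t))
        for v in probs:
            total += v
            if total > 0 and v < rel * total:
                small_run += 1
                if small_run >= run:
                    return float(total), int(n_hi)
            else:
                small_run = 0
            n_hi += 1
        block = min(2 * block, 65536)
    return float(total), int(n_hi)
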