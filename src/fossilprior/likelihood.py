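"""The missing-history likelihood curve L(t1).

Given clade-level birth/death rates, the extant diversity N, the observed
diversity n in the oldest occupied bin, a per-interval preservation rate R
and the age t_min of the base of that bin, the likelihood of a missing
interval of length t1 (time between the true origin of the clade and its
oldest preserved fossil occurrence) marginalises the unknown true first-bin
diversity a under binomial preservation:

    L(t1) = sum_{a=n}^{a_cap} P(1 -> a, t1) * Binom(n | a, R) * P(a -> N, t2)

with t2 the observed interval from the first fossil occurrence to the
present (taken as t_min, i.e. the first occurrence is placed at the bin
base).  The sum is truncated by a tail rule once additional terms stop
contributing.  Under a uniform prior on t1 the area-normalised curve is the
posterior shape used downstream as a node-age prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom as _binom

from .birthdeath import (
    BDParams,
    TAIL_REL,
    log_prob_from_one,
    log_prob_transition_to,
)
from .errors import CurveFailure

#: Grid points with likelihood below this fraction of the running maximum
#: count toward the automatic stopping rule of the curve builder.
CURVE_FLOOR_REL = 1e-6
CURVE_FLOOR_RUN = 10
CURVE_CEILING_FACTOR = 10.0

#: Mass of the latent-diversity sum above a = N at the curve mode that
#: triggers the applicability warning (true early diversity may exceed N).
A_CAP_MASS_WARN = 0.01


@dataclass
class CladeCalibrationInput:
    """Fixed quantities entering the missing-history likelihood.

    t_min is the age (Ma) of the base of the oldest occupied bin; it is both
    the zero offset of the t1 axis and, by default, the observed interval t2.
    a_cap bounds the latent first-bin diversity and defaults to the extant
    diversity N, the model's stated domain of applicability.
    """

    origination: float
    extinction: float
    extant_diversity: int
    observed_first_bin_diversity: int
    preservation: float
    t_min: float
    t2: float | None = None
    a_cap: int | None = None
    condition_on_survival: bool = False

    def __post_init__(self):
        if self.extant_diversity < 1:
            raise ValueError("extant diversity must be >= 1")
        if self.a_cap is None:
            self.a_cap = self.extant_diversity
        if not 1 <= self.observed_first_bin_diversity <= self.a_cap:
            raise ValueError(
                f"observed first-bin diversity n={self.observed_first_bin_diversity} "
                f"must satisfy 1 <= n <= a_cap={self.a_cap}"
            )
        if not 0 < self.preservation <= 1:
            raise ValueError("preservation rate must be in (0, 1]")
        if self.t_min <= 0:
            raise ValueError("t_min must be positive")
        if self.t2 is None:
            self.t2 = self.t_min

    @property
    def params(self) -> BDParams:
        return BDParams(self.origination, self.extinction)


@dataclass
class LikelihoodCurve:
    """Discretised L(t1) on a regular grid starting at t1 = 0.

    ``values`` are raw likelihoods (they can underflow to 0 for extreme
    inputs); ``normalized_values`` are computed from the log-likelihoods and
    rescaled to unit trapezoidal area, and are the representation used for
    quantiles, fitting and reporting.
    """

    offset: float
    grid: np.ndarray
    log_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.all(np.isneginf(self.log_values)):
            raise CurveFailure(
                "likelihood curve is identically zero; the inputs are "
                "inconsistent (e.g. n too large for the preservation rate)"
            )
        m = float(np.max(self.log_values))
        y = np.exp(self.log_values - m)
        area = float(np.trapezoid(y, self.grid))
        self.normalized_values = y / area
        self.metadata.setdefault("log_max", m)

    @property
    def values(self) -> np.ndarray:
        with np.errstate(under="ignore"):
            return np.exp(self.log_values)

    @property
    def ages(self) -> np.ndarray:
        """Grid translated to absolute ages (t1 + offset), Ma."""
        return self.grid + self.offset


def binomial_observation(n: int, a: int, R: float) -> float:
    """P(observe n of a true lineages | per-interval preservation R)."""
    if a < 1:
        raise ValueError("true diversity a must be >= 1")
    if n > a:
        raise ValueError(f"observed diversity n={n} cannot exceed true diversity a={a}")
    return float(_binom.pmf(n, a, R))


def _log_binom_pmf(n: int, a: np.ndarray, R: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lc = gammaln(a + 1) - gammaln(n + 1) - gammaln(a - n + 1)
    if R >= 1.0:
        with np.errstate(divide="ignore"):
            return np.where(a == n, 0.0, -np.inf)
    return lc + n * math.log(R) + (a - n) * math.log1p(-R)


class _LikelihoodEngine:
    """Shared state for evaluating L at many t1 values on one input.

    Caches log P(a -> N, t2), which does not depend on t1, and grows the
    latent-diversity window on demand.
    """

    def __init__(self, inp: CladeCalibrationInput, chunk: int = 64):
        self.inp = inp
        self.chunk = chunk
        self._log_t2 = np.empty(0)
        self._log_obs = np.empty(0)
        self._a_hi = inp.observed_first_bin_diversity - 1

    def _extend(self, a_hi: int) -> None:
        a_hi = min(a_hi, self.inp.a_cap)
        if a_hi <= self._a_hi:
            return
        a_new = np.arange(self._a_hi + 1, a_hi + 1)
        lt2 = log_prob_transition_to(
            a_new, self.inp.extant_diversity, self.inp.params, self.inp.t2
        )
        lobs = _log_binom_pmf(self.inp.observed_first_bin_diversity, a_new,
                              self.inp.preservation)
        self._log_t2 = np.concatenate([self._log_t2, lt2])
        self._log_obs = np.concatenate([self._log_obs, lobs])
        self._a_hi = a_hi

    def log_likelihood_at(self, t1: float) -> tuple[float, int]:
        """(log L(t1), a_reached)."""
        inp = self.inp
        n = inp.observed_first_bin_diversity
        if t1 == 0:
            # P(1 -> a, 0) = delta_{a,1}: the sum collapses (or vanishes)
            if n > 1:
                return -np.inf, n
            self._extend(n)
            return float(
                math.log(inp.preservation) + self._log_t2[0]
            ), n
        log_total = -np.inf
        a_lo = n
        a_reached = n
        log_cond = 0.0
        if inp.condition_on_survival:
            la, _, _, _ = inp.params.log_alpha_beta(t1)
            log_cond = math.log(-math.expm1(la))
        while a_lo <= inp.a_cap:
            a_hi = min(a_lo + self.chunk - 1, inp.a_cap)
            self._extend(a_hi)
            a = np.arange(a_lo, a_hi + 1)
            sl = slice(a_lo - n, a_hi - n + 1)
            lp1 = log_prob_from_one(a, inp.params, t1) - log_cond
            lterms = lp1 + self._log_obs[sl] + self._log_t2[sl]
            a_reached = a_hi
            blk_max = float(np.max(lterms))
            log_total = float(np.logaddexp.reduce(np.append(lterms, log_total)))
            if np.isneginf(blk_max):
                break  # structurally zero from here on (e.g. pure-death p = 0)
            if np.isfinite(log_total) and blk_max < log_total + math.log(TAIL_REL):
                break
            a_lo = a_hi + 1
        return log_total, a_reached

    def tail_mass_beyond_cap(self, t1: float, extra: int = 2000) -> float:
        """Fraction of the (extended) latent sum lying above a = a_cap."""
        inp = self.inp
        base, _ = self.log_likelihood_at(t1)
        if np.isneginf(base):
            return 0.0
        above = -np.inf
        a_lo = inp.a_cap + 1
        while a_lo <= inp.a_cap + extra:
            a = np.arange(a_lo, min(a_lo + self.chunk, inp.a_cap + extra + 1))
            lp1 = log_prob_from_one(a, inp.params, t1)
            lt2 = log_prob_transition_to(a, inp.extant_diversity, inp.params, inp.t2)
            lobs = _log_binom_pmf(
                inp.observed_first_bin_diversity, a, inp.preservation
            )
            lterms = lp1 + lt2 + lobs
            blk_max = float(np.max(lterms))
            above = float(np.logaddexp.reduce(np.append(lterms, above)))
            ref = np.logaddexp(above, base)
            if np.isneginf(blk_max) or blk_max < ref + math.log(TAIL_REL):
                break
            a_lo = a[-1] + 1
        if np.isneginf(above):
            return 0.0
        return float(np.exp(above - np.logaddexp(above, base)))


def likelihood_at(t1: float, inp: CladeCalibrationInput) -> tuple[float, int]:
    """L(t1) and the truncation point of the latent-diversity sum."""
    if t1 < 0:
        raise ValueError("t1 must be non-negative")
    log_l, a_reached = _LikelihoodEngine(inp).log_likelihood_at(t1)
    with np.errstate(under="ignore"):
        return float(np.exp(log_l)), a_reached


def build_curve(inp: CladeCalibrationInput, t1_max: float | None = None,
                step: float = 1.0, check_a_cap: bool = True) -> LikelihoodCurve:
    """Evaluate L on the grid 0, step, 2*step, ...

    With ``t1_max=None`` the grid extends until the likelihood has dropped
    below CURVE_FLOOR_REL of its maximum for CURVE_FLOOR_RUN consecutive
    points, with a hard ceiling of CURVE_CEILING_FACTOR * t_min.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    engine = _LikelihoodEngine(inp)
    ceiling = t1_max if t1_max is not None else CURVE_CEILING_FACTOR * inp.t_min
    n_pts_ceiling = int(math.floor(ceiling / step + 1e-9)) + 1

    log_vals: list[float] = []
    a_reached: list[int] = []
    best = -np.inf
    floor_run = 0
    i = 0
    while i < n_pts_ceiling:
        lv, ar = engine.log_likelihood_at(i * step)
        log_vals.append(lv)
        a_reached.append(ar)
        if lv > best:
            best = lv
            floor_run = 0
        elif np.isfinite(best) and lv < best + math.log(CURVE_FLOOR_REL):
            floor_run += 1
            if t1_max is None and floor_run >= CURVE_FLOOR_RUN:
                i += 1
                break
        else:
            floor_run = 0
        i += 1

    curve = LikelihoodCurve(
        offset=inp.t_min,
        grid=np.arange(len(log_vals)) * step,
        log_values=np.array(log_vals),
        metadata={"a_reached": np.array(a_reached), "step": step},
    )
    if check_a_cap and inp.preservation < 1:
        mode_t1 = float(curve.grid[int(np.argmax(curve.log_values))])
        if mode_t1 > 0:
            mass = engine.tail_mass_beyond_cap(mode_t1)
            curve.metadata["mass_beyond_a_cap"] = mass
            if mass > A_CAP_MASS_WARN:
                warnings.warn(
                    f"{mass:.1%} of the latent-diversity mass at the curve mode "
                    f"lies above a_cap={inp.a_cap}; the assumption that true "
                    "first-bin diversity is below the extant diversity may be "
                    "violated",
                    stacklevel=2,
                )
    return curve


def curve_quantile(curve: LikelihoodCurve, level: float) -> float:
    """Empirical ``level``-quantile of the normalised curve values.

    This is a horizontal likelihood threshold: a grid point whose normalised
    likelihood exceeds the 0.95-quantile sits in the top 5% of curve values,
    making the 95% tier the hardest to reach.
    """
    if not 0 <= level <= 1:
        raise ValueError("level must be in [0, 1]")
    return float(np.quantile(curve.normalized_values, level))


def write_curve(curve: LikelihoodCurve, path) -> None:
    """Write the curve as TSV: t1, age, likelihood, normalized."""
    import pandas as pd

    pd.DataFrame(
        {
            "t1": curve.grid,
            "age": curve.ages,
            "likelihood": curve.values,
            "normalized": curve.normalized_values,
        }
    ).to_csv(path, sep="\t", index=False)
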