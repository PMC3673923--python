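"""Per-capita origination/extinction rates and preservation-rate estimation.

Per-bin rates follow the boundary-crosser estimators of Foote: with N_bt
ranges crossing both boundaries of a bin of length dt, N_t crossing the top
and N_b crossing the bottom,

    p_hat = ln(N_t / N_bt) / dt        (origination, per lineage per Ma)
    q_hat = ln(N_b / N_bt) / dt        (extinction,  per lineage per Ma)

Either rate is undefined when its counts vanish.  The clade-level rates used
by the branching model are the unweighted arithmetic means of the defined
per-bin estimates; the diversification model assumes rates constant through
time, so fluctuation between bins is treated as estimation noise.

The range-frequency ratio (FreqRat) preservation estimator is
R_hat = f2^2 / (f1 * f3) where f_k counts taxa with ranges of exactly k bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PreservationRateUndefined, RateEstimationFailure
from .strat import BinCrossingCounts, FossilRangeDataset, StratBin, classify_bin_crossers


@dataclass(frozen=True)
class RatePair:
    """Origination/extinction rates per lineage per Ma; ``None`` = undefined."""

    origination: float | None
    extinction: float | None
    bin: StratBin | None = None

    def __post_init__(self):
        for val in (self.origination, self.extinction):
            if val is not None and val < 0:
                raise ValueError(f"negative rate {val}")


@dataclass(frozen=True)
class AverageRates:
    """Record-wide mean rates plus per-bin details."""

    origination: float
    extinction: float
    n_bins_origination: int
    n_bins_extinction: int
    per_bin: tuple[RatePair, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class RangeFrequencySpectrum:
    """f_k = number of taxa whose range spans exactly k bins (k >= 1)."""

    counts: tuple[int, ...]

    def f(self, k: int) -> int:
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.counts[k - 1] if k <= len(self.counts) else 0

    @property
    def n_taxa(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class PreservationRate:
    """Per-interval probability of preservation and recovery, 0 < R <= 1."""

    R: float

    def __post_init__(self):
        if not 0 < self.R <= 1:
            raise ValueError(f"preservation rate must be in (0, 1], got {self.R}")


def foote_rates(counts: BinCrossingCounts, duration: float) -> RatePair:
    """Per-capita rates for a single bin from its boundary-crosser counts."""
    if duration <= 0:
        raise ValueError(f"bin duration must be positive, got {duration}")
    p = q = None
    if counts.n_bt > 0 and counts.n_t > 0:
        p = math.log(counts.n_t / counts.n_bt) / duration
    if counts.n_bt > 0 and counts.n_b > 0:
        q = math.log(counts.n_b / counts.n_bt) / duration
    return RatePair(p, q, bin=counts.bin)


def per_bin_rates(dataset: FossilRangeDataset) -> list[RatePair]:
    """Foote rates for every bin intersected by the record."""
    first, last = dataset.first_last_indices()
    ts = dataset.timescale
    out = []
    for k in range(int(first.min()), int(last.max()) + 1):
        hit = (first <= k) & (last >= k)
        if not hit.any():
            out.append(RatePair(None, None, bin=ts.bins[k]))
            continue
        lower = first[hit] < k
        upper = last[hit] > k
        counts = BinCrossingCounts(
            n_bt=int(np.sum(lower & upper)),
            n_bL=int(np.sum(lower & ~upper)),
            n_Ft=int(np.sum(~lower & upper)),
            n_FL=int(np.sum(~lower & ~upper)),
            bin=ts.bins[k],
        )
        out.append(foote_rates(counts, ts.bins[k].duration))
    return out


def average_rates(dataset: FossilRangeDataset,
                  weighting: str = "duration") -> AverageRates:
    """Mean of the defined per-bin rates across the record.

    The default averages per-bin rates weighted by bin duration, which is
    equivalent to dividing the summed per-bin log turnover ratios by the
    total time with defined estimates.  An unweighted arithmetic mean
    (``weighting="none"``) gives every bin the same vote regardless of its
    length; on timescales with sub-Ma bins (the Quaternary stages) a single
    range truncated near the Recent then contributes a per-Ma rate one to
    two orders of magnitude above the record-wide signal, which is why the
    duration-weighted mean is the default.

    Raises :class:`RateEstimationFailure` when fewer than two bins yield a
    defined origination rate, or fewer than two a defined extinction rate —
    the failure mode of records whose ranges do not overlap enough.
    """
    if weighting not in ("duration", "none"):
        raise ValueError(f"weighting must be 'duration' or 'none', got {weighting!r}")
    per_bin = tuple(per_bin_rates(dataset))
    ps = [(r.origination, r.bin.duration) for r in per_bin if r.origination is not None]
    qs = [(r.extinction, r.bin.duration) for r in per_bin if r.extinction is not None]
    if len(ps) < 2 or len(qs) < 2:
        raise RateEstimationFailure(
            f"insufficiently overlapping ranges: {len(ps)} bins with a defined "
            f"origination rate, {len(qs)} with a defined extinction rate "
            "(need at least 2 of each)"
        )

    def _mean(pairs):
        vals = np.array([v for v, _ in pairs])
        if weighting == "none":
            return float(np.mean(vals))
        return float(np.average(vals, weights=[d for _, d in pairs]))

    return AverageRates(
        origination=_mean(ps),
        extinction=_mean(qs),
        n_bins_origination=len(ps),
        n_bins_extinction=len(qs),
        per_bin=per_bin,
    )


def range_frequency_spectrum(dataset: FossilRangeDataset) -> RangeFrequencySpectrum:
    """Distribution of range lengths in bins across taxa."""
    first, last = dataset.first_last_indices()
    spans = last - first + 1
    kmax = int(spans.max())
    counts = tuple(int(np.sum(spans == k)) for k in range(1, kmax + 1))
    return RangeFrequencySpectrum(counts)


def freqrat(spectrum: RangeFrequencySpectrum) -> PreservationRate:
    """FreqRat preservation-rate estimate R_hat = f2^2 / (f1 * f3).

    The raw ratio can exceed 1 on real records; it is then clamped to 1 with
    a warning, since values above 1 are not interpretable as probabilities.
    """
    f1, f2, f3 = spectrum.f(1), spectrum.f(2), spectrum.f(3)
    if f1 == 0 or f3 == 0:
        raise PreservationRateUndefined(
            f"FreqRat undefined: f1={f1}, f3={f3} (both must be positive)"
        )
    raw = f2 * f2 / (f1 * f3)
    if raw > 1:
        warnings.warn(
            f"FreqRat estimate {raw:.4g} exceeds 1; clamped to 1 (boundary "
            "estimate — treat with caution)",
            stacklevel=2,
        )
        raw = 1.0
    if raw == 0:
        raise PreservationRateUndefined("FreqRat estimate is 0 (f2 = 0)")
    return PreservationRate(raw)
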