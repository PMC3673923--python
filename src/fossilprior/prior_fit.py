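"""Least-squares gamma fit to the discretised likelihood curve.

The area-normalised curve is matched against a gamma density in (shape,
scale) by least squares; the raw likelihood scale and the density scale are
not comparable, which is why the fit is done on the normalised curve.  The
minimum-age offset (the age of the base of the oldest occupied bin) is never
optimised: the fitted density lives on the t1 axis and the prior on a node
age is offset + Gamma(shape, scale).

The t1 = 0 grid point is excluded from the residuals: for shape < 1 (the
typical decaying curve) the gamma density diverges there, and for n >= 2 the
curve carries a structural zero that no gamma can represent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import gamma as _gamma

from .errors import FitFailure
from .likelihood import LikelihoodCurve

#: Default ceiling on the normalised residual (SSE / sum of squared curve
#: values) above which the fit is declared a failure.
TAU_FIT = 0.05

#: Deterministic multiplicative jitters applied to the moment-based start.
_START_JITTERS = ((1.0, 1.0), (0.5, 2.0), (2.0, 0.5), (3.0, 1.0 / 3.0), (0.25, 4.0))


@dataclass(frozen=True)
class GammaPrior:
    """An offset gamma prior on a node age: offset + Gamma(shape, scale)."""

    shape: float
    scale: float
    offset: float
    fit_sse: float
    converged: bool

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def density_95(self) -> tuple[float, float]:
        """Central 95% interval on the age scale (Ma)."""
        return density_interval(self, 0.95)

    def pdf(self, t1) -> np.ndarray:
        """Density on the t1 axis (age minus offset)."""
        return _gamma.pdf(t1, self.shape, scale=self.scale)


def density_interval(prior: GammaPrior, mass: float = 0.95) -> tuple[float, float]:
    """Equal-tail central interval of the offset gamma, on the age scale."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    tail = (1.0 - mass) / 2.0
    lo, hi = _gamma.ppf([tail, 1.0 - tail], prior.shape, scale=prior.scale)
    return prior.offset + float(lo), prior.offset + float(hi)


def _curve_moments(curve: LikelihoodCurve) -> tuple[float, float]:
    x, y = curve.grid, curve.normalized_values
    m = float(np.trapezoid(x * y, x))
    v = float(np.trapezoid((x - m) ** 2 * y, x))
    return m, max(v, 1e-12)


def fit_gamma(curve: LikelihoodCurve, tau_fit: float = TAU_FIT) -> GammaPrior:
    """Fit (shape, scale) of a gamma density to the normalised curve.

    Starts from the moment estimates (shape = m^2/v, scale = v/m) and falls
    back to a fixed set of jittered starts when the first solve does not
    converge below ``tau_fit``.  Raises :class:`FitFailure` (carrying the
    best non-converged prior) when no start succeeds.
    """
    x = np.asarray(curve.grid, dtype=float)
    y = np.asarray(curve.normalized_values, dtype=float)
    keep = x > 0
    if int(np.sum(keep & (y > 0))) < 10:
        raise FitFailure("curve has fewer than 10 positive points to fit")
    x, y = x[keep], y[keep]
    ss_curve = float(np.sum(y**2))

    m, v = _curve_moments(curve)
    shape0 = max(m * m / v, 1e-3)
    scale0 = max(v / m, 1e-3) if m > 0 else 1.0

    def residuals(theta):
        shape, scale = np.exp(theta)
        return y - _gamma.pdf(x, shape, scale=scale)

    best = None
    for js, jc in _START_JITTERS:
        theta0 = np.log([shape0 * js, scale0 * jc])
        sol = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-12)
        sse = float(np.sum(sol.fun**2)) / ss_curve
        if best is None or sse < best[0]:
            best = (sse, sol)
        if sol.success and sse <= tau_fit:
            break

    sse, sol = best
    shape, scale = np.exp(sol.x)
    converged = bool(sol.success) and sse <= tau_fit
    prior = GammaPrior(
        shape=float(shape),
        scale=float(scale),
        offset=float(curve.offset),
        fit_sse=sse,
        converged=converged,
    )
    if not converged:
        raise FitFailure(
            f"gamma fit failed: normalised residual {sse:.4g} "
            f"(threshold {tau_fit}), success={sol.success}",
            prior=prior,
        )
    return prior


# ---------------------------------------------------------------------------
# Reporting


def prior_to_dict(prior: GammaPrior) -> dict:
    lo, hi = density_interval(prior, 0.95)
    return {
        "shape": prior.shape,
        "scale": prior.scale,
        "offset_ma": prior.offset,
        "density_95": [lo, hi],
        "fit_sse": prior.fit_sse,
        "converged": prior.converged,
    }


def prior_from_dict(d: dict) -> GammaPrior:
    return GammaPrior(
        shape=float(d["shape"]),
        scale=float(d["scale"]),
        offset=float(d["offset_ma"]),
        fit_sse=float(d["fit_sse"]),
        converged=bool(d["converged"]),
    )


def load_prior(path) -> GammaPrior:
    with open(path) as fh:
        return prior_from_dict(json.load(fh))


def report_prior(prior: GammaPrior, curve: LikelihoodCurve, out_prefix: str,
                 plot: bool = True) -> dict:
    """Write the JSON report, the curve TSV and an overlay plot.

    The JSON fields map directly onto the offset-gamma node-age prior
    settings of Bayesian clock software (shape, scale, zero offset in Ma).
    Returns the paths written.
    """
    from .likelihood import write_curve

    paths = {}
    json_path = f"{out_prefix}.prior.json"
    with open(json_path, "w") as fh:
        json.dump(prior_to_dict(prior), fh, indent=2)
        fh.write("\n")
    paths["json"] = json_path

    curve_path = f"{out_prefix}.curve.tsv"
    write_curve(curve, curve_path)
    paths["curve"] = curve_path

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.ages, curve.normalized_values, "k-", lw=1.5,
                label="normalised likelihood")
        tt = np.linspace(curve.grid[0], curve.grid[-1], 512)
        ax.plot(tt + curve.offset, prior.pdf(tt), "r--", lw=1.5,
                label=f"Gamma({prior.shape:.3g}, {prior.scale:.3g})"
                      + ("" if prior.converged else " [not converged]"))
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
        fig.tight_layout()
        png_path = f"{out_prefix}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        paths["plot"] = png_path
    return paths
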