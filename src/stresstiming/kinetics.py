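"""Statistical-kinetics inference of rate-limiting step counts.

For a response produced by completing a chain of memory-less molecular
steps, the randomness parameter ``R = (sigma_t / mu_t)^2`` of the response
times bounds the number of rate-limiting steps from below: ``n >= 1/R``,
with equality for a strictly linear chain of equal-rate irreversible steps.
``1/R``, rounded up, is therefore an estimate of the effective number of
rate-limiting steps.  If the chain model holds, response times follow an
Erlang distribution (gamma with integer shape); consistency is checked by
fitting a gamma by maximum likelihood, rounding the shape, simulating many
datasets of the same size from the fit, and counting the fraction that a
two-sample Kolmogorov-Smirnov test cannot distinguish from the data.

Since ``R <= 1`` for any such chain (at least one step exists), the
standard deviation can never exceed the mean; and across promoters the
smallest observed ``sigma_t / mu_t`` defines an empirical *precision
limit*: a line through the origin below which no response falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "KineticsEstimate",
    "PrecisionLimit",
    "randomness_and_steps",
    "fit_erlang",
    "ks_consistency",
    "erlang_consistency",
    "precision_limit",
    "slope_in_minutes",
]


@dataclass
class KineticsEstimate:
    """Randomness parameter and rate-limiting step count for one response.

    ``unbounded`` flags a degenerate, zero-variance input for which the
    step-count bound diverges; the integer fields are then ``None``.
    """

    mu_t: float
    sigma_t: float
    ratio: float
    randomness: float  # R = ratio^2
    n_min_real: float | None
    n_steps: int | None
    unbounded: bool = False
    erlang_shape: int | None = None
    erlang_scale: float | None = None
    ks_consistency: float | None = None
    ks_alpha: float = 0.05


@dataclass
class PrecisionLimit:
    """Line through the origin with the smallest observed sigma_t / mu_t."""

    slope: float
    anchor: object  # identifier of the promoter/condition defining the slope
    points: list = field(default_factory=list)  # (id, mu_t, sigma_t) triples
    bound_violations: list = field(default_factory=list)  # ids with sigma_t > mu_t


def randomness_and_steps(mu_t: float, sigma_t: float) -> KineticsEstimate:
    """Randomness parameter and the implied rate-limiting step count.

    ``ratio = sigma_t / mu_t``, ``R = ratio^2``, ``n_min = 1/R``; the step
    count is ``ceil(1/R)`` (the bound rounds *up*).  ``sigma_t = 0`` gives
    an unbounded estimate, flagged rather than reported as a number.
    """
    if mu_t <= 0:
        raise ValueError(f"mu_t must be positive, got {mu_t}")
    if sigma_t < 0:
        raise ValueError(f"sigma_t must be non-negative, got {sigma_t}")
    ratio = sigma_t / mu_t
    randomness = ratio**2
    if sigma_t == 0:
        return KineticsEstimate(
            mu_t=mu_t,
            sigma_t=sigma_t,
            ratio=0.0,
            randomness=0.0,
            n_min_real=None,
            n_steps=None,
            unbounded=True,
        )
    n_min = 1.0 / randomness
    return KineticsEstimate(
        mu_t=mu_t,
        sigma_t=sigma_t,
        ratio=ratio,
        randomness=randomness,
        n_min_real=n_min,
        n_steps=max(1, math.ceil(n_min - 1e-9)),
        unbounded=False,
    )


def fit_erlang(times: np.ndarray) -> tuple[int, float]:
    """Maximum-likelihood Erlang fit of response times.

    Fits a gamma distribution with the location fixed at zero, rounds the ML
    shape half-up to the nearest integer (>= 1), and re-solves the scale at
    that integer shape (``scale = mean / shape``, the ML solution for fixed
    shape).  Returns ``(shape, scale)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 10:
        raise ValueError(f"need at least 10 response times, got {times.size}")
    if np.any(times <= 0):
        raise ValueError("response times must be positive for an Erlang fit")
    if np.ptp(times) == 0:
        raise ValueError("degenerate sample: all response times identical")
    shape_ml, _, _ = sps.gamma.fit(times, floc=0)
    shape = max(1, int(math.floor(shape_ml + 0.5)))
    scale = float(times.mean()) / shape
    return shape, scale


def ks_consistency(
    times: np.ndarray,
    shape: int,
    scale: float,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of simulated datasets KS-indistinguishable from the data.

    Simulates ``n_sim`` datasets of the same size from the fitted
    integer-shape gamma and runs a two-sample Kolmogorov-Smirnov test of
    each against the data; returns the fraction with ``p >= alpha``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_sim):
        sim = rng.gamma(shape=shape, scale=scale, size=times.size)
        if sps.ks_2samp(times, sim).pvalue >= alpha:
            n_ok += 1
    return n_ok / n_sim


def erlang_consistency(
    times: np.ndarray,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[int, float, float]:
    """Convenience: fit the Erlang and run the KS consistency check.

    Returns ``(shape, scale, fraction consistent)``.
    """
    shape, scale = fit_erlang(times)
    frac = ks_consistency(times, shape, scale, n_sim=n_sim, alpha=alpha, seed=seed)
    return shape, scale, frac


def precision_limit(summaries) -> PrecisionLimit:
    """Precision-limit line through the origin from per-promoter timings.

    ``summaries`` is an iterable of ``(identifier, mu_t, sigma_t)`` triples
    (or objects with ``mu_t`` / ``sigma_t`` attributes and an optional
    ``measure`` label).  The slope is the smallest ``sigma_t / mu_t``;
    points with ``sigma_t > mu_t`` violate the single-step upper bound and
    are reported, not silently dropped.
    """
    points = []
    for item in summaries:
        if hasattr(item, "mu_t"):
            ident = getattr(item, "label", getattr(item, "measure", "summary"))
            points.append((ident, float(item.mu_t), float(item.sigma_t)))
        else:
            ident, mu, sigma = item
            points.append((ident, float(mu), float(sigma)))
    if not points:
        raise ValueError("precision_limit requires at least one timing summary")
    ratios = [(sigma / mu, ident) for ident, mu, sigma in points]
    slope, anchor = min(ratios, key=lambda x: x[0])
    violations = [ident for ident, mu, sigma in points if sigma > mu * (1 + 1e-12)]
    return PrecisionLimit(
        slope=float(slope), anchor=anchor, points=points, bound_violations=violations
    )


def slope_in_minutes(slope: float) -> int:
    """Precision-limit slope as minutes of timing spread per hour of delay."""
    if not 0 < slope <= 1:
        raise ValueError(f"slope must be in (0, 1], got {slope}")
    return int(math.floor(slope * 60 + 0.5))
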