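"""Completion-time models for chains of memory-less molecular steps.

A stress response is modelled as the completion of a chain of ``n`` sequential
steps, each with an exponentially distributed waiting time of equal rate
``n / mean_time``.  The completion time of such a chain follows an Erlang
distribution (a gamma distribution with integer shape ``n``), whose
coefficient of variation is ``1/sqrt(n)``: many fast steps give precise
timing, a single slow step gives fully exponential (CV = 1) timing.

Dual-reporter experiments distinguish two architectures:

* **serial** -- both reporters hang off one causal chain.  Reporter A fires
  after a shared upstream chain, reporter B after the shared chain plus an
  intermediate chain, so B always fires after A (up to reporter delays) and
  their times are positively correlated through the shared segment.
* **parallel** -- the two reporters are driven by independent chains, so
  their latent times are uncorrelated and carry no strict order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["ChainSpec", "DualChainSpec", "sample_erlang", "sample_dual_times"]


@dataclass(frozen=True)
class ChainSpec:
    """A chain of ``n_steps`` identical exponential steps.

    Parameters
    ----------
    n_steps:
        Number of memory-less steps (Erlang shape), ``>= 1``.
    mean_time:
        Mean completion time of the whole chain in hours, ``> 0``.  The
        per-step rate is ``n_steps / mean_time``.
    """

    n_steps: int
    mean_time: float

    def __post_init__(self) -> None:
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError(f"n_steps must be a positive integer, got {self.n_steps!r}")
        if not self.mean_time > 0:
            raise ValueError(f"mean_time must be positive, got {self.mean_time!r}")

    @property
    def rate(self) -> float:
        """Per-step rate (1/h)."""
        return self.n_steps / self.mean_time

    @property
    def cv(self) -> float:
        """Analytic coefficient of variation, ``1/sqrt(n_steps)``."""
        return 1.0 / np.sqrt(self.n_steps)

    @property
    def variance(self) -> float:
        """Analytic variance of the completion time, ``mean^2 / n``."""
        return self.mean_time**2 / self.n_steps


@dataclass(frozen=True)
class DualChainSpec:
    """Latent-time model for a dual-reporter pair.

    For ``architecture="serial"``, ``shared`` is the chain up to the trigger
    of reporter A and ``mid`` the chain from A's trigger to B's; ``reporter_a``
    and ``reporter_b`` are optional per-reporter chains (``None`` means a
    zero-duration reporter).  Latent times are::

        t_A = T_shared + T_repA
        t_B = T_shared + T_mid + T_repB

    For ``architecture="parallel"``, ``independent_a`` and ``independent_b``
    drive the two reporters with no shared component::

        t_A = T_indA + T_repA,   t_B = T_indB + T_repB
    """

    architecture: Literal["serial", "parallel"]
    shared: ChainSpec | None = None
    mid: ChainSpec | None = None
    independent_a: ChainSpec | None = None
    independent_b: ChainSpec | None = None
    reporter_a: ChainSpec | None = None
    reporter_b: ChainSpec | None = None

    def __post_init__(self) -> None:
        if self.architecture == "serial":
            if self.shared is None or self.mid is None:
                raise ValueError("serial architecture requires 'shared' and 'mid' chains")
        elif self.architecture == "parallel":
            if self.independent_a is None or self.independent_b is None:
                raise ValueError(
                    "parallel architecture requires 'independent_a' and 'independent_b' chains"
                )
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")


def sample_erlang(
    spec: ChainSpec, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` completion times of the chain ``spec``.

    Each draw is the sum of ``spec.n_steps`` independent exponential waiting
    times with rate ``spec.n_steps / spec.mean_time``, i.e. an Erlang
    (integer-shape gamma) variate with mean ``spec.mean_time`` and CV
    ``1/sqrt(n_steps)``.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=spec.n_steps, scale=spec.mean_time / spec.n_steps, size=count)


def _maybe_sample(
    spec: ChainSpec | None, count: int, rng: np.random.Generator
) -> np.ndarray:
    if spec is None:
        return np.zeros(count)
    return sample_erlang(spec, count, rng)


def sample_dual_times(
    spec: DualChainSpec, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``count`` latent time pairs ``(t_A, t_B)`` as a ``(count, 2)`` array.

    Serial pairs share the upstream chain draw, so ``t_B - t_A`` equals
    ``T_mid + T_repB - T_repA`` and the shared variance induces a positive
    correlation; parallel pairs are fully independent.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    rep_a = _maybe_sample(spec.reporter_a, count, rng)
    rep_b = _maybe_sample(spec.reporter_b, count, rng)
    if spec.architecture == "serial":
        t_shared = sample_erlang(spec.shared, count, rng)
        t_mid = sample_erlang(spec.mid, count, rng)
        t_a = t_shared + rep_a
        t_b = t_shared + t_mid + rep_b
    else:
        t_a = sample_erlang(spec.independent_a, count, rng) + rep_a
        t_b = sample_erlang(spec.independent_b, count, rng) + rep_b
    return np.column_stack([t_a, t_b])
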