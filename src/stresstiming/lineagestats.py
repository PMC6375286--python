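"""Lineage-aware timing statistics.

Lineage trees pseudo-replicate measurements: all descendants of one founder
share history, so treating every leaf as independent understates variance
and overstates significance.  The remedy used throughout this package is
*subsampling*: draw one random root-to-leaf trajectory per founder
(choosing uniformly among daughters at every division), compute the
statistic of interest on that reduced set, and repeat many times.  Summary
statistics are averaged over subsamples; their uncertainties come from
bootstrapping founders within the subsamples.  For dual-reporter pairs the
same machinery yields subsample-averaged Pearson correlations and a
permutation test for strict temporal order (reporter B after reporter A in
every cell), with exact enumeration of all pairings when few founders make
that feasible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsConfig",
    "TimingSummary",
    "PairTimingResult",
    "leaf_selection_weights",
    "subsample_trajectories",
    "timing_summary",
    "paired_correlation",
    "strict_order_test",
    "pair_timing_result",
]

_ENUMERATION_LIMIT = 7  # up to 7! = 5040 pairings enumerated exactly


@dataclass(frozen=True)
class StatsConfig:
    """Subsample / bootstrap / permutation sizes and the master seed."""

    n_subsamples: int = 1000
    n_bootstrap: int = 1000
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_subsamples, self.n_bootstrap, self.n_permutations):
            if v < 1:
                raise ValueError("all replicate counts must be >= 1")


@dataclass
class TimingSummary:
    """Mean and spread of response times with subsampling/bootstrap errors."""

    mu_t: float
    sigma_t: float
    se_mu: float
    se_sigma: float
    n_founders: int
    n_samples: int
    responder_fraction: float
    measure: str = "threshold"

    @property
    def ratio(self) -> float:
        """Dimensionless timing variability sigma_t / mu_t."""
        return self.sigma_t / self.mu_t


@dataclass
class PairTimingResult:
    """Subsample-averaged correlation and strict-order statistics for a pair."""

    r_mean: float
    r_sd: float
    p_median: float
    order_statistic: float  # mean over subsamples of #(t_B > t_A)
    order_fraction: float  # mean over subsamples of the ordered fraction
    permutation_p: float
    n_samples_used: int


def _substream(config: StatsConfig, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, label]))


def leaf_selection_weights(
    children: Mapping[int, Sequence[int]], founder: int
) -> tuple[list[int], np.ndarray]:
    """Leaves under ``founder`` with their single-trajectory probabilities.

    A random walk from the founder to a leaf picks uniformly among children
    at every division, so a leaf's probability is the product of ``1/k``
    over the branchings on its path (``2^-depth`` in a binary tree).
    """
    leaves: list[int] = []
    probs: list[float] = []
    stack: list[tuple[int, float]] = [(founder, 1.0)]
    while stack:
        cid, p = stack.pop()
        kids = children.get(cid, [])
        if not kids:
            leaves.append(cid)
            probs.append(p)
        else:
            for kid in kids:
                stack.append((kid, p / len(kids)))
    order = sorted(range(len(leaves)), key=lambda i: leaves[i])
    return [leaves[i] for i in order], np.asarray([probs[i] for i in order])


def subsample_trajectories(
    children: Mapping[int, Sequence[int]],
    founders: Sequence[int],
    leaf_values: Mapping[int, float | Sequence[float]],
    config: StatsConfig,
) -> np.ndarray:
    """Draw ``n_subsamples`` single-trajectory samples, one leaf per founder.

    ``leaf_values`` maps each leaf to its response time (scalar) or pair of
    response times; non-responding trajectories are encoded as NaN and stay
    NaN in the samples (dropped per sample downstream).  Returns an array of
    shape ``(S, F)`` or ``(S, F, 2)``.
    """
    founders = list(founders)
    if not founders:
        raise ValueError("no founders given")
    rng = _substream(config, 0x51)
    probe = np.atleast_1d(np.asarray(leaf_values[next(iter(leaf_values))], dtype=float))
    width = probe.size
    shape = (config.n_subsamples, len(founders)) + ((width,) if width > 1 else ())
    out = np.empty(shape, dtype=float)
    for fi, founder in enumerate(founders):
        leaves, probs = leaf_selection_weights(children, founder)
        missing = [lf for lf in leaves if lf not in leaf_values]
        if missing:
            raise ValueError(f"no response value for leaves {missing[:5]} of founder {founder}")
        vals = np.asarray([np.atleast_1d(leaf_values[lf]) for lf in leaves], dtype=float)
        idx = rng.choice(len(leaves), size=config.n_subsamples, p=probs)
        picked = vals[idx]
        out[:, fi] = picked if width > 1 else picked[:, 0]
    return out


def timing_summary(
    samples: np.ndarray,
    config: StatsConfig,
    responder_fraction: float = 1.0,
    measure: str = "threshold",
) -> TimingSummary:
    """Timing mean and standard deviation averaged over subsamples.

    ``mu_t`` is the average over subsamples of the per-sample mean response
    time, ``sigma_t`` the average of the per-sample standard deviation
    (ddof=1).  Standard errors are from ``n_bootstrap`` founder-level
    bootstrap replicates: founders are resampled with replacement, the
    per-sample statistics recomputed and averaged over subsamples, and the
    spread over replicates reported.  NaN entries (non-responders) are
    dropped within each sample; samples with fewer than two responders are
    skipped.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a (n_subsamples, n_founders) array")
    n_valid = np.sum(~np.isnan(samples), axis=1)
    usable = n_valid >= 2
    if not usable.any():
        raise ValueError(
            "fewer than two responding founders in every subsample; "
            "sigma_t is undefined"
        )
    sub = samples[usable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu_t = float(np.nanmean(np.nanmean(sub, axis=1)))
        sigma_t = float(np.nanmean(np.nanstd(sub, axis=1, ddof=1)))

        rng = _substream(config, 0x52)
        n_f = samples.shape[1]
        boot_mu = np.empty(config.n_bootstrap)
        boot_sigma = np.empty(config.n_bootstrap)
        for b in range(config.n_bootstrap):
            idx = rng.integers(0, n_f, size=n_f)
            res = sub[:, idx]
            ok = np.sum(~np.isnan(res), axis=1) >= 2
            if not ok.any():
                boot_mu[b] = np.nan
                boot_sigma[b] = np.nan
                continue
            boot_mu[b] = np.nanmean(np.nanmean(res[ok], axis=1))
            boot_sigma[b] = np.nanmean(np.nanstd(res[ok], axis=1, ddof=1))
        se_mu = float(np.nanstd(boot_mu, ddof=1)) if config.n_bootstrap > 1 else 0.0
        se_sigma = (
            float(np.nanstd(boot_sigma, ddof=1)) if config.n_bootstrap > 1 else 0.0
        )
    return TimingSummary(
        mu_t=mu_t,
        sigma_t=sigma_t,
        se_mu=se_mu,
        se_sigma=se_sigma,
        n_founders=samples.shape[1],
        n_samples=int(usable.sum()),
        responder_fraction=responder_fraction,
        measure=measure,
    )


def _complete_pairs(sample: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(sample).any(axis=1)
    return sample[mask]


def paired_correlation(
    pair_samples: np.ndarray, config: StatsConfig
) -> tuple[float, float, float, int]:
    """Subsample-averaged Pearson correlation for a dual-reporter pair.

    Per subsample, Pearson's r and its two-sided p-value are computed over
    the founders with both response times present (at least three needed);
    reported are the mean and sd of r over subsamples and the median
    p-value.  Zero-variance samples are skipped with a warning.
    """
    pair_samples = np.asarray(pair_samples, dtype=float)
    if pair_samples.ndim != 3 or pair_samples.shape[2] != 2:
        raise ValueError("pair_samples must have shape (S, F, 2)")
    rs, ps = [], []
    n_skipped = 0
    for sample in pair_samples:
        pairs = _complete_pairs(sample)
        if pairs.shape[0] < 3:
            n_skipped += 1
            continue
        if np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
            n_skipped += 1
            continue
        r, p = sps.pearsonr(pairs[:, 0], pairs[:, 1])
        rs.append(r)
        ps.append(p)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} subsample(s) skipped (fewer than 3 complete pairs or "
            "zero variance)"
        )
    if not rs:
        raise ValueError("no usable subsample for the paired correlation")
    rs = np.asarray(rs)
    r_sd = float(rs.std(ddof=1)) if rs.size > 1 else 0.0
    return float(rs.mean()), r_sd, float(np.median(ps)), len(rs)


def _order_statistic(t_a: np.ndarray, t_b: np.ndarray) -> int:
    # ties count as non-ordered
    return int(np.sum(t_b > t_a))


def _permutation_fraction(
    t_a: np.ndarray, t_b: np.ndarray, observed: int, rng: np.random.Generator, n_perm: int
) -> float:
    """Fraction of random A/B pairings at least as strictly ordered as observed."""
    m = t_a.size
    if m <= _ENUMERATION_LIMIT:
        perms = np.asarray(list(permutations(range(m))))
        stats = np.sum(t_b[perms] > t_a[None, :], axis=1)
        return float(np.mean(stats >= observed))
    shuffled = rng.permuted(np.tile(t_b, (n_perm, 1)), axis=1)
    stats = np.sum(shuffled > t_a[None, :], axis=1)
    return float(np.mean(stats >= observed))


def strict_order_test(
    pair_samples: np.ndarray, config: StatsConfig
) -> tuple[float, float, float]:
    """Permutation test for strict temporal order of a dual-reporter pair.

    The statistic is the number of founders whose reporter-B time exceeds
    their reporter-A time (ties non-ordered).  Per subsample, B times are
    randomly re-paired with A times across founders (all ``m!`` pairings
    enumerated when ``m <= 7``, otherwise ``n_permutations`` shuffles) and
    the fraction of pairings with a statistic at least as large as observed
    is recorded; the reported p-value is the mean of these fractions over
    subsamples.  Returns ``(mean observed statistic, mean ordered fraction,
    permutation p)``.
    """
    pair_samples = np.asarray(pair_samples, dtype=float)
    if pair_samples.ndim != 3 or pair_samples.shape[2] != 2:
        raise ValueError("pair_samples must have shape (S, F, 2)")
    rng = _substream(config, 0x53)
    observed_stats, fractions, p_fracs = [], [], []
    for sample in pair_samples:
        pairs = _complete_pairs(sample)
        if pairs.shape[0] < 2:
            continue
        t_a, t_b = pairs[:, 0], pairs[:, 1]
        obs = _order_statistic(t_a, t_b)
        observed_stats.append(obs)
        fractions.append(obs / t_a.size)
        p_fracs.append(
            _permutation_fraction(t_a, t_b, obs, rng, config.n_permutations)
        )
    if not observed_stats:
        raise ValueError("no subsample with at least two complete pairs")
    return (
        float(np.mean(observed_stats)),
        float(np.mean(fractions)),
        float(np.mean(p_fracs)),
    )


def pair_timing_result(
    pair_samples: np.ndarray, config: StatsConfig
) -> PairTimingResult:
    """Full dual-reporter summary: correlation plus strict-order test."""
    r_mean, r_sd, p_median, n_used = paired_correlation(pair_samples, config)
    order_stat, order_frac, perm_p = strict_order_test(pair_samples, config)
    return PairTimingResult(
        r_mean=r_mean,
        r_sd=r_sd,
        p_median=p_median,
        order_statistic=order_stat,
        order_fraction=order_frac,
        permutation_p=perm_p,
        n_samples_used=n_used,
    )
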