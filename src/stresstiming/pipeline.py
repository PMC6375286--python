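"""High-level glue from trace tables to timing summaries and pair results.

These helpers connect the per-module operations into the full analysis:
build the lineage structure from a trace table, map detected response times
onto leaves, draw founder-level subsamples (combining colonies, with cell
ids namespaced per colony), and hand the samples to the timing and pair
statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import KineticsEstimate, erlang_consistency, randomness_and_steps
from .lineagestats import (
    PairTimingResult,
    StatsConfig,
    TimingSummary,
    pair_timing_result,
    subsample_trajectories,
    timing_summary,
)
from .response import ResponseTimeSet

__all__ = [
    "lineage_structure",
    "response_subsamples",
    "channel_summary",
    "pair_summary",
    "kinetics_from_samples",
]


def lineage_structure(
    table: pd.DataFrame,
) -> tuple[dict, list]:
    """Children map and founder list across colonies.

    Cells are keyed ``(colony_id, cell_id)`` so colonies can be pooled into
    one founder set.  Founders are taken as the cells whose frames straddle
    time zero (first cell on each root path with a frame at/after zero).
    """
    children: dict = {}
    founders: list = []
    for colony, cdf in table.groupby("colony_id", sort=False):
        parents = (
            cdf[["cell_id", "parent_id"]]
            .drop_duplicates()
            .set_index("cell_id")["parent_id"]
        )
        for cid, pid in parents.items():
            children.setdefault((colony, cid), [])
            if pd.notna(pid):
                children.setdefault((colony, pid), []).append((colony, cid))
        has_post = cdf.groupby("cell_id")["time_h"].max() >= 0
        has_pre_parent = {}
        for cid in parents.index:
            pid = parents[cid]
            has_pre_parent[cid] = pd.notna(pid) and has_post.get(pid, False)
        for cid in parents.index:
            if has_post[cid] and not has_pre_parent[cid]:
                founders.append((colony, cid))
    for key in children:
        children[key] = sorted(children[key])
    return children, sorted(founders)


def response_subsamples(
    table: pd.DataFrame,
    rt: ResponseTimeSet,
    config: StatsConfig,
    channels: list[str] | None = None,
) -> np.ndarray:
    """Single-trajectory subsamples of response times, pooled over colonies.

    Returns shape ``(S, F)`` for one channel or ``(S, F, k)`` for several
    (founders with a non-responding trajectory in a sample appear as NaN
    there).
    """
    channels = channels or sorted(rt.table["channel"].unique())
    children, founders = lineage_structure(table)
    leaf_values: dict = {}
    for (colony, leaf), grp in rt.table.groupby(["colony_id", "trajectory_id"]):
        vals = []
        for ch in channels:
            sel = grp.loc[grp["channel"] == ch, "response_time"]
            vals.append(float(sel.iloc[0]) if len(sel) else np.nan)
        leaf_values[(colony, leaf)] = vals if len(channels) > 1 else vals[0]
    # restrict founders to those with measured leaves
    measured = set(leaf_values)
    founders = [
        f
        for f in founders
        if _all_leaves_measured(children, f, measured)
    ]
    return subsample_trajectories(children, founders, leaf_values, config)


def _all_leaves_measured(children: dict, founder, measured: set) -> bool:
    stack = [founder]
    while stack:
        cid = stack.pop()
        kids = children.get(cid, [])
        if not kids:
            if cid not in measured:
                return False
        stack.extend(kids)
    return True


def channel_summary(
    table: pd.DataFrame,
    rt: ResponseTimeSet,
    channel: str,
    config: StatsConfig,
) -> TimingSummary:
    """Subsampled timing summary for one channel, pooled over colonies."""
    samples = response_subsamples(table, rt, config, channels=[channel])
    sel = rt.fractions["channel"] == channel
    frac = float(rt.fractions.loc[sel, "responder_fraction"].mean())
    measure = rt.table["measure"].iloc[0]
    return timing_summary(samples, config, responder_fraction=frac, measure=measure)


def pair_summary(
    table: pd.DataFrame,
    rt: ResponseTimeSet,
    config: StatsConfig,
    channels: list[str] | None = None,
) -> PairTimingResult:
    """Dual-reporter correlation and strict-order test, pooled over colonies."""
    channels = channels or sorted(rt.table["channel"].unique())
    if len(channels) != 2:
        raise ValueError(f"pair analysis needs exactly two channels, got {channels}")
    samples = response_subsamples(table, rt, config, channels=channels)
    return pair_timing_result(samples, config)


def kinetics_from_samples(
    summary: TimingSummary,
    response_times: np.ndarray | None = None,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> KineticsEstimate:
    """Step-count estimate, optionally with the Erlang KS-consistency check.

    ``response_times`` (a pooled set of per-trajectory times) enables the
    Erlang fit and simulated-KS consistency; without it only the
    randomness-parameter bound is reported.
    """
    est = randomness_and_steps(summary.mu_t, summary.sigma_t)
    if response_times is not None and not est.unbounded:
        times = np.asarray(response_times, dtype=float)
        times = times[~np.isnan(times)]
        shape, scale, frac = erlang_consistency(
            times, n_sim=n_sim, alpha=alpha, seed=seed
        )
        est.erlang_shape = shape
        est.erlang_scale = scale
        est.ks_consistency = frac
        est.ks_alpha = alpha
    return est
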