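"""Response-time detection and responder classification.

A trajectory's *response time* is the moment after stress addition at which
its corrected expression first reaches a threshold.  The colony-level
measure sets one threshold per microcolony and channel: the post-stress
minimum of the pointwise-median trace over all responders (> fold-change
cells) plus a fraction (default 25%) of that median trace's post-stress
range.  The per-cell alternative uses half of each trajectory's own maximum
expression.  Trajectories that never reach the threshold are flagged as
non-responders and excluded from timing statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .traces import ExpressionTraceSet, Trajectory, doubling_series, extract_trajectories

__all__ = [
    "ResponseTimeConfig",
    "ResponseTimeSet",
    "find_responders",
    "colony_threshold",
    "detect_response_time",
    "halfmax_response_time",
    "response_times",
]


@dataclass(frozen=True)
class ResponseTimeConfig:
    """Parameters of response-time detection.

    ``threshold_fraction`` positions the colony threshold within the
    post-stress range of the responder-median trace; ``responder_fold`` is
    the fold-change a trajectory must exceed (relative to its mean
    pre-stress baseline, floored at ``baseline_floor``) to count toward the
    threshold construction; ``interpolation`` is ``"linear"`` (sub-frame
    crossing) or ``"frame"`` (first frame at/above threshold);
    ``time_axis`` is ``"hours"`` or ``"doublings"``.
    """

    threshold_fraction: float = 0.25
    responder_fold: float = 3.0
    baseline_floor: float = 1e-6
    interpolation: str = "linear"
    time_axis: str = "hours"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.responder_fold <= 1:
            raise ValueError("responder_fold must exceed 1")
        if self.baseline_floor <= 0:
            raise ValueError("baseline_floor must be positive")
        if self.interpolation not in ("linear", "frame"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.time_axis not in ("hours", "doublings"):
            raise ValueError(f"unknown time_axis {self.time_axis!r}")


@dataclass
class ResponseTimeSet:
    """Per-trajectory response times plus per-colony responder fractions.

    ``table`` columns: colony_id, founder_id, trajectory_id, channel,
    measure, response_time, responded, threshold_used.  ``fractions``
    columns: colony_id, channel, measure, responder_fraction (fraction of
    trajectories that crossed the threshold).
    """

    table: pd.DataFrame
    fractions: pd.DataFrame
    config: ResponseTimeConfig = field(default_factory=ResponseTimeConfig)


def find_responders(
    trajectories: Sequence[Trajectory], channel: str, config: ResponseTimeConfig
) -> tuple[list[Trajectory], float]:
    """Classify fold-change responders within one colony.

    A trajectory responds if its maximum post-stress expression exceeds
    ``responder_fold`` times its baseline (mean pre-stress expression,
    floored at ``baseline_floor``).  Returns the responder subset and the
    responder fraction.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    responders = []
    for tr in trajectories:
        pre = tr.values[channel][tr.times < 0]
        if pre.size == 0:
            raise ValueError(
                f"trajectory {tr.leaf_id} in colony {tr.colony_id} has no "
                "pre-stress frames; cannot form a fold-change baseline"
            )
        baseline = max(float(pre.mean()), config.baseline_floor)
        post = tr.values[channel][tr.times >= 0]
        if post.size and post.max() / baseline > config.responder_fold:
            responders.append(tr)
    return responders, len(responders) / len(trajectories)


def colony_threshold(
    responders: Sequence[Trajectory], channel: str, config: ResponseTimeConfig
) -> float:
    """Threshold from the pointwise-median responder trace.

    On post-stress frames, the median over responders is taken pointwise;
    the threshold is that median trace's minimum plus
    ``threshold_fraction`` times its range.
    """
    if not responders:
        raise ValueError("threshold requires at least one responder trajectory")
    frames: dict[float, list[float]] = {}
    for tr in responders:
        post = tr.times >= 0
        for t, v in zip(tr.times[post], tr.values[channel][post]):
            frames.setdefault(round(float(t), 9), []).append(float(v))
    med = np.array([np.median(v) for _, v in sorted(frames.items())])
    lo, hi = med.min(), med.max()
    if hi - lo <= 0:
        raise ValueError("median responder trace has zero post-stress range")
    return float(lo + config.threshold_fraction * (hi - lo))


def _first_crossing(
    x: np.ndarray, values: np.ndarray, threshold: float, interpolation: str
) -> float | None:
    """First upward crossing of ``threshold`` on the axis ``x``.

    A value exactly equal to the threshold at a frame yields that frame's
    coordinate.  Returns ``None`` when the threshold is never reached.
    """
    above = values >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0 or interpolation == "frame" or values[k] == threshold:
        return float(x[k])
    frac = (threshold - values[k - 1]) / (values[k] - values[k - 1])
    return float(x[k - 1] + frac * (x[k] - x[k - 1]))


def detect_response_time(
    times: np.ndarray,
    values: np.ndarray,
    threshold: float,
    interpolation: str = "linear",
) -> float | None:
    """Response time as the first post-stress crossing of ``threshold``.

    Only frames with ``times >= 0`` are considered.  ``None`` marks a
    non-responder (threshold never reached).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    post = times >= 0
    if not post.any():
        raise ValueError("trajectory has no post-stress frames")
    return _first_crossing(times[post], values[post], threshold, interpolation)


def halfmax_response_time(
    times: np.ndarray, values: np.ndarray, interpolation: str = "linear"
) -> float:
    """Time until half of the trajectory's own maximum expression.

    The maximum is taken over post-stress frames and must be positive.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    post = times >= 0
    if not post.any():
        raise ValueError("trajectory has no post-stress frames")
    vmax = values[post].max()
    if vmax <= 0:
        raise ValueError("non-positive maximum expression; half-max undefined")
    t = _first_crossing(times[post], values[post], vmax / 2.0, interpolation)
    assert t is not None  # half of the max is always reached
    return t


def _trajectory_axis(tr: Trajectory, config: ResponseTimeConfig) -> np.ndarray:
    if config.time_axis == "hours":
        return tr.times
    segments = [(tr.times[s], tr.sizes[s]) for s in tr.segments]
    _, doublings = doubling_series(segments)
    return doublings


def response_times(
    expr: ExpressionTraceSet,
    config: ResponseTimeConfig | None = None,
    measure: str = "threshold",
) -> ResponseTimeSet:
    """Detect response times for every trajectory of every colony.

    ``measure="threshold"`` uses the colony-level threshold from the
    responder-median trace; ``measure="halfmax"`` uses half of each
    trajectory's own maximum.  The reported ``responder_fraction`` is the
    fraction of trajectories that reached the applicable threshold.
    """
    if measure not in ("threshold", "halfmax"):
        raise ValueError(f"unknown measure {measure!r}")
    config = config or ResponseTimeConfig()
    trajectories = extract_trajectories(expr)
    rows, frac_rows = [], []
    colonies: dict[str, list[Trajectory]] = {}
    for tr in trajectories:
        colonies.setdefault(tr.colony_id, []).append(tr)

    for colony, trs in colonies.items():
        for ch in expr.channels:
            if measure == "threshold":
                responders, _ = find_responders(trs, ch, config)
                thr = colony_threshold(responders, ch, config)
            n_crossed = 0
            for tr in trs:
                axis = _trajectory_axis(tr, config)
                post = tr.times >= 0
                if measure == "threshold":
                    rt = _first_crossing(
                        axis[post], tr.values[ch][post], thr, config.interpolation
                    )
                    thr_used = thr
                else:
                    vmax = tr.values[ch][post].max()
                    thr_used = vmax / 2.0 if vmax > 0 else np.nan
                    rt = (
                        _first_crossing(
                            axis[post], tr.values[ch][post], thr_used, config.interpolation
                        )
                        if vmax > 0
                        else None
                    )
                responded = rt is not None
                n_crossed += responded
                rows.append(
                    {
                        "colony_id": colony,
                        "founder_id": tr.founder_id,
                        "trajectory_id": tr.leaf_id,
                        "channel": ch,
                        "measure": measure,
                        "response_time": rt if responded else np.nan,
                        "responded": int(responded),
                        "threshold_used": thr_used,
                    }
                )
            frac_rows.append(
                {
                    "colony_id": colony,
                    "channel": ch,
                    "measure": measure,
                    "responder_fraction": n_crossed / len(trs),
                }
            )
    return ResponseTimeSet(
        table=pd.DataFrame(rows), fractions=pd.DataFrame(frac_rows), config=config
    )
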