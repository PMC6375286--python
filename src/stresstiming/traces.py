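"""Trace tables and preprocessing of raw single-cell fluorescence.

The on-disk format is a long, tab-separated table with one row per cell per
frame: ``colony_id, cell_id, parent_id, frame, time_h, area,
fluor_<channel>..., bg_<channel>...`` where ``parent_id`` is empty for tree
roots and ``bg_<channel>`` (optional) is the per-pixel background outside
cells.  This mirrors the output of segmentation-and-tracking pipelines for
microcolony time-lapse movies.

Preprocessing converts raw totals into expression levels (total fluorescence
divided by cell area, minus per-pixel background and autofluorescence),
computes instantaneous growth rates from log cell size, and builds
continuous cumulative-doubling curves across cell divisions.  Corrected
expression may go negative after subtraction and is deliberately not
clamped: clamping would bias threshold crossings near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "ExpressionTraceSet",
    "Trajectory",
    "read_trace_table",
    "write_trace_table",
    "validate_trace_table",
    "compute_expression",
    "normalize_traces",
    "moving_average",
    "growth_rate_series",
    "doubling_series",
    "population_average",
    "extract_trajectories",
]

REQUIRED_COLUMNS = ["colony_id", "cell_id", "parent_id", "frame", "time_h", "area"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for turning raw totals into corrected expression."""

    background_mode: str = "per_frame"  # or "constant"
    autofluorescence_mode: str = "constant"  # or "per_timepoint"
    growth_window: int = 3
    doubling_window: int = 5
    extrapolation_points: int = 3

    def __post_init__(self) -> None:
        if self.background_mode not in ("per_frame", "constant"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.autofluorescence_mode not in ("constant", "per_timepoint"):
            raise ValueError(
                f"unknown autofluorescence_mode {self.autofluorescence_mode!r}"
            )
        for w in (self.growth_window, self.doubling_window):
            if w < 1 or w % 2 == 0:
                raise ValueError(f"smoothing windows must be odd and >= 1, got {w}")
        if self.extrapolation_points < 2:
            raise ValueError("extrapolation_points must be >= 2")


@dataclass
class ExpressionTraceSet:
    """Corrected per-area expression per cell per channel.

    ``data`` keeps the lineage columns of the source table plus one
    ``expr_<channel>`` column per channel, on the identical frame grid.
    """

    data: pd.DataFrame
    channels: list[str]
    metadata: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """One root-to-leaf path through a colony, concatenated frame-wise."""

    colony_id: str
    leaf_id: int
    founder_id: int
    cell_path: list[int]
    times: np.ndarray
    values: dict[str, np.ndarray]
    sizes: np.ndarray
    segments: list[slice]  # frame spans of each cell on the path


def _fluor_channels(df: pd.DataFrame) -> list[str]:
    return [c.removeprefix("fluor_") for c in df.columns if c.startswith("fluor_")]


def validate_trace_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and lineage invariants; return the validated frame.

    Raises ``ValueError`` naming the offending cell for missing columns,
    orphan parents, non-monotone times, non-contiguous parent/child frames,
    or non-positive areas.  Unknown extra columns are preserved with a
    warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table is missing required columns: {missing}")
    channels = _fluor_channels(df)
    if not channels:
        raise ValueError("trace table has no fluor_<channel> column")
    known = set(REQUIRED_COLUMNS) | {f"fluor_{c}" for c in channels} | {
        f"bg_{c}" for c in channels
    }
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"trace table has unknown extra columns {extra}; preserved")

    if (df["area"] <= 0).any():
        bad = df.loc[df["area"] <= 0].iloc[0]
        raise ValueError(f"non-positive area for cell {bad['cell_id']} frame {bad['frame']}")

    for (colony, cid), grp in df.groupby(["colony_id", "cell_id"], sort=False):
        t = grp["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times not strictly increasing for cell {cid} in colony {colony}"
            )

    for colony, cdf in df.groupby("colony_id", sort=False):
        ids = set(cdf["cell_id"])
        first_frame = cdf.groupby("cell_id")["frame"].min()
        last_frame = cdf.groupby("cell_id")["frame"].max()
        child_rows = cdf.loc[cdf["parent_id"].notna(), ["cell_id", "parent_id"]]
        for cid, pid in child_rows.drop_duplicates().itertuples(index=False):
            if pid not in ids:
                raise ValueError(
                    f"cell {cid} in colony {colony} references absent parent {pid}"
                )
            if first_frame[cid] != last_frame[pid] + 1:
                raise ValueError(
                    f"cell {cid} in colony {colony} does not start on the frame "
                    f"after its parent {pid} ends"
                )
    return df


def read_trace_table(path) -> pd.DataFrame:
    """Read and validate a tab-separated trace table."""
    df = pd.read_csv(path, sep="\t")
    if "parent_id" in df.columns:
        df["parent_id"] = df["parent_id"].astype("Int64")
    return validate_trace_table(df)


def write_trace_table(df: pd.DataFrame, path) -> None:
    """Write a trace table as tab-separated text (empty parent for roots)."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def compute_expression(
    table: pd.DataFrame,
    config: PreprocessConfig | None = None,
    background: Mapping[str, float] | None = None,
    autofluorescence: Mapping[str, float | pd.Series] | None = None,
) -> ExpressionTraceSet:
    """Correct raw totals into per-area expression levels.

    ``expression = total / area - per_pixel_background - autofluorescence``.
    Background comes from the ``bg_<channel>`` column (``per_frame`` mode) or
    from the ``background`` mapping (``constant`` mode).  Autofluorescence is
    a per-channel constant, or -- in ``per_timepoint`` mode -- a pandas
    Series of control-strain mean expression indexed by frame, which must
    cover every frame in the table.  Values are not clamped at zero.
    """
    config = config or PreprocessConfig()
    background = dict(background or {})
    autofluorescence = dict(autofluorescence or {})
    channels = _fluor_channels(table)
    out = table[REQUIRED_COLUMNS].copy()

    for ch in channels:
        per_area = table[f"fluor_{ch}"] / table["area"]
        if config.background_mode == "per_frame":
            col = f"bg_{ch}"
            if col not in table.columns:
                raise ValueError(
                    f"background_mode='per_frame' but column {col!r} is missing"
                )
            per_area = per_area - table[col]
        else:
            per_area = per_area - float(background.get(ch, 0.0))

        auto = autofluorescence.get(ch, 0.0)
        if config.autofluorescence_mode == "per_timepoint":
            if not isinstance(auto, pd.Series):
                raise ValueError(
                    f"per_timepoint autofluorescence for channel {ch!r} must be a "
                    "Series indexed by frame"
                )
            missing = set(table["frame"]) - set(auto.index)
            if missing:
                raise ValueError(
                    f"autofluorescence series for {ch!r} does not cover frames "
                    f"{sorted(missing)[:5]}"
                )
            per_area = per_area - table["frame"].map(auto)
        else:
            per_area = per_area - float(auto)
        out[f"expr_{ch}"] = per_area

    meta = {
        "background_mode": config.background_mode,
        "autofluorescence_mode": config.autofluorescence_mode,
    }
    return ExpressionTraceSet(data=out, channels=channels, metadata=meta)


def normalize_traces(expr: ExpressionTraceSet, mode: str) -> ExpressionTraceSet:
    """Normalize expression traces.

    ``median_full_response`` divides every cell in a colony by the range of
    the colony's pointwise-median trace (cell-to-cell ratios preserved);
    ``own_max`` divides each cell by its own maximum.  A zero-range
    reference raises, naming the colony or cell.
    """
    if mode not in ("median_full_response", "own_max"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    df = expr.data.copy()
    for ch in expr.channels:
        col = f"expr_{ch}"
        if mode == "median_full_response":
            for colony, cdf in df.groupby("colony_id", sort=False):
                med = cdf.groupby("frame")[col].median()
                rng = med.max() - med.min()
                if rng <= 0:
                    raise ValueError(
                        f"zero median-trace range for colony {colony} channel {ch}"
                    )
                df.loc[cdf.index, col] = cdf[col] / rng
        else:
            for (colony, cid), cdf in df.groupby(["colony_id", "cell_id"], sort=False):
                vals = cdf[col]
                if vals.max() - vals.min() <= 0:
                    raise ValueError(
                        f"constant trace for cell {cid} in colony {colony} channel {ch}"
                    )
                if vals.max() <= 0:
                    raise ValueError(
                        f"non-positive maximum for cell {cid} in colony {colony}"
                    )
                df.loc[cdf.index, col] = vals / vals.max()
    out = ExpressionTraceSet(df, list(expr.channels), dict(expr.metadata))
    out.metadata["normalization"] = mode
    return out


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, windows shrinking symmetrically at the edges.

    Symmetric shrinking keeps the filter unbiased on linear trends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(x, dtype=float)
    if window == 1:
        return x.copy()
    h = window // 2
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    k = np.minimum(h, np.minimum(i, n - 1 - i))
    return (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)


def growth_rate_series(
    times: np.ndarray, sizes: np.ndarray, window: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous growth rate from log cell size.

    Raw rate between frames is ``diff(log(size)) / diff(t)``; a centered
    moving average of the given window smooths it.  Returns
    ``(mid_times, rates)`` with one value per frame interval.
    """
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two frames for a growth rate")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    raw = np.diff(np.log(sizes)) / np.diff(times)
    mid = 0.5 * (times[:-1] + times[1:])
    return mid, moving_average(raw, window)


def doubling_series(
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
    window: int = 5,
    extrapolation_points: int = 3,
    t_zero: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative doublings along a single trajectory through divisions.

    ``segments`` is the list of ``(times, sizes)`` arrays of each cell on a
    root-to-leaf path, in order.  ``log2(size)`` drops by ~1 at each
    division; continuity is restored by linearly extrapolating the previous
    cell's last ``extrapolation_points`` log2 values to the child's first
    frame and shifting the child up by the gap.  The curve is then shifted
    so that its value at ``t_zero`` (stress addition) is 0 doublings and
    smoothed with a centered moving average.
    """
    if not segments:
        raise ValueError("empty trajectory")
    all_t: list[np.ndarray] = []
    all_d: list[np.ndarray] = []
    offset = 0.0
    for si, (t, s) in enumerate(segments):
        t = np.asarray(t, dtype=float)
        log2s = np.log2(np.asarray(s, dtype=float))
        if si > 0:
            prev_t, prev_d = all_t[-1], all_d[-1]
            k = min(extrapolation_points, prev_t.size)
            if k < 2:
                raise ValueError(
                    f"segment {si - 1} has only {prev_t.size} frame(s); cannot fit "
                    "the pre-division extrapolation line"
                )
            coef = np.polyfit(prev_t[-k:], prev_d[-k:], 1)
            predicted = np.polyval(coef, t[0])
            offset = predicted - log2s[0]
        all_t.append(t)
        all_d.append(log2s + offset)
    times = np.concatenate(all_t)
    doublings = np.concatenate(all_d)
    if np.any(np.diff(times) <= 0):
        raise ValueError("trajectory times must be strictly increasing across segments")
    doublings = doublings - np.interp(t_zero, times, doublings)
    return times, moving_average(doublings, window)


def population_average(
    traces: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize each population trace to [0, 1], then average.

    Returns the pointwise mean and standard deviation (ddof=0) over traces.
    All traces must share one time grid (equal lengths).
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    n = len(traces[0])
    normed = []
    for i, tr in enumerate(traces):
        tr = np.asarray(tr, dtype=float)
        if tr.size != n:
            raise ValueError(f"trace {i} has length {tr.size}, expected {n}")
        rng = tr.max() - tr.min()
        if rng <= 0:
            raise ValueError(f"trace {i} has zero range; cannot normalize")
        normed.append((tr - tr.min()) / rng)
    arr = np.vstack(normed)
    return arr.mean(axis=0), arr.std(axis=0)


def extract_trajectories(expr: ExpressionTraceSet) -> list[Trajectory]:
    """Build all root-to-leaf trajectories of every colony.

    The founder on a path is the first cell with a frame at or after time
    zero, i.e. the cell alive at stress addition.
    """
    out: list[Trajectory] = []
    df = expr.data
    for colony, cdf in df.groupby("colony_id", sort=False):
        parents = (
            cdf[["cell_id", "parent_id"]]
            .drop_duplicates()
            .set_index("cell_id")["parent_id"]
        )
        children: dict[int, list[int]] = {cid: [] for cid in parents.index}
        for cid, pid in parents.items():
            if pd.notna(pid):
                children[pid].append(cid)
        leaves = [cid for cid, kids in children.items() if not kids]
        groups = {cid: g for cid, g in cdf.groupby("cell_id", sort=False)}
        for leaf in sorted(leaves):
            path = [leaf]
            while pd.notna(parents[path[-1]]):
                path.append(parents[path[-1]])
            path = path[::-1]
            segs = [groups[cid] for cid in path]
            times = np.concatenate([s["time_h"].to_numpy() for s in segs])
            sizes = np.concatenate([s["area"].to_numpy() for s in segs])
            values = {
                ch: np.concatenate([s[f"expr_{ch}"].to_numpy() for s in segs])
                for ch in expr.channels
            }
            slices, pos = [], 0
            for s in segs:
                slices.append(slice(pos, pos + len(s)))
                pos += len(s)
            founder = None
            for cid, sl in zip(path, slices):
                if np.any(times[sl] >= 0):
                    founder = cid
                    break
            if founder is None:
                continue  # trajectory ends before stress addition
            out.append(
                Trajectory(
                    colony_id=colony,
                    leaf_id=leaf,
                    founder_id=founder,
                    cell_path=path,
                    times=times,
                    values=values,
                    sizes=sizes,
                    segments=slices,
                )
            )
    return out
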