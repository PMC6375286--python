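"""Synthetic microcolonies: lineage trees and dual-reporter fluorescence traces.

Emulates time-lapse data from exponentially growing, dividing bacteria in a
microcolony.  The stressor is added at time zero; cells alive at that moment
are the *founders*, the units of statistical independence downstream.  Each
founder lineage carries a latent activation time per reporter channel drawn
from a chain-completion model (:mod:`stresstiming.chains`); descendants
inherit that time, optionally perturbed at each division.  Traces are
rendered as total fluorescence per cell per frame, including fluorescent
protein maturation delay, per-frame photobleaching, autofluorescence (with an
optional linear drift), a constant per-pixel background, and Gaussian
measurement noise, so the downstream preprocessing has realistic work to do.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .chains import ChainSpec, DualChainSpec, sample_dual_times, sample_erlang

__all__ = [
    "ReporterSpec",
    "SimConfig",
    "CellRecord",
    "LineageTree",
    "simulate_lineage",
    "assign_activation_times",
    "render_traces",
    "generate_dataset",
]

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class ReporterSpec:
    """Optical model of one fluorescent reporter channel.

    production_rate is fluorescence units per hour per unit area once the
    promoter is active and the protein matured; maturation_time delays
    detectability (hours); decay_rate is a first-order loss of mature
    reporter (1/h) -- with it, per-area expression relaxes to its plateau at
    rate ``growth_rate + decay_rate``, so the observable rise can be fast
    compared with dilution alone; bleach_per_frame is the fraction of mature
    signal lost at each imaging frame; autofluorescence (per unit area) may
    drift linearly at autofluorescence_trend per hour; noise_sd is the
    Gaussian measurement noise on total fluorescence.
    """

    production_rate: float = 100.0
    maturation_time: float = 10.0 / 60.0
    decay_rate: float = 0.0
    bleach_per_frame: float = 0.0
    autofluorescence: float = 0.0
    autofluorescence_trend: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.production_rate < 0:
            raise ValueError("production_rate must be >= 0")
        if self.maturation_time < 0:
            raise ValueError("maturation_time must be >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if not 0 <= self.bleach_per_frame < 1:
            raise ValueError("bleach_per_frame must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic microcolony experiment.

    Durations are hours; time zero is stress addition.  ``chain`` is a
    :class:`ChainSpec` (single channel) or :class:`DualChainSpec` (two
    channels); ``reporters`` maps channel names to :class:`ReporterSpec`, in
    the order (A, B) for a dual chain.  ``seed`` fixes all randomness.
    """

    n_founders: int = 20
    growth_rate_mean: float = 0.35
    growth_rate_sd: float = 0.0
    division_size_ratio: float = 2.0
    division_ratio_sd: float = 0.0
    frame_interval: float = 1.0 / 6.0
    pre_stress_duration: float = 1.0
    post_stress_duration: float = 8.0
    chain: ChainSpec | DualChainSpec = field(
        default_factory=lambda: ChainSpec(n_steps=8, mean_time=2.0)
    )
    reporters: Mapping[str, ReporterSpec] = field(
        default_factory=lambda: {"yfp": ReporterSpec()}
    )
    background: Mapping[str, float] = field(default_factory=dict)
    lineage_jitter_sd: float = 0.0
    randomize_initial_size: bool = True
    colony_id: str = "colony1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError(f"n_founders must be >= 1, got {self.n_founders}")
        if self.growth_rate_sd < 0:
            raise ValueError("growth_rate_sd must be >= 0")
        if self.growth_rate_mean <= 0:
            raise ValueError("growth_rate_mean must be > 0")
        if self.frame_interval <= 0 or self.pre_stress_duration < 0:
            raise ValueError("durations must be positive")
        if self.frame_interval > self.post_stress_duration:
            raise ValueError("frame_interval must not exceed post_stress_duration")
        if self.division_size_ratio <= 1:
            raise ValueError("division_size_ratio must exceed 1")
        if self.lineage_jitter_sd < 0:
            raise ValueError("lineage_jitter_sd must be >= 0")
        n_ch = 2 if isinstance(self.chain, DualChainSpec) else 1
        if len(self.reporters) != n_ch:
            raise ValueError(
                f"chain implies {n_ch} channel(s) but {len(self.reporters)} reporter(s) given"
            )

    @property
    def channels(self) -> list[str]:
        return list(self.reporters)


@dataclass
class CellRecord:
    """One tracked cell: lineage links, growth parameters, per-frame sizes."""

    cell_id: int
    parent_id: int | None
    birth_time: float
    division_time: float | None  # None for cells alive at the end
    growth_rate: float
    birth_size: float
    frames: np.ndarray  # frame indices into the colony frame grid
    times: np.ndarray
    sizes: np.ndarray


@dataclass
class LineageTree:
    """A simulated microcolony: cells keyed by id plus the common frame grid."""

    cells: dict[int, CellRecord]
    frame_times: np.ndarray
    colony_id: str = "colony1"

    @property
    def founders(self) -> list[int]:
        """Cells alive at stress addition (time zero), in id order."""
        out = []
        for cid, c in self.cells.items():
            div = math.inf if c.division_time is None else c.division_time
            if c.birth_time <= _TIME_EPS and div > _TIME_EPS:
                out.append(cid)
        return sorted(out)

    @property
    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {cid: [] for cid in self.cells}
        for cid, c in self.cells.items():
            if c.parent_id is not None:
                ch[c.parent_id].append(cid)
        return {k: sorted(v) for k, v in ch.items()}

    @property
    def leaves(self) -> list[int]:
        ch = self.children
        return sorted(cid for cid, kids in ch.items() if not kids)

    def path_to_root(self, cell_id: int) -> list[int]:
        """Ids from the tree root down to ``cell_id`` (inclusive)."""
        path = [cell_id]
        while self.cells[path[-1]].parent_id is not None:
            path.append(self.cells[path[-1]].parent_id)
        return path[::-1]

    def descendants(self, cell_id: int) -> list[int]:
        ch = self.children
        out, stack = [], [cell_id]
        while stack:
            cid = stack.pop()
            for kid in ch[cid]:
                out.append(kid)
                stack.append(kid)
        return sorted(out)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero by rejection."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("could not draw a positive growth rate; sd too large vs mean")


def simulate_lineage(config: SimConfig) -> LineageTree:
    """Grow a microcolony of exponentially elongating, dividing cells.

    Each cell elongates as ``size(t) = birth_size * exp(g (t - birth))`` with
    a per-cell rate ``g`` from a normal truncated at zero, and divides into
    two equal daughters when it reaches ``division_size_ratio`` times its
    birth size (ratio perturbed lognormally by ``division_ratio_sd``).  The
    ``n_founders`` initial cells are born at ``-pre_stress_duration``; per-
    frame sizes are emitted on the common frame grid.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11]))
    t0 = -config.pre_stress_duration
    t_end = config.post_stress_duration
    # grid never exceeds t_end; a division after the last frame would be
    # unobservable and is treated as not having happened
    n_frames = int(math.floor((t_end - t0) / config.frame_interval + 1e-9)) + 1
    frame_times = t0 + config.frame_interval * np.arange(n_frames)
    t_last = float(frame_times[-1])

    cells: dict[int, CellRecord] = {}
    next_id = 1
    # queue entries: (cell_id, parent_id, birth_time, birth_size, phase)
    # phase in [0, 1) is the fraction of the division cycle already elapsed
    # at birth; nonzero only for initial cells caught mid-cycle.
    queue: deque[tuple[int, int | None, float, float, float]] = deque()
    for _ in range(config.n_founders):
        phase = rng.uniform(0, 1) if config.randomize_initial_size else 0.0
        size0 = float(config.division_size_ratio**phase)
        queue.append((next_id, None, t0, size0, phase))
        next_id += 1

    while queue:
        cid, parent, birth, bsize, phase = queue.popleft()
        g = _positive_normal(rng, config.growth_rate_mean, config.growth_rate_sd)
        ratio = config.division_size_ratio
        if config.division_ratio_sd > 0:
            ratio *= float(np.exp(rng.normal(0.0, config.division_ratio_sd)))
        # remaining log-growth until division: a cell caught at phase p of its
        # cycle only needs the complement of the cycle before dividing
        t_div = birth + (1.0 - phase) * math.log(ratio) / g
        division_time: float | None = t_div if t_div <= t_last + _TIME_EPS else None

        if division_time is None:
            # leaf cells own every remaining frame, including the last
            mask = frame_times >= birth - _TIME_EPS
        else:
            mask = (frame_times >= birth - _TIME_EPS) & (
                frame_times < division_time - _TIME_EPS
            )
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(
                f"cell {cid} (birth {birth:.3f} h, division {division_time}) spans no "
                "imaging frame; decrease frame_interval or slow divisions"
            )
        times = frame_times[idx]
        sizes = bsize * np.exp(g * (times - birth))
        cells[cid] = CellRecord(
            cell_id=cid,
            parent_id=parent,
            birth_time=birth,
            division_time=division_time,
            growth_rate=g,
            birth_size=bsize,
            frames=idx,
            times=times,
            sizes=sizes,
        )
        if division_time is not None:
            size_div = bsize * math.exp(g * (division_time - birth))
            for _ in range(2):
                queue.append((next_id, cid, division_time, size_div / 2.0, 0.0))
                next_id += 1

    return LineageTree(cells=cells, frame_times=frame_times, colony_id=config.colony_id)


def assign_activation_times(
    tree: LineageTree,
    chain: ChainSpec | DualChainSpec,
    lineage_jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[int, np.ndarray]:
    """Draw latent activation times per founder lineage.

    One activation time per channel is drawn for every founder from the
    chain-completion model and inherited by all its descendants; each
    division may perturb the inherited time by zero-mean Gaussian jitter of
    sd ``lineage_jitter_sd`` (hours).  Cells that only exist before stress
    addition get ``+inf`` (they never activate within their lifetime).

    Returns a mapping cell_id -> array of shape (n_channels,).
    """
    founders = tree.founders
    if not founders:
        raise ValueError("tree has no founder cells alive at time zero")
    rng = np.random.default_rng(seed)
    if isinstance(chain, DualChainSpec):
        base = sample_dual_times(chain, len(founders), rng)
    else:
        base = sample_erlang(chain, len(founders), rng)[:, None]
    n_ch = base.shape[1]

    times: dict[int, np.ndarray] = {
        cid: np.full(n_ch, np.inf) for cid in tree.cells
    }
    children = tree.children
    for founder, t_f in zip(founders, base):
        times[founder] = np.asarray(t_f, dtype=float)
        stack = [founder]
        while stack:
            cid = stack.pop()
            for kid in children[cid]:
                t_kid = times[cid].copy()
                if lineage_jitter_sd > 0:
                    t_kid = t_kid + rng.normal(0.0, lineage_jitter_sd, size=n_ch)
                    t_kid = np.maximum(t_kid, _TIME_EPS)
                times[kid] = t_kid
                stack.append(kid)
    return times


def _advance_mature(
    m: float,
    rep: "ReporterSpec",
    birth_size: float,
    g: float,
    birth: float,
    a: float,
    b: float,
    on_from: float,
) -> float:
    """Mature reporter amount at time ``b`` given amount ``m`` at time ``a``.

    Solves ``dM/dt = production_rate * size(t) * [t >= on_from] -
    decay_rate * M`` with ``size(t) = birth_size * exp(g (t - birth))``.
    """
    lam = rep.decay_rate
    out = m * math.exp(-lam * (b - a)) if lam > 0 else m
    a_on = max(a, on_from)
    if b <= a_on or rep.production_rate == 0:
        return out
    k = g + lam
    if k == 0:
        return out + rep.production_rate * birth_size * (b - a_on)
    return out + (
        rep.production_rate
        * birth_size
        / k
        * (
            math.exp(g * (b - birth))
            - math.exp(g * (a_on - birth) - lam * (b - a_on))
        )
    )


def render_traces(
    tree: LineageTree,
    activation_times: Mapping[int, np.ndarray],
    reporters: Mapping[str, ReporterSpec],
    seed: int | np.random.Generator = 0,
    background: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Render total-fluorescence traces per cell per frame.

    Mature reporter accumulates at ``production_rate * area`` once the
    channel's activation time plus maturation has passed, is split equally
    between the two (equal-sized) daughters at division, and loses
    ``bleach_per_frame`` of its amount at every imaging frame (after the
    frame is recorded).  Emitted totals are mature signal plus
    (autofluorescence + trend * t + per-pixel background) * area plus
    Gaussian noise.  Returns a long-format trace table.
    """
    background = dict(background or {})
    rng = np.random.default_rng(seed)
    channels = list(reporters)
    for ch in channels:
        background.setdefault(ch, 0.0)

    # inherited mature amount per cell per channel, filled in tree order
    inherited: dict[int, np.ndarray] = {}
    rows_cell, rows_frame, rows_time, rows_area = [], [], [], []
    fluor: dict[str, list[float]] = {ch: [] for ch in channels}

    order = sorted(tree.cells, key=lambda cid: (tree.cells[cid].birth_time, cid))
    for cid in order:
        cell = tree.cells[cid]
        act = np.asarray(activation_times[cid], dtype=float)
        if act.shape != (len(channels),):
            raise ValueError(
                f"cell {cid}: expected {len(channels)} activation time(s), got {act.shape}"
            )
        m = inherited.get(cid, np.zeros(len(channels))).copy()
        prev_t = cell.birth_time
        for k in range(cell.times.size):
            t = cell.times[k]
            for j, ch in enumerate(channels):
                rep = reporters[ch]
                m[j] = _advance_mature(
                    m[j],
                    rep,
                    cell.birth_size,
                    cell.growth_rate,
                    cell.birth_time,
                    prev_t,
                    t,
                    act[j] + rep.maturation_time,
                )
            rows_cell.append(cid)
            rows_frame.append(int(cell.frames[k]))
            rows_time.append(float(t))
            rows_area.append(float(cell.sizes[k]))
            for j, ch in enumerate(channels):
                rep = reporters[ch]
                total = m[j] + (
                    rep.autofluorescence
                    + rep.autofluorescence_trend * t
                    + background[ch]
                ) * cell.sizes[k]
                fluor[ch].append(total)
                m[j] *= 1.0 - rep.bleach_per_frame
            prev_t = t
        if cell.division_time is not None:
            for j, ch in enumerate(channels):
                rep = reporters[ch]
                m[j] = _advance_mature(
                    m[j],
                    rep,
                    cell.birth_size,
                    cell.growth_rate,
                    cell.birth_time,
                    prev_t,
                    cell.division_time,
                    act[j] + rep.maturation_time,
                )
            ch_ids = tree.children[cid]
            for kid in ch_ids:
                inherited[kid] = m / 2.0  # equal daughters: proportional split

    table = pd.DataFrame(
        {
            "colony_id": tree.colony_id,
            "cell_id": rows_cell,
            "parent_id": [
                tree.cells[c].parent_id if tree.cells[c].parent_id is not None else pd.NA
                for c in rows_cell
            ],
            "frame": rows_frame,
            "time_h": rows_time,
            "area": rows_area,
        }
    )
    for ch in channels:
        vals = np.asarray(fluor[ch])
        if reporters[ch].noise_sd > 0:
            vals = vals + rng.normal(0.0, reporters[ch].noise_sd, size=vals.size)
        table[f"fluor_{ch}"] = vals
        table[f"bg_{ch}"] = background[ch]
    table["parent_id"] = table["parent_id"].astype("Int64")
    return table.sort_values(["cell_id", "frame"], ignore_index=True)


def generate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, LineageTree]:
    """Simulate a full dataset: trace table, ground truth, and the tree.

    Ground truth has one row per cell per channel with the latent activation
    time, the founder it descends from, and the chain parameters; all
    randomness is derived from ``config.seed``.
    """
    tree = simulate_lineage(config)
    act_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x22]))
    activation = assign_activation_times(
        tree, config.chain, config.lineage_jitter_sd, act_rng
    )
    render_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x33]))
    table = render_traces(tree, activation, config.reporters, render_rng, config.background)

    founders = tree.founders
    founder_of: dict[int, int] = {f: f for f in founders}
    for f in founders:
        for d in tree.descendants(f):
            founder_of[d] = f
    channels = config.channels
    rows = []
    for cid, act in activation.items():
        if cid not in founder_of:
            continue  # pre-stress ancestors carry no latent time
        for j, ch in enumerate(channels):
            rows.append(
                {
                    "colony_id": tree.colony_id,
                    "cell_id": cid,
                    "founder_id": founder_of[cid],
                    "channel": ch,
                    "activation_time_h": act[j],
                }
            )
    truth = pd.DataFrame(rows).sort_values(["cell_id", "channel"], ignore_index=True)
    return table, truth, tree
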