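"""Stability- and aggregation-based heart-rate tracking (SAB-HRT).

Per-window spectral HR estimates are noisy: a window may lock onto a
residual motion component, a harmonic, or nothing at all. The tracker
exploits the physiological fact that true HR moves slowly relative to the
2 s estimate cadence. It works on blocks of 20 consecutive estimates
(40 s at a 2 s window shift):

*   traverse the block's present estimates in order, chaining each value
    onto the most recently updated *stability group* whose last member is
    within 10 bpm, or seeding a new group;
*   keep the largest group as the block's HR values — isolated outliers
    end up in minority groups and are discarded;
*   on a size tie, extend the block forward by half its length (20 s) and
    regroup, up to three times; a persistent tie falls back to the most
    recently updated of the tied groups;
*   linearly interpolate the kept points onto the 2 s output grid and
    smooth with a centred moving average (30 s window by default,
    reducible to 10 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyBlockError, InsufficientDataError

__all__ = [
    "HrEstimate",
    "StabilityGroup",
    "HrTrace",
    "form_stability_groups",
    "select_group",
    "resolve_block",
    "interpolate_block",
    "smooth_trace",
    "track",
]


@dataclass(frozen=True)
class HrEstimate:
    """One per-window HR candidate anchored at the window start time.

    ``hr`` is in bpm, or None when the spectral stage produced no valid peak.
    """

    t: float
    hr: float | None

    @property
    def present(self) -> bool:
        return self.hr is not None and not math.isnan(self.hr)


@dataclass
class StabilityGroup:
    """An ordered chain of (sequence index, hr) pairs, each link <= threshold apart."""

    members: list[tuple[int, float]] = field(default_factory=list)

    @property
    def last_update(self) -> int:
        return self.members[-1][0]

    @property
    def last_hr(self) -> float:
        return self.members[-1][1]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HrTrace:
    """Continuous HR output on a uniform time grid (no missing values)."""

    t: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.shape != self.hr.shape or self.t.ndim != 1:
            raise ConfigurationError("t and hr must be 1-D and equal length")


def form_stability_groups(
    block: list[HrEstimate], threshold: float = 10.0
) -> list[StabilityGroup]:
    """Partition a block's present estimates into stability groups.

    Sequential traversal: the first present HR seeds the first group; each
    subsequent HR joins the group whose last member is within ``threshold``
    bpm, preferring the most recently updated qualifying group; if none
    qualifies a new group is created. Missing estimates are skipped. Every
    present HR lands in exactly one group.
    """
    groups: list[StabilityGroup] = []
    any_present = False
    for idx, est in enumerate(block):
        if not est.present:
            continue
        any_present = True
        qualifying = [g for g in groups if abs(est.hr - g.last_hr) <= threshold]
        if qualifying:
            target = max(qualifying, key=lambda g: g.last_update)
            target.members.append((idx, est.hr))
        else:
            groups.append(StabilityGroup(members=[(idx, est.hr)]))
    if not any_present:
        raise EmptyBlockError("block contains no present HR estimate")
    return groups


def select_group(groups: list[StabilityGroup]) -> StabilityGroup | None:
    """The unique largest group, or None to signal a size tie."""
    if not groups:
        raise ConfigurationError("no groups to select from")
    best = max(g.size for g in groups)
    largest = [g for g in groups if g.size == best]
    if len(largest) > 1:
        return None
    return largest[0]


def resolve_block(
    estimates: list[HrEstimate],
    start: int,
    block_len: int = 20,
    threshold: float = 10.0,
    extension_len: int = 10,
    max_extensions: int = 3,
) -> tuple[list[tuple[float, float]], int]:
    """Group one block, handling ties by forward extension.

    Returns the selected group's ``(t, hr)`` points and the number of
    estimates consumed (the block length after any extensions). A size tie
    extends the block forward by ``extension_len`` estimates (half the
    block, 20 s at the 2 s shift) and regroups, up to ``max_extensions``
    times or until the stream is exhausted; a persistent tie falls back to
    the most recently updated of the tied largest groups. An all-missing
    block yields no points.
    """
    n_avail = len(estimates) - start
    length = min(block_len, n_avail)
    chosen: StabilityGroup | None = None
    for _ in range(max_extensions + 1):
        block = estimates[start : start + length]
        try:
            groups = form_stability_groups(block, threshold=threshold)
        except EmptyBlockError:
            return [], length
        chosen = select_group(groups)
        if chosen is not None or length >= n_avail:
            break
        length = min(length + extension_len, n_avail)
    if chosen is None:
        best = max(g.size for g in groups)
        chosen = max((g for g in groups if g.size == best), key=lambda g: g.last_update)
    points = [(estimates[start + i].t, hr) for i, hr in chosen.members]
    return points, length


def interpolate_block(
    points: list[tuple[float, float]], grid: np.ndarray
) -> HrTrace:
    """Linear interpolation of selected points onto grid timestamps.

    Grid points before the first / after the last selected point take the
    nearest selected value (constant extension).
    """
    if not points:
        raise ConfigurationError("need at least one selected point")
    pts = sorted(points)
    t = np.array([p[0] for p in pts])
    hr = np.array([p[1] for p in pts])
    grid = np.asarray(grid, dtype=float)
    return HrTrace(t=grid, hr=np.interp(grid, t, hr))


def smooth_trace(trace: HrTrace, window_s: float = 30.0) -> HrTrace:
    """Centred moving average over ``window_s``, shrinking at the edges.

    On the 2 s grid a 30 s window covers 15 points and a 10 s window 5
    points. Near the trace ends the window shrinks symmetrically, so the
    output keeps the trace's full span and constants are preserved exactly.
    """
    n = trace.t.size
    if n == 0:
        raise ConfigurationError("empty trace")
    step = float(trace.t[1] - trace.t[0]) if n > 1 else window_s
    half = max(int(round(window_s / step)) // 2, 0)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = trace.hr[i - h : i + h + 1].mean()
    return HrTrace(t=trace.t.copy(), hr=out)


def track(
    estimates: list[HrEstimate],
    block_len: int = 20,
    threshold: float = 10.0,
    extension_len: int = 10,
    max_extensions: int = 3,
    smooth_window_s: float = 30.0,
    grid_step_s: float = 2.0,
) -> HrTrace:
    """Full SAB-HRT pass over a stream of per-window estimates.

    Consumes consecutive non-overlapping blocks, concatenates the selected
    points, interpolates onto the global output grid (bridging inter-block
    gaps linearly for continuity) and smooths. A terminal partial block is
    processed when at least half a block remains, and dropped otherwise.
    """
    if len(estimates) < block_len:
        raise InsufficientDataError(
            f"tracking starts once {block_len} estimates are collected"
        )
    points: list[tuple[float, float]] = []
    pos = 0
    while len(estimates) - pos >= block_len:
        block_points, consumed = resolve_block(
            estimates,
            pos,
            block_len=block_len,
            threshold=threshold,
            extension_len=extension_len,
            max_extensions=max_extensions,
        )
        points.extend(block_points)
        pos += consumed
    remaining = len(estimates) - pos
    if remaining >= block_len // 2:
        block_points, consumed = resolve_block(
            estimates,
            pos,
            block_len=remaining,
            threshold=threshold,
            extension_len=extension_len,
            max_extensions=max_extensions,
        )
        points.extend(block_points)
    if not points:
        raise InsufficientDataError("no block produced a selected group")
    points.sort()
    t0, t1 = points[0][0], points[-1][0]
    grid = t0 + grid_step_s * np.arange(int(round((t1 - t0) / grid_step_s)) + 1)
    trace = interpolate_block(points, grid)
    return smooth_trace(trace, window_s=smooth_window_s)
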