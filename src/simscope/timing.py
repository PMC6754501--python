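"""Acquisition timing: interleaved SLM/camera/laser scheduling and frame rates.

The additive model: a raw-frame slot is ``exposure + slm_switch (+ overhead)``;
a camera's readout must finish before its next exposure, otherwise the
sequence waits.  For a single channel this reduces to
``exposure + switch + readout_delay`` per raw frame.  All internal times are
kept exact in ms; floor rounding to integer fps happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np

from simscope.model import FRAMES_PER_SET

__all__ = [
    "TimingConfig",
    "TimingEvent",
    "TimingPlan",
    "fov_extent",
    "frame_rate_table",
    "plan_acquisition",
    "readout_delay_ms",
    "span",
    "timestamp_series",
]

SLM_SWITCH_MS_DEFAULT = 0.44
# anchor points: extra delay the SLM sequence waits for camera readout
_READOUT_ANCHORS = ((256, 0.85), (512, 2.1))
MAX_ROI_LINES = 2048


def readout_delay_ms(roi_lines: int) -> float:
    """Extra per-frame delay waiting for camera readout, by ROI height.

    Linear through the anchor points (256 lines → 0.85 ms, 512 lines →
    2.1 ms), extrapolated, clamped at 0: for small fields (≤ ~80 lines) the
    readout hides entirely inside the SLM switch time.
    """
    if not 1 <= roi_lines <= MAX_ROI_LINES:
        raise ValueError(f"roi_lines outside supported range 1..{MAX_ROI_LINES}: {roi_lines}")
    (l0, d0), (l1, d1) = _READOUT_ANCHORS
    slope = (d1 - d0) / (l1 - l0)
    return max(0.0, d0 + (roi_lines - l0) * slope)


def fov_extent(lines: int, pixel_size_um: float = 0.08) -> float:
    """Field-of-view height in µm for a given number of camera lines."""
    if lines < 1:
        raise ValueError(f"lines must be >= 1, got {lines}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be positive, got {pixel_size_um}")
    return lines * pixel_size_um


@dataclass(frozen=True)
class TimingConfig:
    exposure_ms: float = 1.0
    n_channels: int = 1
    roi_lines: int = 512
    slm_switch_ms: float = SLM_SWITCH_MS_DEFAULT
    pixel_size_um: float = 0.08
    interframe_delay_ms: float = 0.0
    overhead_ms: float = 0.0  # calibration term for unmodeled per-frame overhead

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 3:
            raise ValueError(f"n_channels must be 1..3, got {self.n_channels}")
        for name in ("exposure_ms", "slm_switch_ms", "interframe_delay_ms", "overhead_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exposure_ms == 0 and self.slm_switch_ms == 0:
            raise ValueError("degenerate config: zero exposure with zero SLM switch time")
        readout_delay_ms(self.roi_lines)  # validates range


@dataclass(frozen=True)
class TimingEvent:
    t_start_ms: float
    t_end_ms: float
    device: str  # "SLM", "camera_<c>", "laser_<c>"
    state: str  # "expose", "switch", "readout", "on"


@dataclass
class TimingPlan:
    config: TimingConfig
    events: list[TimingEvent]
    slot_ms: float  # effective per-raw-frame slot (one channel's frame)
    cycle_ms: float  # one SIM frame, all channels, incl. interframe delay
    sim_fps: float
    raw_fps: float
    duty_cycle: dict[int, float]
    feasible: bool = True

    @property
    def sim_fps_int(self) -> int:
        """Frame rate floored to an integer (presentation convention)."""
        return int(np.floor(self.sim_fps))


def plan_acquisition(config: TimingConfig) -> TimingPlan:
    """Build the interleaved event schedule and achievable frame rates.

    Channels take turns exposing (round-robin); each camera reads out during
    the other channels' slots.  If a camera's readout would not finish before
    its next exposure, every slot is stretched just enough.
    """
    n = config.n_channels
    switch = config.slm_switch_ms
    delay = readout_delay_ms(config.roi_lines)
    readout_ms = switch + delay  # full camera processing time after exposure end
    slot = config.exposure_ms + switch + config.overhead_ms
    # time from a camera's exposure end to its next exposure start is
    # n*slot - exposure; stretch slots if readout does not fit
    gap = n * slot - config.exposure_ms
    if gap < readout_ms:
        slot += (readout_ms - gap) / n
    cycle = FRAMES_PER_SET * n * slot + config.interframe_delay_ms
    sim_fps = 1000.0 / cycle
    raw_fps = FRAMES_PER_SET * n * sim_fps
    duty = {c: FRAMES_PER_SET * config.exposure_ms / cycle for c in range(n)}

    events: list[TimingEvent] = []
    t = 0.0
    for _raw_idx in range(FRAMES_PER_SET):
        for c in range(n):
            e0, e1 = t, t + config.exposure_ms
            events.append(TimingEvent(e0, e1, f"camera_{c}", "expose"))
            events.append(TimingEvent(e0, e1, f"laser_{c}", "on"))
            events.append(TimingEvent(e1, e1 + switch, "SLM", "switch"))
            events.append(TimingEvent(e1, e1 + readout_ms, f"camera_{c}", "readout"))
            t += slot
    return TimingPlan(config=config, events=events, slot_ms=slot, cycle_ms=cycle,
                      sim_fps=sim_fps, raw_fps=raw_fps, duty_cycle=duty)


def span(n_frames: int, sim_fps: float) -> float:
    """Wall-clock seconds covered by ``n_frames`` SIM frames at ``sim_fps``."""
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if sim_fps <= 0:
        raise ValueError("sim_fps must be positive")
    return n_frames / sim_fps


def timestamp_series(plan: TimingPlan, n_sim_frames: int, t0_ns: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-raw-frame and per-SIM-frame timestamps (ns), strictly increasing.

    Raw timestamps mark exposure-end instants in acquisition order; a SIM
    frame's timestamp is its last raw frame's.
    """
    if not plan.feasible:
        raise ValueError("cannot generate timestamps for an infeasible plan")
    n = plan.config.n_channels
    expose_end_offsets = []
    t = 0.0
    for _raw in range(FRAMES_PER_SET):
        for _c in range(n):
            expose_end_offsets.append(t + plan.config.exposure_ms)
            t += plan.slot_ms
    offsets = np.asarray(expose_end_offsets)
    raw_ts = []
    for s in range(n_sim_frames):
        raw_ts.append(t0_ns + np.round((s * plan.cycle_ms + offsets) * 1e6).astype(np.int64))
    raw_ts_arr = (np.concatenate(raw_ts) if raw_ts
                  else np.empty(0, dtype=np.int64))
    sim_ts = raw_ts_arr[FRAMES_PER_SET * n - 1:: FRAMES_PER_SET * n] if n_sim_frames else \
        np.empty(0, dtype=np.int64)
    return raw_ts_arr, sim_ts


def frame_rate_table(exposures_ms: Sequence[float], channels: Sequence[int],
                     roi_lines: Sequence[int], **config_kwargs) -> tuple[list[dict], str]:
    """Tabulate integer fps and duty cycles over a parameter grid.

    Returns the rows (dicts) and a formatted text table.
    """
    if not exposures_ms or not channels or not roi_lines:
        raise ValueError("all parameter lists must be non-empty")
    rows = []
    for n_ch in channels:
        for lines in roi_lines:
            for exp in exposures_ms:
                plan = plan_acquisition(TimingConfig(
                    exposure_ms=exp, n_channels=n_ch, roi_lines=lines, **config_kwargs))
                rows.append({
                    "channels": n_ch, "exposure_ms": exp, "roi_lines": lines,
                    "fps": plan.sim_fps_int, "sim_fps_exact": plan.sim_fps,
                    "duty_cycle": plan.duty_cycle[0],
                })
    buf = StringIO()
    buf.write(f"{'ch':>3} {'lines':>6} {'exp_ms':>7} {'fps':>5} {'duty':>6}\n")
    for r in rows:
        buf.write(f"{r['channels']:>3} {r['roi_lines']:>6} {r['exposure_ms']:>7.2f} "
                  f"{r['fps']:>5d} {r['duty_cycle']:>6.1%}\n")
    return rows, buf.getvalue()
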