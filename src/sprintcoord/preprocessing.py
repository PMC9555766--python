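"""Filtering, step segmentation, limb roles and time normalization.

A *step* spans one toe-off to the next toe-off of the contralateral leg,
beginning with front-foot block clearance (the first toe-off).  The swing
leg at the opening toe-off is the *leading* limb for the step (it touches
down within the step); the stance leg at that toe-off is *trailing*.  Roles
alternate every step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError, SegmentationError, SpanError
from .io import AnalysisConfig, AngleSeries, SEGMENTS, Trial, other_side


@dataclass(frozen=True)
class StepWindow:
    """One step: [opening toe-off, touchdown, closing contralateral toe-off]."""

    step_index: int
    t_start: float
    t_td: float
    t_end: float
    leading_side: str
    trailing_side: str

    def __post_init__(self):
        if not (self.t_start < self.t_td < self.t_end):
            raise SegmentationError(
                f"step {self.step_index}: require t_start < t_td < t_end, got "
                f"({self.t_start:g}, {self.t_td:g}, {self.t_end:g})"
            )
        if self.leading_side == self.trailing_side:
            raise SegmentationError(f"step {self.step_index}: identical limb roles")

    @property
    def flight_time(self) -> float:
        """Time from the opening toe-off to touchdown."""
        return self.t_td - self.t_start

    @property
    def contact_time(self) -> float:
        """Time from touchdown to the closing toe-off."""
        return self.t_end - self.t_td

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def touchdown_pct(self) -> float:
        """Touchdown instant as % of normalized step time."""
        return 100.0 * self.flight_time / self.duration


@dataclass
class NormalizedStep:
    """Per-step angle series resampled to a fixed number of points."""

    step_index: int
    angles: dict[str, np.ndarray]
    touchdown_pct: float
    flight_time: float
    contact_time: float
    leading_side: str
    trailing_side: str
    participant_id: str = ""

    @property
    def n_points(self) -> int:
        return next(iter(self.angles.values())).size

    def segment_for_role(self, base: str, role: str) -> np.ndarray:
        """Angle sequence of the sided segment playing ``role`` this step."""
        side = self.leading_side if role == "leading" else self.trailing_side
        from .io import segment_id

        return self.angles[segment_id(base, side)]


def lowpass(series: AngleSeries, cutoff: float | None, order: int = 4) -> AngleSeries:
    """Zero-phase Butterworth low-pass filter; ``cutoff=None`` is a no-op."""
    if cutoff is None:
        return series
    nyq = series.sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff {cutoff:g} Hz must lie in (0, Nyquist={nyq:g}) Hz"
        )
    b, a = butter(order, cutoff / nyq)
    filtered = filtfilt(b, a, series.values)
    return replace(series, values=filtered)


def lowpass_trial(trial: Trial, config: AnalysisConfig) -> Trial:
    series = {
        seg: lowpass(s, config.lowpass_cutoff, config.filter_order)
        for seg, s in trial.series.items()
    }
    return Trial(trial.participant_id, series, list(trial.events), trial.front_block_side)


def assign_limb_roles(step_index: int, front_block_side: str) -> tuple[str, str]:
    """(leading_side, trailing_side) for a step.

    In step 1 the rear-block (swing) leg leads and the front-block leg
    trails; roles swap each subsequent step.
    """
    if step_index < 1:
        raise ParameterError("step_index must be >= 1")
    if step_index % 2 == 1:
        return other_side(front_block_side), front_block_side
    return front_block_side, other_side(front_block_side)


def segment_steps(trial: Trial, n_steps: int | None = None) -> list[StepWindow]:
    """Cut the event list into step windows.

    Events must start with a toe-off (block clearance) and then alternate
    touchdown / contralateral toe-off.  Each window contains exactly one
    touchdown.
    """
    events = sorted(trial.events, key=lambda e: e.time)
    if not events or events[0].kind != "toe_off":
        raise SegmentationError("first event must be the block-clearance toe_off")
    toe_offs = [e for e in events if e.kind == "toe_off"]
    touchdowns = [e for e in events if e.kind == "touchdown"]
    windows: list[StepWindow] = []
    for k in range(1, len(toe_offs)):
        opening, closing = toe_offs[k - 1], toe_offs[k]
        if closing.side != other_side(opening.side):
            raise SegmentationError(
                f"step {k}: closing toe_off must be contralateral to the opening one"
            )
        inside = [e for e in touchdowns if opening.time < e.time < closing.time]
        if len(inside) != 1:
            raise SegmentationError(
                f"step {k}: expected exactly one touchdown in "
                f"[{opening.time:g}, {closing.time:g}], found {len(inside)}"
            )
        td = inside[0]
        if td.side != closing.side:
            raise SegmentationError(
                f"step {k}: touchdown side {td.side} does not match the closing toe_off"
            )
        windows.append(
            StepWindow(
                step_index=k,
                t_start=opening.time,
                t_td=td.time,
                t_end=closing.time,
                leading_side=td.side,
                trailing_side=opening.side,
            )
        )
    if n_steps is not None:
        if len(windows) < n_steps:
            raise SegmentationError(
                f"requested {n_steps} steps but events define only {len(windows)}"
            )
        windows = windows[:n_steps]
    # cross-check role alternation against the block-side rule
    for w in windows:
        lead, trail = assign_limb_roles(w.step_index, trial.front_block_side)
        if (w.leading_side, w.trailing_side) != (lead, trail):
            raise SegmentationError(
                f"step {w.step_index}: event sides inconsistent with "
                f"front_block_side={trial.front_block_side}"
            )
    return windows


def time_normalize(series: AngleSeries, window: StepWindow, n: int) -> np.ndarray:
    """Linearly interpolate the signal at ``n`` equally spaced times over the window."""
    if n < 3:
        raise ParameterError("n must be >= 3")
    if window.t_start < series.start_time or window.t_end > series.end_time:
        raise SpanError(
            f"step {window.step_index} window [{window.t_start:g}, {window.t_end:g}] "
            f"exceeds series span [{series.start_time:g}, {series.end_time:g}]"
        )
    grid = np.linspace(window.t_start, window.t_end, n)
    return np.interp(grid, series.times, series.values)


def normalize_step(trial: Trial, window: StepWindow, config: AnalysisConfig) -> NormalizedStep:
    angles = {
        seg: time_normalize(trial.series[seg], window, config.n_norm_points)
        for seg in SEGMENTS
    }
    return NormalizedStep(
        step_index=window.step_index,
        angles=angles,
        touchdown_pct=window.touchdown_pct,
        flight_time=window.flight_time,
        contact_time=window.contact_time,
        leading_side=window.leading_side,
        trailing_side=window.trailing_side,
        participant_id=trial.participant_id,
    )


def normalize_trial(
    trial: Trial, config: AnalysisConfig, n_steps: int | None = None
) -> list[NormalizedStep]:
    """Filter, segment and time-normalize a trial into per-step records."""
    filtered = lowpass_trial(trial, config)
    windows = segment_steps(filtered, n_steps)
    return [normalize_step(filtered, w, config) for w in windows]
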