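"""Synthetic multi-step sprint kinematics with known coordination ground truth.

The generator builds seven smooth sagittal-plane angle series plus a
consistent gait-event list per participant.  Waveforms are piecewise eased
segments anchored at event-time targets rather than a mechanistic
simulation: enough to carry the coordination structure the analysis assumes
(oscillatory anti-phase thighs with adjustable trailing-leg dominance,
trunk rotation reversals around touchdown, an early-stance dorsiflexion dip
followed by foot-dominant plantarflexion) without modelling dynamics.

Thigh construction gives an analytic ground truth: within every step both
thigh increments stay exactly proportional (trailing = -ratio x leading),
so the coupling angle is constant over the step and the expected bin and
dominancy follow in closed form from the slope ratio.  Linear filtering and
linear time-normalization preserve that proportionality exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigError
from .io import AngleSeries, GaitEvent, Trial, other_side, segment_id, write_trial
from .preprocessing import assign_limb_roles


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Per-step target tuples shorter than ``n_steps`` are extended by
    repeating their last entry.  ``*_sd`` fields are between-participant
    jitter SDs; setting them all to zero yields identical participants.
    """

    n_participants: int = 21
    n_steps: int = 4
    sample_rate: float = 200.0
    front_block_side: str = "right"

    # step timing (seconds)
    flight_mean: float = 0.26
    flight_sd: float = 0.02
    contact_mean: float = 0.19
    contact_sd: float = 0.015
    step_time_jitter_sd: float = 0.008  # within-participant, per step

    # thighs
    thigh_amplitude: float = 25.0
    thigh_amplitude_sd: float = 2.5
    asymmetry_ratio: float = 1.4  # trailing / leading angular-speed ratio
    asymmetry_ratio_sd: float = 0.1
    thigh_start_leading: float = 95.0
    thigh_start_trailing: float = 55.0
    boundary_slope: float = 0.15  # relative easing slope at step boundaries

    # trunk
    trunk_start: float = 35.0
    trunk_start_sd: float = 4.0
    trunk_flight_drop: float = 8.0
    trunk_step_increment: float = 8.0
    trunk_step_increment_sd: float = 1.0

    # stance-leg shank / foot targets per step (degrees)
    shank_td: tuple = (40.0, 50.0, 57.0, 62.0)
    shank_to: tuple = (24.0, 27.0, 29.0, 30.0)
    foot_td: tuple = (-25.0, -15.0, -10.0, -8.0)
    foot_to: tuple = (-70.0, -62.0, -57.0, -54.0)
    dorsiflexion_rise: float = 8.0
    dorsiflexion_frac: float = 0.35  # fraction of contact at peak dorsiflexion
    foot_swing_angle: float = 5.0
    shank_block_angle: tuple = (20.0, 32.0)  # (front-block leg, rear leg) at start
    target_sd: float = 2.5

    noise_sd: float = 0.25  # deg, band-limited below 30 Hz
    pad: float = 0.3  # seconds of recording before TO_0 and after the last TO
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_steps < 1:
            raise ConfigError("n_participants and n_steps must be >= 1")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.flight_mean <= 0 or self.contact_mean <= 0:
            raise ConfigError("step durations must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.asymmetry_ratio <= 0:
            raise ConfigError("asymmetry_ratio must be > 0")
        if not 0 <= self.boundary_slope < 1:
            raise ConfigError("boundary_slope must lie in [0, 1)")


def _per_step(values, n: int) -> np.ndarray:
    v = list(values)
    if len(v) < n:
        v = v + [v[-1]] * (n - len(v))
    return np.asarray(v[:n], dtype=float)


def _ease(u: np.ndarray, beta: float) -> np.ndarray:
    """Monotone easing on [0, 1] with endpoint slope ``beta`` (relative)."""
    return u - (1.0 - beta) * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _piecewise_ease(times: np.ndarray, knot_t, knot_v, beta: float) -> np.ndarray:
    """Evaluate an eased piecewise-monotone curve through (knot_t, knot_v).

    Holds the first/last knot value outside the knot range.
    """
    knot_t = np.asarray(knot_t, dtype=float)
    knot_v = np.asarray(knot_v, dtype=float)
    out = np.empty_like(times)
    out[times <= knot_t[0]] = knot_v[0]
    out[times >= knot_t[-1]] = knot_v[-1]
    for t0, t1, v0, v1 in zip(knot_t[:-1], knot_t[1:], knot_v[:-1], knot_v[1:]):
        m = (times >= t0) & (times < t1)
        if not np.any(m):
            continue
        u = (times[m] - t0) / (t1 - t0)
        out[m] = v0 + (v1 - v0) * _ease(u, beta)
    return out


def _band_limited_noise(rng, n: int, fs: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    cutoff = min(30.0, 0.45 * fs)
    b, a = butter(4, cutoff / (fs / 2.0))
    smooth = filtfilt(b, a, white)
    s = smooth.std()
    return smooth / s * sd if s > 0 else smooth


def generate_events(cfg: SimConfig, rng) -> list[GaitEvent]:
    """Alternating TO/TD event list starting at the block-clearance toe-off.

    Event times are snapped onto the sample grid so that waveform reversal
    corners coincide with samples (keeps per-step increments analytically
    clean for ground-truth checks).
    """

    def snap(t: float) -> float:
        return round(t * cfg.sample_rate) / cfg.sample_rate

    events = [GaitEvent("toe_off", snap(cfg.pad), cfg.front_block_side, "TO_0")]
    t = events[0].time
    side = cfg.front_block_side
    for k in range(1, cfg.n_steps + 1):
        side = other_side(side)
        fl = max(0.10, cfg.flight_mean + rng.normal(0.0, cfg.step_time_jitter_sd))
        ct = max(0.08, cfg.contact_mean + rng.normal(0.0, cfg.step_time_jitter_sd))
        td, to = snap(t + fl), snap(t + fl + ct)
        events.append(GaitEvent("touchdown", td, side, f"TD_{k}"))
        events.append(GaitEvent("toe_off", to, side, f"TO_{k}"))
        t = to
    return events


def generate_trial(cfg: SimConfig, participant_index: int = 0) -> Trial:
    """One participant's event-annotated seven-segment trial.

    Deterministic given ``(cfg.rng_seed, participant_index)``.
    """
    rng = np.random.default_rng([cfg.rng_seed, participant_index])

    # per-participant parameter jitter
    ratio = max(0.2, cfg.asymmetry_ratio + rng.normal(0.0, cfg.asymmetry_ratio_sd))
    amp = max(5.0, cfg.thigh_amplitude + rng.normal(0.0, cfg.thigh_amplitude_sd))
    trunk0 = cfg.trunk_start + rng.normal(0.0, cfg.trunk_start_sd)
    trunk_inc = cfg.trunk_step_increment + rng.normal(0.0, cfg.trunk_step_increment_sd)
    cfg_p = SimConfig(**{**asdict(cfg), "flight_mean": max(
        0.10, cfg.flight_mean + rng.normal(0.0, cfg.flight_sd)),
        "contact_mean": max(0.08, cfg.contact_mean + rng.normal(0.0, cfg.contact_sd)),
        "noise_sd": cfg.noise_sd})
    shank_td = _per_step(cfg.shank_td, cfg.n_steps) + rng.normal(0, cfg.target_sd, cfg.n_steps)
    shank_to = _per_step(cfg.shank_to, cfg.n_steps) + rng.normal(0, cfg.target_sd, cfg.n_steps)
    foot_td = _per_step(cfg.foot_td, cfg.n_steps) + rng.normal(0, cfg.target_sd, cfg.n_steps)
    foot_to = _per_step(cfg.foot_to, cfg.n_steps) + rng.normal(0, cfg.target_sd, cfg.n_steps)

    events = generate_events(cfg_p, rng)
    t_end = events[-1].time + cfg.pad
    n_samples = int(np.ceil(t_end * cfg.sample_rate)) + 1
    times = np.arange(n_samples) / cfg.sample_rate
    if events[-1].time > times[-1]:
        raise ConfigError("infeasible timing: events exceed the sampled span")

    toe_offs = [e for e in events if e.kind == "toe_off"]
    touchdowns = [e for e in events if e.kind == "touchdown"]
    beta = cfg.boundary_slope

    # --- thighs: reversal knots at toe-offs, exact slope-ratio asymmetry ----
    thigh_knots: dict[str, tuple[list, list]] = {}
    value = {
        other_side(cfg.front_block_side): cfg.thigh_start_leading,
        cfg.front_block_side: cfg.thigh_start_trailing,
    }
    kt: dict[str, list] = {s: [toe_offs[0].time] for s in value}
    kv: dict[str, list] = {s: [value[s]] for s in value}
    for k in range(1, cfg.n_steps + 1):
        leading, trailing = assign_limb_roles(k, cfg.front_block_side)
        value[trailing] += ratio * amp
        value[leading] -= amp
        for s in (leading, trailing):
            kt[s].append(toe_offs[k].time)
            kv[s].append(value[s])
    for s in kt:
        thigh_knots[s] = (kt[s], kv[s])

    # --- trunk: clockwise in flight, anticlockwise in stance, net rise ------
    trunk_t = [toe_offs[0].time]
    trunk_v = [trunk0]
    base = trunk0
    for k in range(1, cfg.n_steps + 1):
        base += trunk_inc
        trunk_t += [touchdowns[k - 1].time, toe_offs[k].time]
        trunk_v += [trunk_v[-1] - cfg.trunk_flight_drop, base]

    # --- shank / foot per leg: stance targets + dorsiflexion dip ------------
    shank_knots = {s: ([], []) for s in ("left", "right")}
    foot_knots = {s: ([], []) for s in ("left", "right")}
    front = cfg.front_block_side
    shank_knots[front][0].append(toe_offs[0].time)
    shank_knots[front][1].append(cfg.shank_block_angle[0])
    shank_knots[other_side(front)][0].append(toe_offs[0].time)
    shank_knots[other_side(front)][1].append(cfg.shank_block_angle[1])
    foot_knots[front][0].append(toe_offs[0].time)
    foot_knots[front][1].append(foot_to[0] * 0.6)
    foot_knots[other_side(front)][0].append(toe_offs[0].time)
    foot_knots[other_side(front)][1].append(cfg.foot_swing_angle)
    for k in range(1, cfg.n_steps + 1):
        leading, _ = assign_limb_roles(k, cfg.front_block_side)
        td, to = touchdowns[k - 1].time, toe_offs[k].time
        i = k - 1
        st, sv = shank_knots[leading]
        st += [td, to]
        sv += [shank_td[i], shank_to[i]]
        ft, fv = foot_knots[leading]
        dip_t = td + cfg.dorsiflexion_frac * (to - td)
        # mid-swing recovery knot for in-phase flight motion
        prev_t = ft[-1]
        ft += [prev_t + 0.5 * (td - prev_t), td, dip_t, to]
        fv += [cfg.foot_swing_angle, foot_td[i], foot_td[i] + cfg.dorsiflexion_rise, foot_to[i]]

    series: dict[str, AngleSeries] = {}

    def _mk(seg: str, values: np.ndarray) -> None:
        if cfg.noise_sd > 0:
            values = values + _band_limited_noise(rng, n_samples, cfg.sample_rate, cfg.noise_sd)
        series[seg] = AngleSeries(seg, cfg.sample_rate, values, start_time=0.0)

    for s in ("left", "right"):
        _mk(segment_id("thigh", s), _piecewise_ease(times, *thigh_knots[s], beta))
        _mk(segment_id("shank", s), _piecewise_ease(times, *shank_knots[s], beta))
        _mk(segment_id("foot", s), _piecewise_ease(times, *foot_knots[s], beta))
    _mk("trunk", _piecewise_ease(times, trunk_t, trunk_v, beta))

    return Trial(
        participant_id=f"P{participant_index + 1:02d}",
        series=series,
        events=events,
        front_block_side=cfg.front_block_side,
    )


def generate_cohort(cfg: SimConfig) -> list[Trial]:
    """All participants' trials, reproducible from the config seed."""
    return [generate_trial(cfg, i) for i in range(cfg.n_participants)]


# ---------------------------------------------------------------------------
# generator-implied ground truth (thigh-thigh coupling)
# ---------------------------------------------------------------------------

def expected_thigh_bin(ratio: float, rule: str = "distal") -> int:
    """Bin implied by the generator's thigh slopes, from increment signs only.

    Within every step the trailing (proximal) thigh increment is
    ``+ratio x c`` and the leading (distal) one ``-c`` with ``c > 0``:
    anti-phase with the proximal segment rotating (+).  The dominant segment
    follows from comparing ``ratio`` to 1 (ties broken by ``rule``).
    """
    if ratio > 1:
        return 7  # anti-phase proximal (+)
    if ratio < 1:
        return 6  # anti-phase distal (-)
    return 6 if rule == "distal" else 7


def expected_thigh_dominancy(ratio: float) -> float:
    """Dominancy magnitude (%) implied by the generator's slope ratio."""
    distal_share = np.degrees(np.arctan(1.0 / ratio)) * 100.0 / 90.0
    return float(max(distal_share, 100.0 - distal_share))


# ---------------------------------------------------------------------------
# cohort output
# ---------------------------------------------------------------------------

def write_cohort(trials: list[Trial], cfg: SimConfig, out_dir: str | Path) -> Path:
    """Write per-participant angle/event CSVs plus a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for trial in trials:
        angles = out_dir / f"{trial.participant_id}_angles.csv"
        events = out_dir / f"{trial.participant_id}_events.csv"
        write_trial(trial, angles, events)
        records.append(
            {
                "participant": trial.participant_id,
                "angles": angles.name,
                "events": events.name,
            }
        )
    manifest = {"config": asdict(cfg), "participants": records}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir / "manifest.json"
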