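"""Modified vector coding: coupling angles, 8-bin classification, dominancy.

The coupling angle gamma is the direction, in [0, 360) degrees measured
anticlockwise from the right horizontal, of the vector between adjacent
points on the proximal-vs-distal angle-angle plot.  The circle is split
into four phase quadrants (in-phase / anti-phase x rotation direction),
each halved into a proximal- and a distal-dominant 45-degree bin.

Dominancy converts gamma to gradians: a quadrant spans 100 gradians, so the
position within the quadrant maps linearly to a 0-100% distal share; the
reported magnitude is the dominant share, constrained to [50, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import AnalysisConfig, segment_id
from .preprocessing import NormalizedStep

BIN_WIDTH_DEG = 45.0
N_BINS = 8

#: static bin table, index 0..7 anticlockwise from gamma = 0.
#: phase: relationship of the two rotations; dominant: which segment rotates
#: more; direction: rotation sign of the *dominant* segment in that bin.
BIN_TABLE = (
    {"index": 0, "phase": "in-phase", "dominant": "proximal", "direction": "+", "color": "#08306b"},
    {"index": 1, "phase": "in-phase", "dominant": "distal", "direction": "+", "color": "#6baed6"},
    {"index": 2, "phase": "anti-phase", "dominant": "distal", "direction": "+", "color": "#74c476"},
    {"index": 3, "phase": "anti-phase", "dominant": "proximal", "direction": "-", "color": "#00441b"},
    {"index": 4, "phase": "in-phase", "dominant": "proximal", "direction": "-", "color": "#3f007d"},
    {"index": 5, "phase": "in-phase", "dominant": "distal", "direction": "-", "color": "#bcbddc"},
    {"index": 6, "phase": "anti-phase", "dominant": "distal", "direction": "-", "color": "#fb6a4a"},
    {"index": 7, "phase": "anti-phase", "dominant": "proximal", "direction": "+", "color": "#67000d"},
)

PROXIMAL_DOMINANT_BINS = frozenset(b["index"] for b in BIN_TABLE if b["dominant"] == "proximal")
DISTAL_DOMINANT_BINS = frozenset(b["index"] for b in BIN_TABLE if b["dominant"] == "distal")


@dataclass(frozen=True)
class CouplingDefinition:
    """Which segment plays the proximal and which the distal role.

    ``proximal_name``/``distal_name`` are the words used in bin display
    labels (e.g. "trailing"/"leading" for the thigh-thigh coupling).
    """

    name: str
    proximal_name: str
    distal_name: str


COUPLINGS = {
    "thigh_thigh": CouplingDefinition("thigh_thigh", "trailing", "leading"),
    "trunk_shank": CouplingDefinition("trunk_shank", "trunk", "shank"),
    "shank_foot": CouplingDefinition("shank_foot", "shank", "foot"),
}


def bin_label(coupling: CouplingDefinition, index: int) -> str:
    """Display label of a bin, named by the dominant segment and its rotation sign."""
    b = BIN_TABLE[index]
    seg = coupling.proximal_name if b["dominant"] == "proximal" else coupling.distal_name
    return f"{b['phase']} {seg} ({b['direction']})"


def bin_color(index: int) -> str:
    return BIN_TABLE[index]["color"]


def coupling_angle(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Coupling angles (deg, in [0, 360)) between adjacent angle-angle points.

    Output has length ``n - 1``; intervals where both increments are exactly
    zero are undefined and returned as NaN.
    """
    proximal = np.asarray(proximal, dtype=float)
    distal = np.asarray(distal, dtype=float)
    if proximal.shape != distal.shape:
        raise ValidationError("proximal and distal sequences must have equal length")
    if proximal.ndim != 1 or proximal.size < 2:
        raise ValidationError("need at least two points per sequence")
    dp = np.diff(proximal)
    dd = np.diff(distal)
    gamma = np.degrees(np.arctan2(dd, dp)) % 360.0
    gamma[gamma >= 360.0] = 0.0  # float wrap of tiny negative directions
    gamma[(dp == 0.0) & (dd == 0.0)] = np.nan
    return gamma


def classify_bin(gamma, rule: str = "distal"):
    """Map coupling angle(s) to bin index 0-7.

    Bins are half-open ``[lower, upper)`` 45-degree sectors.  ``rule``
    decides exact quadrant diagonals (50% dominancy ties): ``"distal"``
    (default) assigns them to the distal-dominant bin, ``"proximal"`` to
    the proximal-dominant one.  Undefined (NaN) angles map to -1.
    """
    g = np.asarray(gamma, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    out = np.full(g.shape, -1, dtype=int)
    ok = np.isfinite(g)
    gv = g[ok] % 360.0
    idx = np.floor(gv / BIN_WIDTH_DEG).astype(int) % N_BINS
    # exact quadrant diagonals are 50% dominancy ties between the two
    # adjacent bins; assign them per the configured rule
    wanted = DISTAL_DOMINANT_BINS if rule == "distal" else PROXIMAL_DOMINANT_BINS
    on_diagonal = (gv % 90.0) == BIN_WIDTH_DEG
    snap = on_diagonal & ~np.isin(idx, list(wanted))
    idx[snap] = (idx[snap] - 1) % N_BINS
    out[ok] = idx
    return int(out[0]) if scalar else out


def dominancy(gamma, rule: str = "distal"):
    """Dominant segment and dominancy magnitude (%) for coupling angle(s).

    Folds gamma into one quadrant, converts it to gradians to obtain the
    distal share ``d`` in [0, 100], and reports ``max(d, 100 - d)`` with the
    corresponding segment.  Exactly 100 on the axes (one segment still),
    exactly 50 on the diagonals (equal rotation; tie broken by ``rule``).
    """
    g = np.asarray(gamma, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g).astype(float) % 360.0
    theta = g % 180.0
    theta = np.where(theta > 90.0, 180.0 - theta, theta)
    d = theta * 100.0 / 90.0  # distal share, gradian conversion
    magnitude = np.maximum(d, 100.0 - d)
    dominant = np.where(d > 50.0, "distal", "proximal").astype(object)
    tie = d == 50.0
    dominant[tie] = "distal" if rule == "distal" else "proximal"
    undef = ~np.isfinite(np.atleast_1d(np.asarray(gamma, dtype=float)))
    dominant[undef] = None
    magnitude = np.where(undef, np.nan, magnitude)
    if scalar:
        return dominant[0], float(magnitude[0])
    return dominant, magnitude


@dataclass
class CoordinationProfile:
    """Per-interval coordination description of one step and coupling."""

    participant_id: str
    step_index: int
    coupling: CouplingDefinition
    gamma: np.ndarray
    defined: np.ndarray
    bin_index: np.ndarray
    imputed: np.ndarray
    dominant: np.ndarray
    dominancy_pct: np.ndarray
    touchdown_pct: float = float("nan")

    @property
    def n_intervals(self) -> int:
        return self.gamma.size

    def bin_labels(self) -> list[str]:
        return [
            bin_label(self.coupling, int(i)) if i >= 0 else ""
            for i in self.bin_index
        ]

    def assigned(self) -> np.ndarray:
        """Mask of intervals carrying a bin (defined or inherited)."""
        return self.bin_index >= 0


def _coupling_series(step: NormalizedStep, coupling: CouplingDefinition):
    """(proximal, distal) angle sequences for a coupling within one step.

    Intra-limb couplings use the limb in stance during the step, i.e. the
    leading limb, which touches down within the step.
    """
    name = coupling.name
    if name == "thigh_thigh":
        return (
            step.segment_for_role("thigh", "trailing"),
            step.segment_for_role("thigh", "leading"),
        )
    if name == "trunk_shank":
        return step.angles["trunk"], step.segment_for_role("shank", "leading")
    if name == "shank_foot":
        return (
            step.segment_for_role("shank", "leading"),
            step.segment_for_role("foot", "leading"),
        )
    raise ValidationError(f"unknown coupling {name!r}")


def build_profile(
    step: NormalizedStep,
    coupling: CouplingDefinition | str,
    config: AnalysisConfig | None = None,
) -> CoordinationProfile:
    """Compose coupling angle, bin classification and dominancy for one step.

    Undefined intervals (both segments motionless) inherit the previous
    defined bin when one exists; otherwise they stay unassigned (-1) and are
    excluded from bin frequencies.  Both cases are flagged via ``defined``
    and ``imputed``.
    """
    if isinstance(coupling, str):
        coupling = COUPLINGS[coupling]
    config = config or AnalysisConfig()
    rule = config.bin_boundary_rule
    prox, dist = _coupling_series(step, coupling)
    gamma = coupling_angle(prox, dist)
    defined = np.isfinite(gamma)
    bins = classify_bin(gamma, rule=rule)
    imputed = np.zeros(gamma.size, dtype=bool)
    last = -1
    for i in range(gamma.size):
        if bins[i] >= 0:
            last = bins[i]
        elif last >= 0:
            bins[i] = last
            imputed[i] = True
    dominant, magnitude = dominancy(gamma, rule=rule)
    return CoordinationProfile(
        participant_id=step.participant_id,
        step_index=step.step_index,
        coupling=coupling,
        gamma=gamma,
        defined=defined,
        bin_index=bins,
        imputed=imputed,
        dominant=dominant,
        dominancy_pct=magnitude,
        touchdown_pct=step.touchdown_pct,
    )


def classify_from_increments(dp: float, dd: float, rule: str = "distal") -> int:
    """Independent bin classifier built from increment signs and magnitudes.

    Used as a cross-check oracle for :func:`classify_bin`; does not go
    through the coupling angle.  Returns -1 when both increments are zero.
    """
    if dp == 0.0 and dd == 0.0:
        return -1
    if abs(dd) > abs(dp):
        dominant = "distal"
    elif abs(dd) < abs(dp):
        dominant = "proximal"
    else:
        dominant = "distal" if rule == "distal" else "proximal"
    same_sign = dp * dd > 0
    if dp == 0.0 or dd == 0.0:
        # pure single-segment motion sits on an axis: the moving segment is
        # dominant; the half-open bin convention puts the axis in the bin
        # anticlockwise of it.
        if dd > 0:
            return 2
        if dd < 0:
            return 6
        return 4 if dp < 0 else 0
    phase = "in-phase" if same_sign else "anti-phase"
    sign = "+" if (dd > 0 if dominant == "distal" else dp > 0) else "-"
    for b in BIN_TABLE:
        if b["phase"] == phase and b["dominant"] == dominant and b["direction"] == sign:
            return b["index"]
    raise AssertionError("unreachable")
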