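"""Group-level coordination description.

Circular mean/SD profiles across participants, per-step bin frequencies and
the step-to-step coupling-angle difference score (a bin-ring distance summed
over the step and expressed as a percentage of its maximum; 0 = identical
coordination, 100 = diametrically opposite everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AnalysisConfig
from .vector_coding import N_BINS, CoordinationProfile, bin_label, classify_bin, dominancy

MAX_BIN_DISTANCE = N_BINS // 2  # diametrically opposite on the 8-bin ring


def circular_mean(angles_deg) -> tuple[float, float]:
    """Circular mean direction (deg in [0, 360)) and mean resultant length r.

    NaN entries are ignored.  With no finite entry, or r numerically zero,
    the mean is undefined (NaN).
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan"), float("nan")
    rad = np.radians(a)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return float("nan"), 0.0
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # float wrap of tiny negative directions
        mean = 0.0
    return mean, r


def circular_sd_from_r(r: float, formula: str = "angular_deviation") -> float:
    """Circular standard deviation (deg) from the mean resultant length.

    ``angular_deviation`` uses sqrt(2(1 - r)); ``ln_r`` uses sqrt(-2 ln r).
    """
    if not np.isfinite(r):
        return float("nan")
    r = min(max(r, 0.0), 1.0)
    if formula == "angular_deviation":
        sd_rad = np.sqrt(2.0 * (1.0 - r))
    elif formula == "ln_r":
        sd_rad = np.sqrt(-2.0 * np.log(r)) if r > 0 else float("inf")
    else:
        raise ValidationError(f"unknown circular SD formula {formula!r}")
    return float(np.degrees(sd_rad))


def circular_sd_profile(
    gamma_matrix: np.ndarray, formula: str = "angular_deviation"
) -> np.ndarray:
    """Per-interval circular SD (deg) across participants.

    ``gamma_matrix`` is participants x intervals; intervals with fewer than
    two defined values yield NaN.
    """
    g = np.asarray(gamma_matrix, dtype=float)
    if g.ndim != 2:
        raise ValidationError("gamma_matrix must be participants x intervals")
    out = np.full(g.shape[1], np.nan)
    for i in range(g.shape[1]):
        col = g[:, i]
        col = col[np.isfinite(col)]
        if col.size < 2:
            continue
        _, r = circular_mean(col)
        out[i] = circular_sd_from_r(r, formula)
    return out


@dataclass
class GroupProfile:
    """Pointwise circular summary of one coupling/step across participants."""

    coupling_name: str
    step_index: int
    mean_deg: np.ndarray
    r: np.ndarray
    sd_deg: np.ndarray
    mean_bin: np.ndarray
    mean_dominancy: np.ndarray
    touchdown_pct: float = float("nan")
    n_participants: int = 0

    @property
    def n_intervals(self) -> int:
        return self.mean_deg.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coupling": self.coupling_name,
                "step": self.step_index,
                "interval_index": np.arange(self.n_intervals),
                "mean_deg": self.mean_deg,
                "r": self.r,
                "sd_deg": self.sd_deg,
                "mean_bin": self.mean_bin,
                "mean_dominancy": self.mean_dominancy,
                "touchdown_pct": self.touchdown_pct,
            }
        )


def group_profile(
    profiles: list[CoordinationProfile], config: AnalysisConfig | None = None
) -> GroupProfile:
    """Pointwise circular mean/SD across participants' profiles of one step."""
    config = config or AnalysisConfig()
    if not profiles:
        raise ValidationError("need at least one profile")
    names = {p.coupling.name for p in profiles}
    steps = {p.step_index for p in profiles}
    if len(names) > 1 or len(steps) > 1:
        raise ValidationError("group profile mixes couplings or steps")
    n = profiles[0].n_intervals
    if any(p.n_intervals != n for p in profiles):
        raise ValidationError("profiles have heterogeneous lengths")
    g = np.vstack([p.gamma for p in profiles])
    mean = np.full(n, np.nan)
    r = np.full(n, np.nan)
    for i in range(n):
        mean[i], r[i] = circular_mean(g[:, i])
    sd = circular_sd_profile(g, config.circular_sd_formula)
    mean_bin = classify_bin(mean, rule=config.bin_boundary_rule)
    _, mean_dom = dominancy(mean, rule=config.bin_boundary_rule)
    td = float(np.mean([p.touchdown_pct for p in profiles]))
    return GroupProfile(
        coupling_name=profiles[0].coupling.name,
        step_index=profiles[0].step_index,
        mean_deg=mean,
        r=r,
        sd_deg=sd,
        mean_bin=mean_bin,
        mean_dominancy=mean_dom,
        touchdown_pct=td,
        n_participants=len(profiles),
    )


def bin_frequencies(profile: CoordinationProfile | np.ndarray) -> np.ndarray:
    """Percentage of assigned intervals falling in each of the 8 bins.

    Accepts a profile or a raw bin-index array (-1 = unassigned, excluded).
    Sums to 100 exactly (before any display rounding).
    """
    bins = profile.bin_index if isinstance(profile, CoordinationProfile) else np.asarray(profile)
    bins = bins[bins >= 0]
    if bins.size == 0:
        raise ValidationError("no assigned intervals; bin frequencies undefined")
    counts = np.bincount(bins, minlength=N_BINS).astype(float)
    return counts / bins.size * 100.0


@dataclass(frozen=True)
class CADiffScore:
    """Similarity score between two steps' bin sequences (0 = identical)."""

    step_pair: tuple[int, int]
    score: float
    n_intervals: int


def ca_diff(bins_a: np.ndarray, bins_b: np.ndarray, step_pair=(0, 0)) -> CADiffScore:
    """Coupling-angle difference score between two bin sequences.

    Per interval the distance is the circular distance of the bin indices on
    the 8-bin ring (0..4); the score is the summed distance as a percentage
    of the maximum (4 per interval).  Intervals unassigned (-1) in either
    sequence are excluded from numerator and denominator.
    """
    a = np.asarray(bins_a, dtype=int)
    b = np.asarray(bins_b, dtype=int)
    if a.shape != b.shape:
        raise ValidationError("bin sequences must have equal length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise ValidationError("no jointly assigned intervals")
    d = np.abs(a - b)
    d = np.minimum(d, N_BINS - d)
    score = float(d.sum() / (MAX_BIN_DISTANCE * a.size) * 100.0)
    return CADiffScore(step_pair=tuple(step_pair), score=score, n_intervals=int(a.size))


def bin_ring_distance(a: int, b: int) -> int:
    """Circular distance between two bin indices on the 8-bin ring (0..4)."""
    d = abs(int(a) - int(b))
    return min(d, N_BINS - d)


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

def bin_frequency_table(profiles: list[CoordinationProfile]) -> pd.DataFrame:
    """Long-format participant x step x bin frequency table."""
    rows = []
    for p in profiles:
        freqs = bin_frequencies(p)
        for b in range(N_BINS):
            rows.append(
                {
                    "participant": p.participant_id,
                    "coupling": p.coupling.name,
                    "step": p.step_index,
                    "bin_index": b,
                    "bin_label": bin_label(p.coupling, b),
                    "freq_pct": freqs[b],
                }
            )
    return pd.DataFrame(rows)


def ca_diff_table(profiles: list[CoordinationProfile]) -> pd.DataFrame:
    """CA_Diff between consecutive steps, per participant and coupling."""
    rows = []
    keyed: dict[tuple[str, str], list[CoordinationProfile]] = {}
    for p in profiles:
        keyed.setdefault((p.participant_id, p.coupling.name), []).append(p)
    for (pid, cname), plist in keyed.items():
        plist = sorted(plist, key=lambda p: p.step_index)
        for p1, p2 in zip(plist, plist[1:]):
            if p2.step_index != p1.step_index + 1:
                continue
            s = ca_diff(p1.bin_index, p2.bin_index, (p1.step_index, p2.step_index))
            rows.append(
                {
                    "participant": pid,
                    "coupling": cname,
                    "step_pair": f"S{p1.step_index}-S{p2.step_index}",
                    "score_pct": s.score,
                }
            )
    return pd.DataFrame(rows)


def summarize_ca_diff(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of CA_Diff per coupling and step pair."""
    return (
        table.groupby(["coupling", "step_pair"])["score_pct"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
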