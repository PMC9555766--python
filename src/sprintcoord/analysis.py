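"""End-to-end orchestration: trials -> profiles, tables and group summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .coordstats import (
    GroupProfile,
    bin_frequency_table,
    ca_diff_table,
    group_profile,
    summarize_ca_diff,
)
from .io import AnalysisConfig, Trial, read_trial
from .preprocessing import NormalizedStep, lowpass_trial, normalize_trial, segment_steps
from .inference import extract_event_angles
from .vector_coding import COUPLINGS, CoordinationProfile, build_profile

log = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """All per-interval and per-step products of a cohort analysis."""

    config: AnalysisConfig
    couplings: list[str]
    steps: list[NormalizedStep] = field(default_factory=list)
    profiles: list[CoordinationProfile] = field(default_factory=list)
    step_characteristics: pd.DataFrame = field(default_factory=pd.DataFrame)
    discrete_kinematics: pd.DataFrame = field(default_factory=pd.DataFrame)
    bin_freq: pd.DataFrame = field(default_factory=pd.DataFrame)
    ca_diff: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_profiles: dict = field(default_factory=dict)

    def profiles_for(self, coupling: str) -> list[CoordinationProfile]:
        return [p for p in self.profiles if p.coupling.name == coupling]


def analyze_cohort(
    trials: list[Trial],
    config: AnalysisConfig | None = None,
    couplings: list[str] | None = None,
    n_steps: int | None = None,
) -> CohortAnalysis:
    """Run the full coordination pipeline over a cohort of trials."""
    config = config or AnalysisConfig()
    couplings = couplings or list(COUPLINGS)
    result = CohortAnalysis(config=config, couplings=couplings)

    step_rows = []
    discrete_frames = []
    for trial in trials:
        log.info("analyzing %s", trial.participant_id)
        filtered = lowpass_trial(trial, config)
        windows = segment_steps(filtered, n_steps)
        steps = normalize_trial(trial, config, n_steps)
        result.steps.extend(steps)
        for w in windows:
            step_rows.append(
                {
                    "participant": trial.participant_id,
                    "step": w.step_index,
                    "flight_time_s": w.flight_time,
                    "contact_time_s": w.contact_time,
                    "touchdown_pct": w.touchdown_pct,
                }
            )
        discrete_frames.append(extract_event_angles(filtered, windows))
        for step in steps:
            for cname in couplings:
                result.profiles.append(build_profile(step, cname, config))

    result.step_characteristics = pd.DataFrame(step_rows)
    result.discrete_kinematics = pd.concat(discrete_frames, ignore_index=True)
    result.bin_freq = bin_frequency_table(result.profiles)
    result.ca_diff = ca_diff_table(result.profiles)

    for cname in couplings:
        by_step: dict[int, GroupProfile] = {}
        plist = result.profiles_for(cname)
        for step_idx in sorted({p.step_index for p in plist}):
            group = [p for p in plist if p.step_index == step_idx]
            if len(group) >= 1:
                by_step[step_idx] = group_profile(group, config)
        result.group_profiles[cname] = by_step
    return result


def load_cohort(in_dir: str | Path) -> list[Trial]:
    """Load all ``*_angles.csv`` / ``*_events.csv`` pairs from a directory."""
    in_dir = Path(in_dir)
    trials = []
    for angles in sorted(in_dir.glob("*_angles.csv")):
        events = angles.with_name(angles.name.replace("_angles.csv", "_events.csv"))
        trials.append(read_trial(angles, events))
    if not trials:
        raise FileNotFoundError(f"no *_angles.csv files found in {in_dir}")
    return trials


def write_analysis(result: CohortAnalysis, out_dir: str | Path) -> None:
    """Write all analysis tables as CSV files under ``out_dir``."""
    from .io import write_profiles

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.step_characteristics.to_csv(out_dir / "step_characteristics.csv", index=False)
    result.discrete_kinematics.to_csv(out_dir / "discrete_kinematics.csv", index=False)
    result.bin_freq.to_csv(out_dir / "bin_frequencies.csv", index=False)
    result.ca_diff.to_csv(out_dir / "ca_diff.csv", index=False)
    if not result.ca_diff.empty:
        summarize_ca_diff(result.ca_diff).to_csv(out_dir / "ca_diff_summary.csv", index=False)
    for cname in result.couplings:
        write_profiles(result.profiles_for(cname), out_dir / f"profiles_{cname}.csv")
        groups = result.group_profiles.get(cname, {})
        if groups:
            pd.concat([g.to_frame() for g in groups.values()], ignore_index=True).to_csv(
                out_dir / f"group_profile_{cname}.csv", index=False
            )
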