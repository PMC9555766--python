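"""Publication-style coordination plots.

Rendered headlessly (Agg) and deterministically: fixed figure sizes, no
timestamps in metadata, so repeated renders of the same data are
byte-identical and suitable for image-hash regression tests.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .coordstats import GroupProfile
from .errors import ValidationError
from .vector_coding import N_BINS, CoordinationProfile, bin_color, bin_label

_SAVEFIG_KW = dict(dpi=100, metadata={"Software": ""})


def _bars(ax, x, height, bins, touchdown_pct):
    colors = [bin_color(int(b)) if b >= 0 else "#dddddd" for b in bins]
    width = x[1] - x[0] if len(x) > 1 else 1.0
    ax.bar(x, height - 50.0, bottom=50.0, width=width, color=colors, align="edge")
    if np.isfinite(touchdown_pct):
        ax.axvspan(touchdown_pct, 100.0, color="0.8", alpha=0.4, zorder=0)
    ax.set_xlim(0, 100)
    ax.set_ylim(50, 100)
    ax.set_xlabel("normalized time (%)")
    ax.set_ylabel("dominancy (%)")


def plot_profile(
    profile: CoordinationProfile | GroupProfile,
    out: str | Path,
    crossover_pct: float | None = None,
) -> Path:
    """Bar-profile plot: height = dominancy, colour = bin, shaded stance.

    Group profiles get a companion panel with the between-individual
    circular SD curve.
    """
    out = Path(out)
    if isinstance(profile, GroupProfile):
        if profile.n_intervals == 0:
            raise ValidationError("empty profile")
        fig, (ax, ax2) = plt.subplots(
            2, 1, figsize=(8, 5), sharex=True, height_ratios=[2, 1]
        )
        x = np.arange(profile.n_intervals, dtype=float)
        dom = np.where(np.isfinite(profile.mean_dominancy), profile.mean_dominancy, 50.0)
        _bars(ax, x, dom, profile.mean_bin, profile.touchdown_pct)
        ax.set_title(
            f"{profile.coupling_name} step {profile.step_index} "
            f"(n={profile.n_participants})"
        )
        ax2.plot(x, profile.sd_deg, color="black")
        ax2.set_ylabel("circular SD (deg)")
        ax2.set_xlabel("normalized time (%)")
    else:
        if profile.n_intervals == 0:
            raise ValidationError("empty profile")
        fig, ax = plt.subplots(figsize=(8, 3.2))
        x = np.arange(profile.n_intervals, dtype=float)
        dom = np.where(np.isfinite(profile.dominancy_pct), profile.dominancy_pct, 50.0)
        _bars(ax, x, dom, profile.bin_index, profile.touchdown_pct)
        ax.set_title(
            f"{profile.participant_id} {profile.coupling.name} step {profile.step_index}"
        )
        if crossover_pct is not None:
            ax.axvline(crossover_pct, color="black", lw=1.5)
    fig.tight_layout()
    fig.savefig(out, **_SAVEFIG_KW)
    plt.close(fig)
    return out


def plot_sd_curves(groups: dict, out: str | Path, coupling_name: str = "") -> Path:
    """Between-individual circular SD per step, overlaid."""
    out = Path(out)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for step_idx, g in sorted(groups.items()):
        ax.plot(np.arange(g.n_intervals), g.sd_deg, label=f"step {step_idx}")
    ax.set_xlabel("normalized time (%)")
    ax.set_ylabel("circular SD (deg)")
    ax.set_title(coupling_name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, **_SAVEFIG_KW)
    plt.close(fig)
    return out


def plot_bin_frequencies(bin_freq, coupling_name: str, out: str | Path) -> Path:
    """Mean bin-frequency matrix (bin x step) as an annotated heat table."""
    out = Path(out)
    sub = bin_freq[bin_freq["coupling"] == coupling_name]
    if sub.empty:
        raise ValidationError(f"no bin frequencies for coupling {coupling_name}")
    mean = sub.groupby(["bin_index", "step"])["freq_pct"].mean().unstack()
    full = mean.reindex(index=range(N_BINS), fill_value=0.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(full.to_numpy(), cmap="Greys", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(full.shape[1]), [f"S{s}" for s in full.columns])
    labels = sub.drop_duplicates("bin_index").set_index("bin_index")["bin_label"]
    ax.set_yticks(range(N_BINS), [labels.get(b, str(b)) for b in range(N_BINS)])
    for (i, j), v in np.ndenumerate(full.to_numpy()):
        ax.text(j, i, f"{v:.0f}", ha="center", va="center",
                color="white" if v > 50 else "black", fontsize=8)
    for b in range(N_BINS):
        ax.plot(-0.62, b, "s", color=bin_color(b), markersize=9, clip_on=False)
    fig.colorbar(im, ax=ax, label="mean frequency (%)")
    ax.set_title(coupling_name)
    fig.tight_layout()
    fig.savefig(out, **_SAVEFIG_KW)
    plt.close(fig)
    return out


def thigh_crossover_pct(step) -> float | None:
    """First normalized-time % where leading and trailing thigh angles meet."""
    lead = step.segment_for_role("thigh", "leading")
    trail = step.segment_for_role("thigh", "trailing")
    diff = lead - trail
    sign_change = np.where(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size == 0:
        return None
    return float(sign_change[0]) / (lead.size - 1) * 100.0
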