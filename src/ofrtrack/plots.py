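"""Scatter-plot exports for session results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import SubjectSummary, TrialRecord  # noqa: E402

_COLORS = {"up": "tab:blue", "down": "tab:orange"}


def plot_fixation_movement(trials: list[TrialRecord], path: str | Path,
                           title: str = "") -> None:
    """Per-trial eye-in-head displacements, fixation vs movement epoch.

    Two panels of (x, y) displacement in degrees, one dot per valid trial,
    colored by stimulus direction — the standard session overview: fixation
    dots should cluster at the origin, movement dots should separate
    vertically by stimulus direction.
    """
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2), sharex=True, sharey=True)
    for ax, attr, label in ((axes[0], "fixation_disp_deg", "fixation epoch"),
                            (axes[1], "movement_disp_deg", "movement epoch")):
        for tr in trials:
            disp = getattr(tr, attr)
            if not tr.valid or disp is None:
                continue
            ax.plot(disp[0], disp[1], "o", ms=4, alpha=0.6,
                    color=_COLORS.get(tr.stimulus_label, "gray"))
        ax.axhline(0, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_title(label)
        ax.set_xlabel("horizontal (deg)")
    axes[0].set_ylabel("vertical (deg)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_subject_means(summaries: list[SubjectSummary],
                       path: str | Path) -> None:
    """Mean +/- SEM movement-epoch displacement per subject and condition."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    for summ in summaries:
        for label, st in summ.condition_stats.items():
            ax.errorbar(st["mean_x"], st["mean_y"],
                        xerr=st["sem_x"], yerr=st["sem_y"],
                        fmt="o", ms=4, color=_COLORS.get(label, "gray"),
                        alpha=0.7)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("horizontal (deg)")
    ax.set_ylabel("vertical (deg)")
    ax.set_title("movement-epoch mean displacement")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
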