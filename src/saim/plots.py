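"""Figures: activation time courses, batch reaction times, neuronal summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import SimulationResult

__all__ = ["plot_timecourse", "plot_rt_batches", "plot_neuronal_response"]


def plot_timecourse(result: SimulationResult, labels, path) -> None:
    """Template-unit rates (and focus content, if recorded) over iterations."""
    has_foa = result.trajectories is not None
    fig, axes = plt.subplots(1, 2 if has_foa else 1, figsize=(9 if has_foa else 5, 3.2))
    axes = np.atleast_1d(axes)
    kn = result.kn_trajectory
    for k, lab in enumerate(labels):
        axes[0].plot(kn[:, k], label=lab)
    if result.rt is not None:
        axes[0].axvline(result.rt, color="grey", ls=":", lw=1)
    axes[0].set(xlabel="iteration", ylabel="template-unit rate",
                title=f"{result.model}: winner={result.winner}, rt={result.rt}")
    axes[0].legend(frameon=False)
    if has_foa:
        x_cn = result.trajectories["x_cn"]
        axes[1].plot(np.abs(x_cn).sum(axis=(1, 2)))
        axes[1].set(xlabel="iteration", ylabel="|focus content| sum", title="FOA")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rt_batches(study: dict, path) -> None:
    """Per-condition reaction-time distributions for a three-condition study."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    names = list(study["batches"])
    data = [study["batches"][n].rts for n in names]
    ax.boxplot(data, tick_labels=names)
    for i, rts in enumerate(data, start=1):
        ax.plot(np.full(len(rts), i) + np.random.default_rng(0).uniform(-0.06, 0.06, len(rts)),
                rts, ".", color="tab:blue", alpha=0.5)
    ax.set(ylabel="reaction time (iterations)",
           title=f"{study['model']}: multiple-object cost ({study['n_runs']} runs)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_neuronal_response(series_by_model: dict[str, dict[str, np.ndarray]], path) -> None:
    """Summed output + input activation per network, one panel per model."""
    fig, axes = plt.subplots(1, len(series_by_model), figsize=(4.5 * len(series_by_model), 3.2),
                             squeeze=False)
    for ax, (model, series) in zip(axes[0], series_by_model.items()):
        for net, s in series.items():
            t = np.linspace(0, 1, len(s))
            ax.plot(t, s, label=net.upper())
        ax.set(xlabel="fraction of run", ylabel="summed activation", title=model)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
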