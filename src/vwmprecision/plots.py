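"""Figures mirroring the study's result displays.

All functions take the pipeline's tabular outputs and save a PNG; they are
thin matplotlib wrappers used by the ``report`` CLI subcommand.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_precision_vs_age",
    "plot_sp_profile",
    "plot_response_histograms",
    "plot_parameter_bars",
]


def plot_precision_vs_age(measures: pd.DataFrame, path) -> None:
    """Group-mean corrected precision for the memory tasks against age."""
    fig, ax = plt.subplots(figsize=(5, 4))
    grouped = measures.groupby("group")
    for col, label, marker in (
        ("precision_vwm1", "one-item", "o"),
        ("precision_vwm3", "three-item", "s"),
    ):
        mean_age = grouped["age"].mean()
        mean_p = grouped[col].mean()
        sem = grouped[col].sem()
        ax.errorbar(mean_age, mean_p, yerr=sem, marker=marker, label=label, capsize=3)
    ax.set_xlabel("mean age of year group (years)")
    ax.set_ylabel("corrected precision (rad$^{-1}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sp_profile(measures: pd.DataFrame, path) -> None:
    """Corrected precision by serial position, one line per year group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cols = ["precision_sp1", "precision_sp2", "precision_sp3"]
    for group, sub in measures.groupby("group"):
        ax.plot([1, 2, 3], sub[cols].mean(), marker="o", label=f"group {group}")
    ax.set_xticks([1, 2, 3])
    ax.set_xlabel("serial position")
    ax.set_ylabel("corrected precision (rad$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_response_histograms(hist: pd.DataFrame, path) -> None:
    """Response frequencies relative to target and non-target orientations."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=False)
    centres = (hist["bin_left"] + hist["bin_right"]) / 2.0
    width = (hist["bin_right"] - hist["bin_left"]).iloc[0]
    for ax, col, title in zip(axes, ("target", "nontarget"), ("relative to target", "relative to non-targets")):
        ax.bar(centres, hist[col], width=0.9 * width)
        ax.set_xlabel("error (rad)")
        ax.set_title(title, fontsize=10)
    axes[0].set_ylabel("response count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_parameter_bars(measures: pd.DataFrame, path) -> None:
    """Group-mean mixture parameters (kappa on its own axis)."""
    fig, (ax_k, ax_p) = plt.subplots(1, 2, figsize=(8, 3.5))
    grouped = measures.groupby("group")
    groups = sorted(measures["group"].unique())
    ax_k.bar([str(g) for g in groups], grouped["kappa"].mean(), yerr=grouped["kappa"].sem())
    ax_k.set_xlabel("year group")
    ax_k.set_ylabel(r"$\kappa$")
    x = np.arange(len(groups))
    width = 0.25
    for i, (col, label) in enumerate(
        (("p_target", "p(T)"), ("p_nontarget", "p(NT)"), ("p_uniform", "p(U)"))
    ):
        ax_p.bar(x + (i - 1) * width, grouped[col].mean(), width, label=label)
    ax_p.set_xticks(x, [str(g) for g in groups])
    ax_p.set_xlabel("year group")
    ax_p.set_ylabel("probability")
    ax_p.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
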