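"""Optional matplotlib renderings of sweep and degeneracy outputs.

CSV tables are the contract; these helpers exist for quick visual
inspection and mirror the usual presentation: functional sensitivity
against CD8 density on linear axes, degeneracy curves with a logarithmic
probability axis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_sweep", "plot_degeneracy", "plot_band"]


def plot_sweep(df: pd.DataFrame, path: str | Path, var: str = "x_T") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df[var], df["w"], lw=1.5)
    ax.set_xlabel(var)
    ax.set_ylabel("scaled functional sensitivity w")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_degeneracy(df: pd.DataFrame, path: str | Path,
                    group: str | None = None) -> None:
    """Plot P(w > omega) curves; one line per value of ``group`` if given."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if group is None:
        ax.plot(df["omega"], df["prob"], lw=1.5)
    else:
        for key, sub in df.groupby(group, sort=False):
            ax.plot(sub["omega"], sub["prob"], lw=1.5, label=str(key))
        ax.legend(fontsize=8)
    ax.set_yscale("log")
    ax.set_xlabel("threshold omega")
    ax.set_ylabel("P(w > omega)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_band(df: pd.DataFrame, path: str | Path,
              band: tuple[float, float] = (1e-8, 1e-5)) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["x_T"], df["prob"], lw=1.5)
    for level in band:
        ax.axhline(level, ls="--", color="grey", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("scaled total CD8 density x_T")
    ax.set_ylabel("P(w > omega_crit)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
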