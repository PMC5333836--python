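"""Optional figure emission (log-log distributions, per-order bar charts)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import DistributionSet  # noqa: E402
from .ordering import OrderStatistics  # noqa: E402

__all__ = ["plot_distributions", "plot_order_statistics"]


def plot_distributions(dist: DistributionSet, path: str | Path) -> Path:
    """Log-log absolute and relative diameter/length distributions."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, table, name, width in ((axes[0], dist.diameter, "diameter", dist.dD),
                                   (axes[1], dist.length, "length", dist.dl)):
        centers = table["bin_left"] + width / 2.0
        ax.loglog(centers, table["N"], "o-", label="N")
        ax.loglog(centers, table["P"], "s--", label="P")
        ax.set_xlabel(f"segment {name} (um)")
        ax.set_ylabel("frequency")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_order_statistics(stats: OrderStatistics, path: str | Path) -> Path:
    """Per-order diameters, lengths, counts and resistance (if present)."""
    table = stats.table
    cols = [("diameter_mean", "diameter_sd", "diameter (um)"),
            ("length_mean", None, "length (um)"),
            ("count", None, "segments")]
    if "resistance" in table.columns:
        cols.append(("resistance", None, "R (a.u.)"))
    fig, axes = plt.subplots(1, len(cols), figsize=(3.2 * len(cols), 3.5))
    for ax, (col, err, label) in zip(axes, cols):
        yerr = table[err] if err else None
        ax.bar(table["order"], table[col], yerr=yerr, capsize=3)
        ax.set_xlabel(stats.order_attr.upper())
        ax.set_ylabel(label)
        if col == "resistance":
            ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
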