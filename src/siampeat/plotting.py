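"""Minimal plotting: ordination scatter and flux-partition time series."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design import SampleDesign
from .flux import FluxPartition
from .multivariate import OrdinationResult

_COLORS = {"LO": "tab:green", "PO": "tab:brown", "PL": "tab:blue"}


def plot_ordination(
    ordination: OrdinationResult,
    design: list[SampleDesign],
    path: str | Path,
) -> Path:
    """Scatter the first two principal coordinates, colored by treatment and
    annotated with timepoints."""
    path = Path(path)
    coords = ordination.coordinates
    by_id = {s.sample_id: s for s in design}
    fig, ax = plt.subplots(figsize=(6, 5))
    for sid, row in coords.iterrows():
        s = by_id.get(sid)
        color = _COLORS.get(s.treatment if s else "", "gray")
        ax.scatter(row.iloc[0], row.iloc[1], c=color, s=30)
        if s is not None:
            ax.annotate(f"{s.treatment}-{s.timepoint}", (row.iloc[0], row.iloc[1]),
                        fontsize=6, alpha=0.7)
    props = ordination.proportion_explained
    ax.set_xlabel(f"PCo1 ({100 * props[0]:.1f}%)" if len(props) > 0 else "PCo1")
    ax.set_ylabel(f"PCo2 ({100 * props[1]:.1f}%)" if len(props) > 1 else "PCo2")
    ax.set_title("PCoA of Manhattan distances")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_flux_partition(partition: FluxPartition, path: str | Path) -> Path:
    """Mean litter/peat/priming flux components over the incubation."""
    path = Path(path)
    per = partition.per_jar_day
    by_day = per.groupby("day")[["litter_flux", "peat_flux", "priming_flux"]].mean()
    fig, ax = plt.subplots(figsize=(6, 4))
    for col, style in (
        ("litter_flux", "-o"),
        ("peat_flux", "-s"),
        ("priming_flux", "--^"),
    ):
        ax.plot(by_day.index, by_day[col], style, label=col.replace("_flux", ""))
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("day")
    ax.set_ylabel(f"flux ({partition.unit})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
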