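"""State-trace plots: condition means of one dependent variable against
another, with standard-error bars and the best-fitting monotonic curve."""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .cmr import MonotonicModel, StateTraceData

# default theme: colour per social exchange type, marker per item type,
# fill per emotion-perception group
EXCHANGE_COLORS = {
    "sincere": "#1b9e77",
    "simple_sarcasm": "#d95f02",
    "paradoxical_sarcasm": "#7570b3",
    "sarcasm": "#e7298a",
    "lying": "#66a61e",
}
ITEM_MARKERS = {"target": "o", "lure": "s"}


@dataclass
class PlotSpec:
    data: StateTraceData
    model: MonotonicModel
    output_path: str
    error_bars: str = "se"  # "se" or "none"
    title: str | None = None


def render_state_trace(spec: PlotSpec):
    """Draw the state-trace plot and write it to ``spec.output_path``.

    One point per condition; error bars are the standard errors implied by
    the precision weights (SE = 1/sqrt(w)); the dashed line traces the
    fitted monotonic values in the model's common order.  Returns the
    matplotlib Figure (already saved and closed).
    """
    data, model = spec.data, spec.model
    if spec.error_bars not in ("se", "none"):
        raise ValueError(f"unknown error_bars option {spec.error_bars!r}")

    fig, ax = plt.subplots(figsize=(6, 6))
    x, y = data.x_means, data.y_means
    xerr = 1.0 / np.sqrt(data.x_weights) if spec.error_bars == "se" else None
    yerr = 1.0 / np.sqrt(data.y_weights) if spec.error_bars == "se" else None

    for j, label in enumerate(data.condition_labels):
        if isinstance(label, tuple) and len(label) == 3:
            exchange, item, group = label
            color = EXCHANGE_COLORS.get(exchange, "#444444")
            marker = ITEM_MARKERS.get(item, "o")
            face = color if group == "high" else "white"
        else:
            color, marker, face = "#444444", "o", "#444444"
        ax.errorbar(
            x[j], y[j],
            xerr=None if xerr is None else xerr[j],
            yerr=None if yerr is None else yerr[j],
            fmt=marker, color=color, markerfacecolor=face,
            markeredgecolor=color, ecolor=color, elinewidth=0.8,
            capsize=2, markersize=6,
        )

    order = model.order
    ax.plot(
        model.x_fitted[order], model.y_fitted[order],
        linestyle="--", color="black", linewidth=1.2, zorder=1,
        label="best-fitting monotonic curve",
    )
    ax.set_xlabel(f"{data.dv_names[0]} endorsement rate")
    ax.set_ylabel(f"{data.dv_names[1]} endorsement rate")
    if spec.title:
        ax.set_title(spec.title)

    handles = [
        plt.Line2D([], [], linestyle="--", color="black", label="monotonic fit"),
        plt.Line2D([], [], marker="o", linestyle="", color="#444444", label="target"),
        plt.Line2D([], [], marker="s", linestyle="", color="#444444", label="lure"),
    ]
    ax.legend(handles=handles, loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(spec.output_path, dpi=150)
    plt.close(fig)
    return fig
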