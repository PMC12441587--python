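"""Figure rendering: network diagrams and node-strength dot plots.

Every figure is written together with a CSV sidecar holding the exact
numbers drawn, so downstream checks (and reruns) compare data, not pixels.
Nodes sit on a fixed circular layout, alphabetical by item code, making
diagrams comparable across strata.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .items import ITEM_CODES, ITEM_NAMES

#: Edge colors by per-wave significance pattern.
EDGE_COLORS = {
    (True, True): "#b2182b",    # significant in both waves
    (True, False): "#2166ac",   # only wave 6
    (False, True): "#ef8a62",   # only wave 8
    (False, False): "#bdbdbd",  # neither
}


def circular_layout() -> dict[str, tuple[float, float]]:
    """Fixed positions: unit circle, alphabetical by item code."""
    codes = sorted(ITEM_CODES)
    pos = {}
    for k, c in enumerate(codes):
        theta = 2.0 * math.pi * k / len(codes)
        pos[c] = (math.cos(theta), math.sin(theta))
    return pos


def edge_width(ratio: float) -> float:
    """Monotone map from OR-ratio weight to stroke width (points)."""
    return 0.6 + 3.0 * math.tanh(max(ratio, 0.0) / 2.0)


def render_network_diagram(
    network: nx.Graph,
    path: str | Path,
    ratio_weights: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Draw one stratum's symptom network; returns the sidecar frame.

    Edge width is monotone in the OR-ratio weight (bolder = association
    strengthened over follow-up); edge color encodes the per-wave
    significance pattern. The sidecar CSV (same stem, ``.csv``) lists every
    drawn edge with its weight, ratio, width and color.
    """
    path = Path(path)
    pos = circular_layout()
    rows = []
    for i, j, data in sorted(network.edges(data=True)):
        ratio = data.get("weight") if network.graph.get("scheme") == "or_ratio" else None
        if ratio is None and ratio_weights is not None:
            ratio = ratio_weights.get((i, j), ratio_weights.get((j, i)))
        sig = (bool(data.get("sig_w6", False)), bool(data.get("sig_w8", False)))
        rows.append(
            {
                "item_i": i,
                "item_j": j,
                "weight": float(data.get("weight", 0.0)),
                "or_ratio": float(ratio) if ratio is not None else float("nan"),
                "sig_w6": sig[0],
                "sig_w8": sig[1],
                "width": edge_width(ratio if ratio is not None else 1.0),
                "color": EDGE_COLORS[sig],
            }
        )
    sidecar = pd.DataFrame(
        rows,
        columns=["item_i", "item_j", "weight", "or_ratio",
                 "sig_w6", "sig_w8", "width", "color"],
    )
    sidecar.to_csv(path.with_suffix(".csv"), index=False)

    fig, ax = plt.subplots(figsize=(5, 5))
    nx.draw_networkx_nodes(network, pos, ax=ax, node_size=650,
                           node_color="#f0f0f0", edgecolors="#636363")
    nx.draw_networkx_labels(network, pos, ax=ax, font_size=8)
    if len(sidecar):
        nx.draw_networkx_edges(
            network, pos, ax=ax,
            edgelist=[(r["item_i"], r["item_j"]) for _, r in sidecar.iterrows()],
            width=sidecar["width"].tolist(),
            edge_color=sidecar["color"].tolist(),
        )
    ax.set_title(
        f"{network.graph.get('stratum', '')} / {network.graph.get('sex', '')}"
        + (f" / wave {network.graph['wave']}"
           if network.graph.get("wave") else "")
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return sidecar


def render_strength_dotplot(
    strength_deltas: pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Dot plot of per-symptom node strength, wave 6 vs wave 8, per panel.

    ``strength_deltas`` carries columns item, stratum, sex, strength_w6,
    strength_w8 (one row per symptom per stratum-sex panel). The distance
    between a symptom's two dots is its change in strength. Returns the
    sidecar frame written next to the figure.
    """
    path = Path(path)
    req = {"item", "stratum", "sex", "strength_w6", "strength_w8"}
    missing = req - set(strength_deltas.columns)
    if missing:
        raise ValueError(f"strength table lacks columns {sorted(missing)}")
    panels = sorted(
        strength_deltas.groupby(["stratum", "sex"], observed=True).groups
    )
    sidecar = strength_deltas.sort_values(
        ["stratum", "sex", "item"], kind="stable"
    ).reset_index(drop=True)
    sidecar.to_csv(path.with_suffix(".csv"), index=False)

    ncol = min(3, max(1, len(panels)))
    nrow = max(1, math.ceil(len(panels) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False
    )
    for ax in axes.flat[len(panels):]:
        ax.set_axis_off()
    for ax, key in zip(axes.flat, panels):
        stratum, sex = key
        sub = strength_deltas[
            (strength_deltas["stratum"] == stratum)
            & (strength_deltas["sex"] == sex)
        ].set_index("item").reindex(list(ITEM_CODES))
        y = range(len(ITEM_CODES))
        ax.scatter(sub["strength_w6"], y, color="#2166ac", s=22,
                   label="wave 6", zorder=3)
        ax.scatter(sub["strength_w8"], y, color="#e78ac3", s=22,
                   label="wave 8", zorder=3)
        for k in y:
            ax.plot(
                [sub["strength_w6"].iloc[k], sub["strength_w8"].iloc[k]],
                [k, k], color="#bdbdbd", lw=1, zorder=2,
            )
        ax.set_yticks(list(y))
        ax.set_yticklabels([ITEM_NAMES[c] for c in ITEM_CODES], fontsize=7)
        ax.set_title(f"{stratum} / {sex}", fontsize=9)
        ax.set_xlabel("node strength (sum of significant ORs)", fontsize=7)
    if panels:
        axes.flat[0].legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return sidecar
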