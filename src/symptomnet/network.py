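"""Symptom networks, edge-weight schemes and node strength.

Nodes are the 12 EURO-D items; an edge is drawn between two symptoms only
when more than 20 respondents in the stratum report the pair together
(strictly greater, i.e. at least 21 co-occurrences). Two weight schemes:

``significant_or``
    The edge carries the wave's odds ratio if its association is
    statistically significant, else weight 0. The default significance gate
    requires the lower 95% CI bound to exceed 1 (OR significantly *above*
    unity); a two-sided gate (CI excludes 1) is available.

``or_ratio``
    The edge carries OR(wave 8) / OR(wave 6) — values above 1 mark symptom
    pairs whose association strengthened over follow-up. Both waves must
    clear the co-occurrence threshold.

Node strength is the sum of ``significant_or`` weights over edges incident
on the node, computed separately per wave; the cross-wave difference
(strength at wave 8 minus wave 6) ranks symptoms by how much associative
weight they gained or lost.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .items import ITEM_CODES, item_index

#: Edge-inclusion threshold: a pair needs MORE than this many co-occurrences.
DEFAULT_EDGE_THRESHOLD = 20

SCHEMES = ("significant_or", "or_ratio")


def include_edge(
    n_ij_w6: int | None,
    n_ij_w8: int | None,
    scheme: str,
    wave: int | None = None,
    threshold: int = DEFAULT_EDGE_THRESHOLD,
) -> bool:
    """Apply the co-occurrence rule (strict: ``n_ij > threshold``).

    Single-wave (``significant_or``) networks test that wave's count only;
    ``or_ratio`` needs the threshold in both waves since the ratio requires
    both odds ratios to exist.
    """
    if scheme == "significant_or":
        if wave not in (6, 8):
            raise ValueError("significant_or inclusion needs wave 6 or 8")
        n = n_ij_w6 if wave == 6 else n_ij_w8
        return n is not None and n > threshold
    if scheme == "or_ratio":
        return (
            n_ij_w6 is not None
            and n_ij_w8 is not None
            and n_ij_w6 > threshold
            and n_ij_w8 > threshold
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def or_ratio_weight(or_w6: float, or_w8: float) -> float:
    """OR(wave 8) / OR(wave 6); raises when the ratio is undefined."""
    if not np.isfinite(or_w6) or not np.isfinite(or_w8) or or_w6 <= 0:
        raise ValueError(
            f"or_ratio undefined for OR_w6={or_w6}, OR_w8={or_w8}"
        )
    return float(or_w8 / or_w6)


def significant_or_weight(
    or_value: float, ci_low: float, ci_high: float, gate: str = "above"
) -> float:
    """OR if significant, else 0.

    ``gate="above"``: weight only when the lower CI bound exceeds 1.
    ``gate="diff"``: weight whenever the CI excludes 1 (so a significantly
    *protective* association also keeps its OR).
    """
    if gate == "above":
        return float(or_value) if ci_low > 1.0 else 0.0
    if gate == "diff":
        return float(or_value) if (ci_low > 1.0 or ci_high < 1.0) else 0.0
    raise ValueError(f"unknown gate {gate!r}")


def _stratum_edges(
    edges: pd.DataFrame, stratum: str, sex: str
) -> pd.DataFrame:
    sel = (edges["stratum"] == stratum) & (edges["sex"] == sex)
    return edges.loc[sel]


def build_network(
    edges: pd.DataFrame,
    stratum: str,
    sex: str = "all",
    wave: int | None = None,
    scheme: str = "significant_or",
    threshold: int = DEFAULT_EDGE_THRESHOLD,
    gate: str = "above",
) -> nx.Graph:
    """Assemble one stratum's symptom network from an edge-estimate table.

    ``edges`` is the tidy frame produced by
    :func:`symptomnet.association.estimate_all`. For ``significant_or`` a
    wave must be given; for ``or_ratio`` the wave argument is ignored (the
    scheme spans both waves). All 12 items are present as nodes regardless
    of how many edges survive.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    g = nx.Graph(stratum=stratum, sex=sex, scheme=scheme,
                 wave=(wave if scheme == "significant_or" else 0),
                 gate=gate)
    g.add_nodes_from(ITEM_CODES)

    if edges.empty:
        return g
    sub = _stratum_edges(edges, stratum, sex)
    if sub.empty:
        return g

    by_pair: dict[tuple[str, str], dict[int, pd.Series]] = {}
    for _, row in sub.iterrows():
        by_pair.setdefault((row["item_i"], row["item_j"]), {})[
            int(row["wave"])
        ] = row

    for (i, j), per_wave in sorted(
        by_pair.items(), key=lambda kv: (item_index(kv[0][0]), item_index(kv[0][1]))
    ):
        n6 = int(per_wave[6]["n_ij"]) if 6 in per_wave else None
        n8 = int(per_wave[8]["n_ij"]) if 8 in per_wave else None
        sig6 = bool(per_wave[6]["sig_above"]) if 6 in per_wave else False
        sig8 = bool(per_wave[8]["sig_above"]) if 8 in per_wave else False
        if scheme == "significant_or":
            if wave not in (6, 8):
                raise ValueError("significant_or networks need wave 6 or 8")
            if wave not in per_wave or not include_edge(
                n6, n8, scheme, wave=wave, threshold=threshold
            ):
                continue
            row = per_wave[wave]
            w = significant_or_weight(
                row["or"], row["ci_low"], row["ci_high"], gate=gate
            )
            g.add_edge(i, j, weight=w, or_value=float(row["or"]),
                       n_ij=int(row["n_ij"]), sig_w6=sig6, sig_w8=sig8,
                       scheme=scheme)
        else:
            if not include_edge(n6, n8, scheme, threshold=threshold):
                continue
            or6 = float(per_wave[6]["or"])
            or8 = float(per_wave[8]["or"])
            try:
                w = or_ratio_weight(or6, or8)
            except ValueError:
                continue  # undefined ratio: edge dropped
            g.add_edge(i, j, weight=w, or_w6=or6, or_w8=or8,
                       n_ij_w6=n6, n_ij_w8=n8, sig_w6=sig6, sig_w8=sig8,
                       scheme=scheme)
    return g


def node_strength(network: nx.Graph) -> pd.DataFrame:
    """Per-node sum of incident significant-OR weights.

    Only defined for ``significant_or`` networks; isolated nodes have
    strength 0.
    """
    if network.graph.get("scheme") != "significant_or":
        raise ValueError(
            "node strength is defined on significant_or networks, got "
            f"{network.graph.get('scheme')!r}"
        )
    strengths = dict(network.degree(weight="weight"))
    return pd.DataFrame(
        {
            "item": list(ITEM_CODES),
            "wave": network.graph.get("wave"),
            "stratum": network.graph.get("stratum"),
            "sex": network.graph.get("sex"),
            "strength": [float(strengths.get(c, 0.0)) for c in ITEM_CODES],
        }
    )


def strength_change(
    network_w6: nx.Graph, network_w8: nx.Graph
) -> pd.DataFrame:
    """Per-node strength difference, wave 8 minus wave 6.

    Both networks must describe the same stratum and sex under the
    ``significant_or`` scheme. Output is ordered by \\|delta\\| descending.
    """
    for key in ("stratum", "sex"):
        if network_w6.graph.get(key) != network_w8.graph.get(key):
            raise ValueError(
                f"stratum mismatch: {key} differs "
                f"({network_w6.graph.get(key)!r} vs {network_w8.graph.get(key)!r})"
            )
    s6 = node_strength(network_w6).set_index("item")["strength"]
    s8 = node_strength(network_w8).set_index("item")["strength"]
    out = pd.DataFrame(
        {
            "item": list(ITEM_CODES),
            "stratum": network_w6.graph.get("stratum"),
            "sex": network_w6.graph.get("sex"),
            "strength_w6": s6.reindex(ITEM_CODES).to_numpy(),
            "strength_w8": s8.reindex(ITEM_CODES).to_numpy(),
        }
    )
    out["delta"] = out["strength_w8"] - out["strength_w6"]
    out = out.sort_values(
        "delta", key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
    return out


def network_edge_list(network: nx.Graph) -> pd.DataFrame:
    """Edge-list mirror of a network (one row per edge, attributes as columns)."""
    rows = []
    for i, j, data in sorted(
        network.edges(data=True),
        key=lambda e: (item_index(e[0]), item_index(e[1])),
    ):
        row = {"item_i": i, "item_j": j}
        row.update({k: data[k] for k in sorted(data)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_graphml(network: nx.Graph, path) -> None:
    """GraphML export with per-node ``strength`` where defined."""
    g = network.copy()
    if g.graph.get("scheme") == "significant_or":
        s = node_strength(network).set_index("item")["strength"]
        nx.set_node_attributes(g, s.to_dict(), "strength")
    nx.write_graphml(g, path)
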