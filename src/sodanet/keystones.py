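"""Signed association networks, topological importance, and keystone calls.

Significant pairwise associations are assembled into two undirected signed
weighted graphs per lake — a *synchronous* network (delay 0) and a
*time-shifted* network (delay ±1).  Node importance is measured by weighted
topological importance WI^n: one-step effects ``a_ij = |w_ij| / sum_k
|w_ik|`` (the effect of j on i, proportional to edge-weight share), m-step
effects by matrix powers of ``A`` (walks may revisit nodes), and

    sigma_m[j] = sum_{i != j} (A^m)_{ij}        (diagonal excluded each step)
    WI^n[j]    = (sigma_1[j] + ... + sigma_n[j]) / n

Keystones are nodes with WI^3 > 1, expanded to WI^3 >= 1 whenever fewer than
six nodes pass the strict rule.  A keystone's interaction class is the sign
of its summed signed incident weights; its preferred season comes from
either the relative-abundance rule (season mean exceeding the study mean by
more than the study standard deviation) or the z-score rule (season(s) with
positive mean z-scored abundance).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .tables import SEASONS, OtuTable


# ---------------------------------------------------------------------------
# Graph construction and summaries
# ---------------------------------------------------------------------------

def edge_weight(row) -> float:
    """Signed weight of a significant association: SSCC value for global
    edges, signed LS score for local ones."""
    if row["edge_type"] == "SSCC":
        return float(row["sscc"])
    return float(row["sign"] * row["ls_score"])


def build_network(edges: pd.DataFrame, which: str) -> nx.Graph:
    """Assemble one lake's network from its significant association table.

    ``which`` selects ``"synchronous"`` (delay 0) or ``"time_shifted"``
    (delay ±1) edges.  Nodes without edges never enter the graph, so
    isolated nodes are implicitly dropped.
    """
    if which not in ("synchronous", "time_shifted"):
        raise ValueError(f"unknown network kind {which!r}")
    g = nx.Graph(kind=which)
    sub = edges.loc[edges.get("significant", True) & (edges["network"] == which)]
    if sub.empty:
        warnings.warn(f"no {which} edges: empty network")
        return g
    for _, row in sub.iterrows():
        w = edge_weight(row)
        if w == 0 or row["otu_a"] == row["otu_b"]:
            continue
        g.add_edge(
            row["otu_a"],
            row["otu_b"],
            weight=w,
            sign=int(np.sign(w)),
            type=row["edge_type"],
            delay=int(row["delay"]),
        )
    return g


def network_properties(g: nx.Graph) -> dict:
    """Node/edge counts, density, mean degree, and edge-sign/type tallies."""
    v = g.number_of_nodes()
    e = g.number_of_edges()
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    types = [d.get("type", "LS") for _, _, d in g.edges(data=True)]
    degenerate = v <= 1
    return {
        "nodes": v,
        "edges": e,
        "density": 0.0 if degenerate else 2 * e / (v * (v - 1)),
        "density_defined": not degenerate,
        "mean_degree": 0.0 if v == 0 else 2 * e / v,
        "positive_edges": int(sum(w > 0 for w in weights)),
        "negative_edges": int(sum(w < 0 for w in weights)),
        "ls_edges": int(sum(t == "LS" for t in types)),
        "sscc_edges": int(sum(t == "SSCC" for t in types)),
    }


# ---------------------------------------------------------------------------
# Weighted topological importance
# ---------------------------------------------------------------------------

def topological_importance(g: nx.Graph, steps: int = 3) -> dict:
    """WI^n per node with the per-step neighbourhood effects sigma_m.

    Edge signs are ignored here (absolute weights measure interaction
    strength); the positive/negative classification is a separate, signed
    summary (:func:`keystone_sign`).  Isolated nodes get WI = 0.

    Returns ``{node: {"sigma": [sigma_1..sigma_n], "wi": WI^n}}``.
    """
    nodes = list(g.nodes)
    k = len(nodes)
    if k == 0:
        return {}
    w = np.abs(nx.to_numpy_array(g, nodelist=nodes, weight="weight"))
    strength = w.sum(axis=1)
    a = np.divide(w, strength[:, None], out=np.zeros_like(w), where=strength[:, None] > 0)
    out = {node: {"sigma": [], "wi": 0.0} for node in nodes}
    power = np.eye(k)
    for _ in range(steps):
        power = power @ a
        off = power - np.diag(np.diag(power))
        sigma = off.sum(axis=0)  # column sums: total m-step effect of node j
        for j, node in enumerate(nodes):
            out[node]["sigma"].append(float(sigma[j]))
    for node in nodes:
        out[node]["wi"] = float(sum(out[node]["sigma"]) / steps)
    return out


def call_keystones(wi: dict, strict: float = 1.0, min_count: int = 6) -> set:
    """Keystone rule: WI^3 > 1, expanded to WI^3 >= 1 if fewer than six pass.

    ``wi`` maps node -> WI value (the output of
    :func:`topological_importance` is also accepted).
    """
    values = {
        node: (v["wi"] if isinstance(v, dict) else float(v)) for node, v in wi.items()
    }
    keystones = {node for node, v in values.items() if v > strict}
    if len(keystones) < min_count:
        keystones = {node for node, v in values.items() if v >= strict}
    return keystones


def keystone_sign(g: nx.Graph, node) -> str:
    """Overall interaction direction: sign of summed signed incident weights."""
    if node not in g:
        raise ValueError(f"node {node!r} not in network")
    total = sum(d["weight"] for _, _, d in g.edges(node, data=True))
    if abs(total) < 1e-12:
        return "unspecified"
    return "positive" if total > 0 else "negative"


# ---------------------------------------------------------------------------
# Season preference
# ---------------------------------------------------------------------------

def preferred_season(values, season_labels, method: str = "relabund") -> str:
    """Assign an OTU's preferred season from its per-sample abundance series.

    method="relabund": a season qualifies when its mean exceeds the
    study-period mean by more than the study-period population standard
    deviation; the qualifying season with the largest excess is returned
    (``"none"`` if no season qualifies).

    method="zscore": z-transform the series over the study; the preferred
    season is the single season with positive mean z (``"none"`` if none is
    positive, ``"unspecified"`` if several are).

    Seasons with no present sample are skipped with a warning.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(season_labels)
    if v.shape != labels.shape:
        raise ValueError("values and season labels differ in length")
    seasons = [s for s in SEASONS if s in labels]
    for s in set(labels) - set(SEASONS):
        raise ValueError(f"unknown season label {s!r}")
    skipped = [s for s in SEASONS if s not in labels]
    if skipped:
        warnings.warn(f"no samples in season(s) {skipped}; skipped")
    mean_study = v.mean()
    if method == "relabund":
        sd_study = v.std()  # population SD over present samples
        excess = {s: v[labels == s].mean() - mean_study for s in seasons}
        qualifying = {s: e for s, e in excess.items() if e > sd_study}
        if not qualifying:
            return "none"
        return max(qualifying, key=qualifying.get)
    if method == "zscore":
        sd = v.std()
        z = np.zeros_like(v) if sd == 0 else (v - mean_study) / sd
        positive = [s for s in seasons if z[labels == s].mean() > 0]
        if not positive:
            return "none"
        if len(positive) > 1:
            return "unspecified"
        return positive[0]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Keystone report and export
# ---------------------------------------------------------------------------

def keystone_report(
    networks: dict,
    table: OtuTable,
    season_labels,
    core: set,
    domain_map: dict | None = None,
) -> pd.DataFrame:
    """One record per keystone per network, sorted by WI^3 descending.

    ``networks`` maps network name (synchronous/time_shifted) to its graph;
    ``table`` is the lake's count table over present samples (row order =
    ``season_labels`` order); ``core`` the core OTU set; ``domain_map`` an
    optional OTU -> domain tag (eukaryote/bacterium).
    """
    frac = table.counts / table.counts.sum(axis=1, keepdims=True)
    col = {o: i for i, o in enumerate(table.otu_ids)}
    rows = []
    for net_name, g in networks.items():
        wi = topological_importance(g, steps=3)
        keystones = call_keystones(wi)
        for node in keystones:
            series = frac[:, col[node]] if node in col else None
            rows.append(
                {
                    "otu_id": node,
                    "network": net_name,
                    "wi3": wi[node]["wi"],
                    "sign_class": keystone_sign(g, node),
                    "core_label": "core" if node in core else "noncore",
                    "domain": (domain_map or {}).get(node, "unknown"),
                    "season_relabund": (
                        preferred_season(series, season_labels, "relabund")
                        if series is not None
                        else "none"
                    ),
                    "season_zscore": (
                        preferred_season(series, season_labels, "zscore")
                        if series is not None
                        else "none"
                    ),
                }
            )
    columns = [
        "otu_id",
        "network",
        "wi3",
        "sign_class",
        "core_label",
        "domain",
        "season_relabund",
        "season_zscore",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(rows, columns=columns)
        .sort_values(["wi3", "otu_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def annotate_and_export(
    g: nx.Graph,
    path,
    core: set | None = None,
    seasons: dict | None = None,
    domain_map: dict | None = None,
) -> None:
    """Write GraphML with node annotations (domain, core label, season, WI^3,
    keystone flag, sign class) and edge attributes (weight, sign, type, delay)."""
    wi = topological_importance(g, steps=3)
    keystones = call_keystones(wi)
    for node in g.nodes:
        g.nodes[node]["wi3"] = wi[node]["wi"]
        g.nodes[node]["keystone"] = node in keystones
        g.nodes[node]["sign_class"] = keystone_sign(g, node)
        if core is not None:
            g.nodes[node]["core_label"] = "core" if node in core else "noncore"
        if seasons is not None:
            g.nodes[node]["preferred_season"] = seasons.get(node, "none")
        if domain_map is not None:
            g.nodes[node]["domain"] = domain_map.get(node, "unknown")
    nx.write_graphml(g, path)


def edge_list_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "otu_a": a,
            "otu_b": b,
            "weight": d["weight"],
            "sign": d.get("sign", int(np.sign(d["weight"]))),
            "type": d.get("type", "LS"),
            "delay": d.get("delay", 0),
        }
        for a, b, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["otu_a", "otu_b", "weight", "sign", "type", "delay"]
    )
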