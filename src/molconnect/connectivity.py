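"""Integrative descriptor-connectivity analysis.

The endpoint-specific descriptor selections are intersected into a
common set plus endpoint-unique sets, each descriptor is tested for a
class difference by one-way two-group ANOVA (equivalently a pooled t
test, F = t^2), and the partition is exported as a bipartite-style
connectivity map (endpoint nodes linked to the descriptors selected for
them; common descriptors have degree 2).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .curation import LabelledDataset

__all__ = [
    "intersect_descriptors",
    "anova_table",
    "class_profile",
    "build_connectivity_map",
    "write_sif",
]


def intersect_descriptors(set_a, set_b,
                          name_a: str = "hia", name_b: str = "caco2"):
    """Partition two descriptor selections into common and unique sets.

    Returns ``(common, unique_a, unique_b)``, each sorted for
    deterministic output.
    """
    a, b = set(map(str, set_a)), set(map(str, set_b))
    if not a or not b:
        raise ValueError("both descriptor sets must be non-empty")
    return (sorted(a & b), sorted(a - b), sorted(b - a))


def anova_table(d: LabelledDataset, names=None,
                alpha: float = 0.05, adjust: bool = False) -> pd.DataFrame:
    """Per-descriptor one-way two-group ANOVA (positive vs negative class).

    Returns a DataFrame with F, p and a significance flag at ``alpha``
    (raw p-values, matching the unadjusted convention); pass
    ``adjust=True`` for an additional Benjamini-Hochberg column.
    """
    pos, neg = d.y == 1, d.y == -1
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each class needs at least 2 members for ANOVA")
    cols = [str(n) for n in (names if names is not None else d.X.columns)]
    x = d.X[cols].to_numpy(dtype=float)
    f, p = stats.f_oneway(x[pos], x[neg], axis=0)
    table = pd.DataFrame({"F": f, "p": p}, index=cols)
    table["significant"] = table["p"] <= alpha
    if adjust:
        order = np.argsort(p)
        k = len(p)
        bh = np.empty(k)
        prev = 1.0
        for rank in range(k - 1, -1, -1):
            i = order[rank]
            prev = min(prev, p[i] * k / (rank + 1))
            bh[i] = prev
        table["p_bh"] = bh
    return table


def class_profile(d: LabelledDataset, names=None) -> pd.DataFrame:
    """Class-wise descriptor means and z-scored means (heat-map export)."""
    cols = [str(n) for n in (names if names is not None else d.X.columns)]
    x = d.X[cols]
    mean_pos = x[d.y == 1].mean()
    mean_neg = x[d.y == -1].mean()
    sd = x.std(ddof=1).replace(0.0, np.nan)
    grand = x.mean()
    return pd.DataFrame({
        "mean_positive": mean_pos,
        "mean_negative": mean_neg,
        "z_positive": (mean_pos - grand) / sd,
        "z_negative": (mean_neg - grand) / sd,
    })


def build_connectivity_map(common, unique_a, unique_b,
                           per_descriptor_accuracy: dict | None = None,
                           endpoint_a: str = "hia",
                           endpoint_b: str = "caco2") -> nx.Graph:
    """Bipartite-style connectivity map of the descriptor partition.

    Endpoint nodes connect to every descriptor selected for them, so
    common descriptors are degree-2 nodes and unique ones degree-1.
    Per-descriptor accuracies, when given, annotate the nodes.
    """
    common, unique_a, unique_b = (set(common), set(unique_a), set(unique_b))
    overlap = (common & unique_a) | (common & unique_b) | (unique_a & unique_b)
    if overlap:
        raise ValueError(f"sets must be disjoint; overlap: {sorted(overlap)}")
    g = nx.Graph()
    g.add_node(endpoint_a, kind="endpoint")
    g.add_node(endpoint_b, kind="endpoint")
    acc = per_descriptor_accuracy or {}
    for name in sorted(common):
        g.add_node(name, kind="descriptor", status="common",
                   **({"accuracy": float(acc[name])} if name in acc else {}))
        g.add_edge(endpoint_a, name)
        g.add_edge(endpoint_b, name)
    for name, endpoint in [(n, endpoint_a) for n in sorted(unique_a)] + [
            (n, endpoint_b) for n in sorted(unique_b)]:
        g.add_node(name, kind="descriptor", status="unique",
                   **({"accuracy": float(acc[name])} if name in acc else {}))
        g.add_edge(endpoint, name)
    return g


def write_sif(g: nx.Graph, path) -> None:
    """Write the map as a SIF file (``endpoint associates descriptor``)."""
    lines = []
    for u, v in sorted(g.edges()):
        src, dst = (u, v) if g.nodes[u].get("kind") == "endpoint" else (v, u)
        lines.append(f"{src}\tassociates\t{dst}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_connectivity(g: nx.Graph, out_dir, stem: str = "connectivity") -> dict:
    """Write SIF + GraphML exports; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sif = out / f"{stem}.sif"
    graphml = out / f"{stem}.graphml"
    write_sif(g, sif)
    nx.write_graphml(g, graphml)
    return {"sif": str(sif), "graphml": str(graphml)}
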