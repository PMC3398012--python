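"""Ground-truth generators for every pipeline stage.

Two substrates are emulated:

* small random molecular graphs (valence-capped carbon skeletons) on
  which descriptor implementations can be checked against brute-force
  graph oracles, and
* descriptor matrices for a two-endpoint study with a *planted* block of
  informative descriptors shared between two endpoints (the
  absorption/permeability analogues) plus endpoint-unique informative
  descriptors, so that the downstream selection and connectivity
  analysis has a known answer.

In the planted study the descriptor columns are standard normal with an
exchangeable correlation ``rho`` inside the common informative block
(mimicking real descriptor collinearity); each endpoint's +1/-1 label is
drawn through a logistic link on the standardised sum of its informative
columns scaled to ``effect_sd``, plus N(0, noise_sd^2) label noise.  The
third (bioavailability-like) endpoint is driven by the common block
only.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemgraph import Atom, Bond, MolecularGraph
from .curation import LabelledDataset
from .mlbench import ConfusionCounts

__all__ = [
    "gen_random_graphs",
    "TwoEndpointStudy",
    "gen_two_endpoint_study",
    "bayes_accuracy",
    "gen_confusion_tables",
]


def _random_tree(n: int, rng: np.random.Generator,
                 max_degree: int = 4) -> list[tuple[int, int]]:
    """Random labelled tree grown by preferential-free attachment."""
    edges = []
    degree = np.zeros(n, dtype=int)
    for v in range(1, n):
        candidates = [u for u in range(v) if degree[u] < max_degree]
        if not candidates:
            raise ValueError(f"cannot grow a degree-{max_degree} tree on {n} nodes")
        u = int(rng.choice(candidates))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    return edges


def _cycle_edges(n: int, tree_edges: list[tuple[int, int]], u: int,
                 v: int) -> set[tuple[int, int]]:
    """Edges of the unique cycle closed by adding (u, v) to a tree."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in tree_edges:
        adj[a].append(b)
        adj[b].append(a)
    parent = {u: None}
    stack = [u]
    while stack:
        node = stack.pop()
        if node == v:
            break
        for nxt in adj[node]:
            if nxt not in parent:
                parent[nxt] = node
                stack.append(nxt)
    path = [v]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    ring = {(min(a, b), max(a, b)) for a, b in zip(path, path[1:])}
    ring.add((min(u, v), max(u, v)))
    return ring


def gen_random_graphs(count: int, n_range: tuple[int, int] = (2, 12),
                      cycle_prob: float = 0.0, seed: int = 0,
                      max_degree: int = 4) -> list[MolecularGraph]:
    """Seeded random connected carbon skeletons.

    Each graph is a random tree (valences capped at ``max_degree``) with,
    with probability ``cycle_prob``, one extra ring-closing edge (so the
    cyclomatic number is 1); cycles need at least 3 atoms, so when a
    cycle is drawn the size is sampled from ``[max(lo, 3), hi]``.
    """
    lo, hi = n_range
    if not (2 <= lo <= hi <= 20):
        raise ValueError("n_range must lie within [2, 20]")
    if not 0.0 <= cycle_prob <= 1.0:
        raise ValueError("cycle_prob must lie in [0, 1]")
    if cycle_prob > 0 and hi < 3:
        raise ValueError("cycles need at least 3 atoms")
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(count):
        want_cycle = rng.random() < cycle_prob
        n = int(rng.integers(max(lo, 3) if want_cycle else lo, hi + 1))
        ring_edges: set[tuple[int, int]] = set()
        for _attempt in range(100):
            edges = _random_tree(n, rng, max_degree)
            if want_cycle:
                degree = np.zeros(n, dtype=int)
                adjacent = set()
                for u, v in edges:
                    degree[u] += 1
                    degree[v] += 1
                    adjacent.add((min(u, v), max(u, v)))
                pairs = [(u, v) for u in range(n) for v in range(u + 1, n)
                         if (u, v) not in adjacent
                         and degree[u] < max_degree and degree[v] < max_degree]
                if not pairs:
                    continue  # retry with a fresh tree
                u, v = pairs[int(rng.integers(len(pairs)))]
                ring_edges = _cycle_edges(n, edges, u, v)
                edges.append((u, v))
            break
        else:
            raise ValueError("could not satisfy cycle constraint")
        degree = np.zeros(n, dtype=int)
        for u, v in edges:
            degree[u] += 1
            degree[v] += 1
        atoms = [Atom("C", n_hydrogens=int(4 - degree[i])) for i in range(n)]
        bonds = [Bond(u, v, 1.0,
                      in_ring=(min(u, v), max(u, v)) in ring_edges)
                 for u, v in edges]
        graphs.append(MolecularGraph(atoms=atoms, bonds=bonds))
    return graphs


@dataclass
class TwoEndpointStudy:
    """Three planted labelled data sets plus their ground truth."""

    endpoint_a: LabelledDataset      # HIA-like: common + unique_a columns
    endpoint_b: LabelledDataset      # caco-2-like: common + unique_b columns
    endpoint_joint: LabelledDataset  # bioavailability-like: common only
    common: list[str]
    unique_a: list[str]
    unique_b: list[str]
    effect_sd: float
    noise_sd: float
    rho: float

    @property
    def datasets(self) -> dict[str, LabelledDataset]:
        return {"hia": self.endpoint_a, "caco2": self.endpoint_b,
                "bioavailability": self.endpoint_joint}


def _draw_endpoint(rng: np.random.Generator, n: int, p: int,
                   common_idx: np.ndarray, relevant: np.ndarray,
                   effect_sd: float, noise_sd: float,
                   rho: float, endpoint: str,
                   columns: list[str]) -> LabelledDataset:
    x = rng.standard_normal((n, p))
    if rho > 0 and common_idx.size > 1:
        factor = rng.standard_normal(n)
        x[:, common_idx] = (np.sqrt(rho) * factor[:, None]
                            + np.sqrt(1 - rho) * x[:, common_idx])
    s = x[:, relevant].sum(axis=1)
    # Var(sum X_j): exchangeable rho inside the common block, unique
    # columns independent
    kc = int(np.isin(relevant, common_idx).sum())
    ku = relevant.size - kc
    var = kc + kc * (kc - 1) * rho + ku
    lin = np.zeros(n) if effect_sd == 0 else effect_sd * s / np.sqrt(var)
    lin = lin + (noise_sd * rng.standard_normal(n) if noise_sd > 0 else 0.0)
    prob = 1.0 / (1.0 + np.exp(-lin))
    y = np.where(rng.random(n) < prob, 1, -1)
    if np.unique(y).size < 2:  # pathological draw; flip one label
        y[0] = -y[0]
    frame = pd.DataFrame(x, columns=columns,
                         index=[f"{endpoint}_{i}" for i in range(n)])
    return LabelledDataset(frame, y, endpoint)


def gen_two_endpoint_study(n_per_endpoint: int = 300, p: int = 198,
                           n_common: int = 47, n_unique_a: int = 2,
                           n_unique_b: int = 3, effect_sd: float = 1.5,
                           noise_sd: float = 0.5, rho: float = 0.3,
                           seed: int = 0) -> TwoEndpointStudy:
    """Planted two-endpoint descriptor study with known ground truth.

    Defaults mirror the study design this generator emulates: 198 usable
    descriptors of which 47 informative ones are shared between the two
    endpoints, 2 are unique to the first and 3 to the second; 300
    molecules per endpoint at effect size 1.5 SD with 0.5 SD label
    noise.  The common block is exchangeably correlated (``rho``,
    default 0.3) through a single Gaussian factor, mimicking the strong
    collinearity of topological descriptor panels; all other columns
    are independent standard normals.
    """
    if n_common + n_unique_a + n_unique_b > p:
        raise ValueError("informative sets exceed descriptor count")
    if n_per_endpoint < 10:
        raise ValueError("n_per_endpoint too small")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    columns = [f"D{i + 1:03d}" for i in range(p)]
    perm = rng.permutation(p)
    common_idx = np.sort(perm[:n_common])
    unique_a_idx = np.sort(perm[n_common:n_common + n_unique_a])
    unique_b_idx = np.sort(perm[n_common + n_unique_a:
                                n_common + n_unique_a + n_unique_b])
    ds_a = _draw_endpoint(rng, n_per_endpoint, p, common_idx,
                          np.sort(np.concatenate([common_idx, unique_a_idx])),
                          effect_sd, noise_sd, rho, "hia", columns)
    ds_b = _draw_endpoint(rng, n_per_endpoint, p, common_idx,
                          np.sort(np.concatenate([common_idx, unique_b_idx])),
                          effect_sd, noise_sd, rho, "caco2", columns)
    ds_j = _draw_endpoint(rng, n_per_endpoint, p, common_idx, common_idx,
                          effect_sd, noise_sd, rho, "bioavailability",
                          columns)
    return TwoEndpointStudy(
        endpoint_a=ds_a, endpoint_b=ds_b, endpoint_joint=ds_j,
        common=[columns[i] for i in common_idx],
        unique_a=[columns[i] for i in unique_a_idx],
        unique_b=[columns[i] for i in unique_b_idx],
        effect_sd=effect_sd, noise_sd=noise_sd, rho=rho,
    )


def bayes_accuracy(effect_sd: float, noise_sd: float,
                   n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo Bayes accuracy (%) of the planted label model.

    The optimal classifier observes the standardised informative sum
    (an N(0,1) variate scaled by ``effect_sd``) but not the label noise;
    its accuracy upper-bounds any classifier trained on the descriptors.
    """
    rng = np.random.default_rng(seed)
    lin = effect_sd * rng.standard_normal(n_mc)
    if noise_sd > 0:
        # integrate the label noise with a quadrature-by-sampling grid
        eps = noise_sd * rng.standard_normal((64, 1))
        prob = (1.0 / (1.0 + np.exp(-(lin[None, :] + eps)))).mean(axis=0)
    else:
        prob = 1.0 / (1.0 + np.exp(-lin))
    return 100.0 * float(np.maximum(prob, 1.0 - prob).mean())


def gen_confusion_tables(count: int, seed: int = 0,
                         max_cell: int = 50) -> list[ConfusionCounts]:
    """Seeded random confusion tables with positive totals.

    Every hundredth table (the first of each block) is a constructed
    TP + FP = 0 edge case so precision's not-applicable branch is always
    exercised.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(count):
        if i % 100 == 0:
            tn, fn = int(rng.integers(1, max_cell)), int(rng.integers(0, max_cell))
            tables.append(ConfusionCounts(0, tn, 0, fn))
            continue
        while True:
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, max_cell, 4))
            if tp + tn + fp + fn > 0:
                break
        tables.append(ConfusionCounts(tp, tn, fp, fn))
    return tables
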