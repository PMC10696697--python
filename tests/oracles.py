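"""Independent brute-force oracles used to validate the implementation.

Each oracle re-derives a quantity by a different route from the code it
checks: explicit graph search for cost distances and tree path lengths,
step-by-step agglomeration for dendrograms, and exhaustive subset
enumeration for model selection.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

SQRT2 = float(np.sqrt(2.0))


def dijkstra_grid_oracle(marine: np.ndarray, cells: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs shortest paths on the 8-connected marine grid via networkx."""
    R, C = marine.shape
    G = nx.Graph()
    for r in range(R):
        for c in range(C):
            if not marine[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < R and 0 <= nc < C and marine[nr, nc]:
                    w = cell_size * (SQRT2 if dr and dc else 1.0)
                    G.add_edge(r * C + c, nr * C + nc, weight=w)
            G.add_node(r * C + c)
    n = len(cells)
    D = np.full((n, n), np.inf)
    for i, a in enumerate(cells):
        lengths = nx.single_source_dijkstra_path_length(G, int(a))
        D[i, i] = 0.0
        for j, b in enumerate(cells):
            if int(b) in lengths:
                D[i, j] = lengths[int(b)]
    return D


def tree_path_oracle(tree) -> tuple[float, float]:
    """PD and MPD of a dendropy tree via explicit edge-sum and graph paths."""
    G = nx.Graph()
    ids = {}

    def nid(node):
        if id(node) not in ids:
            ids[id(node)] = len(ids)
        return ids[id(node)]

    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        total += edge.length  # includes the root stem edge
        if edge.tail_node is not None:
            G.add_edge(nid(edge.tail_node), nid(edge.head_node), weight=edge.length)
    leaves = [nid(l) for l in tree.leaf_node_iter()]
    dists = []
    for a, b in itertools.combinations(leaves, 2):
        dists.append(nx.shortest_path_length(G, a, b, weight="weight"))
    mpd = float(np.mean(dists)) if dists else float("nan")
    return total, mpd


def complete_linkage_oracle(D: np.ndarray) -> np.ndarray:
    """Cophenetic matrix by explicit step-by-step complete-linkage merging."""
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(active, 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return coph


def exhaustive_aic_oracle(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Best predictor subset by AIC over all 2^k subsets."""
    terms = list(X.columns)
    best_aic, best_set = np.inf, []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            if subset:
                model = sm.OLS(y, sm.add_constant(X[list(subset)])).fit()
            else:
                model = sm.OLS(y, np.ones((len(y), 1))).fit()
            if model.aic < best_aic - 1e-9:
                best_aic, best_set = model.aic, list(subset)
    return best_set
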