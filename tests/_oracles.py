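"""Independent brute-force reference implementations used only by tests.

Deliberately naive: pure-Python BFS, explicit double loops over atom
pairs, and an SVD route to the influence matrix, so they share no code
path with the package implementations they check.
"""
from collections import deque

import numpy as np


def bfs_distances(n_atoms, edges):
    """All-pairs shortest paths by repeated BFS over an edge list."""
    adj = {i: [] for i in range(n_atoms)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n_atoms, n_atoms), -1, dtype=int)
    for start in range(n_atoms):
        dist[start, start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[start, v] < 0:
                    dist[start, v] = dist[start, u] + 1
                    queue.append(v)
    return dist


def moran_brute(dist, weights, lag):
    """Moran index by direct double loop; returns None when no pairs."""
    w = np.asarray(weights, dtype=float)
    a = len(w)
    wbar = w.mean()
    num, pairs = 0.0, 0
    for i in range(a):
        for j in range(i + 1, a):
            if dist[i, j] == lag:
                num += (w[i] - wbar) * (w[j] - wbar)
                pairs += 1
    if pairs == 0:
        return None
    denom = ((w - wbar) ** 2).sum() / a
    return (num / pairs) / denom


def rdf_brute(coords, weights, radius, beta):
    total = 0.0
    n = len(weights)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            total += weights[i] * weights[j] * np.exp(-beta * (radius - r) ** 2)
    return total


def leverages_svd(coords):
    """Influence-matrix diagonal via an orthonormal basis (H = U U^T)."""
    centered = np.asarray(coords, float) - np.asarray(coords, float).mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    keep = s > 1e-9 * max(s.max(initial=0.0), 1.0)
    basis = u[:, keep]
    return (basis ** 2).sum(axis=1)


def r_index_brute(coords, dist, weights, lag, mode):
    h = leverages_svd(coords)
    n = len(weights)
    terms = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] == lag:
                r = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
                terms.append(np.sqrt(h[i] * h[j]) / r * weights[i] * weights[j])
    if not terms:
        return 0.0
    return sum(terms) if mode == "sum" else max(terms)


def lop_brute(n_atoms, edges):
    """Lopping centric index by literal set-based pruning."""
    adj = {i: set() for i in range(n_atoms)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    alive = set(range(n_atoms))
    classes = []
    while alive:
        terminal = {v for v in alive if len(adj[v] & alive) <= 1}
        removed = terminal if terminal else set(alive)
        classes.append(len(removed))
        alive -= removed
    total = sum(classes)
    return -sum((c / total) * np.log2(c / total) for c in classes)


def loo_brute(X, y, fit):
    """Naive LOO: literally delete each row, refit with ``fit``, predict it.

    ``fit`` maps (X, y) -> (intercept, coefs); returns held-out predictions.
    """
    n = len(y)
    preds = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        b0, coefs = fit(X[mask], y[mask])
        preds[k] = b0 + X[k] @ coefs
    return preds
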