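"""Independent oracles used by the test suite.

Each routine here deliberately re-derives a quantity by a different
route than the package (quaternion superposition instead of SVD,
explicit path enumeration instead of Brandes' algorithm, double loops
instead of KD-trees) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Horn's closed-form quaternion superposition.

    Returns the residual field reference − (R·mobile + t) for the
    optimal rigid transform, without using an SVD.
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    a = mobile - cm
    b = reference - cr
    s = a.T @ b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    evals, evecs = np.linalg.eigh(k)
    q = evecs[:, -1]  # quaternion of the largest eigenvalue
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return b - a @ rot.T


def brute_force_shortest_paths(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BFS all-pairs shortest-path lengths and path counts on a small
    unweighted graph. Returns (dist, sigma)."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in np.nonzero(adj[v])[0]:
                if np.isinf(dist[s, w]):
                    dist[s, w] = dist[s, v] + 1
                    queue.append(int(w))
                if dist[s, w] == dist[s, v] + 1:
                    sigma[s, w] += sigma[s, v]
    return dist, sigma


def brute_force_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of all shortest paths.

    For every unordered pair (u, v) and interior node i, counts the
    fraction of u–v geodesics through i, by dynamic programming over
    the BFS DAG (σ(u→i)·σ(i→v)/σ(u→v) when d(u,i)+d(i,v)=d(u,v)).
    """
    n = adj.shape[0]
    dist, sigma = brute_force_shortest_paths(adj)
    betw = np.zeros(n)
    for u in range(n):
        for v in range(u + 1, n):
            if np.isinf(dist[u, v]):
                continue
            for i in range(n):
                if i in (u, v):
                    continue
                if dist[u, i] + dist[i, v] == dist[u, v]:
                    betw[i] += sigma[u, i] * sigma[i, v] / sigma[u, v]
    return betw


def brute_force_closeness(adj: np.ndarray) -> np.ndarray:
    """Closeness 1/Σ_u sp(u, i) from BFS distances."""
    dist, _ = brute_force_shortest_paths(adj)
    return 1.0 / dist.sum(axis=1)


def brute_force_contact_count(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float
) -> int:
    """Double loop over atom pairs within the cutoff."""
    count = 0
    for p in coords_a:
        for q in coords_b:
            if np.linalg.norm(p - q) <= cutoff:
                count += 1
    return count


def random_connected_adjacency(rng: np.random.Generator, n: int, p: float = 0.35) -> np.ndarray:
    """Random Erdős–Rényi adjacency forced connected by a random spanning path."""
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        adj[a, b] = adj[b, a] = 1
    np.fill_diagonal(adj, 0)
    return adj


def random_structure(rng: np.random.Generator, n: int, jitter: float = 1.0):
    """Connected, non-collinear random Cα chain (perturbed helix).

    Draws are rejected until the 7 Å contact graph is connected, so the
    fixture always satisfies the GNM/ANM preconditions.
    """
    from scipy.sparse.csgraph import connected_components

    from enmpcn.fixtures import _assemble, _helix_coords

    base = _helix_coords(n)
    while True:
        ca = base + jitter * rng.standard_normal((n, 3))
        diff = ca[:, None, :] - ca[None, :, :]
        contact = (diff**2).sum(-1) <= 49.0
        if connected_components(contact, directed=False)[0] == 1:
            return _assemble({"A": ca})
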