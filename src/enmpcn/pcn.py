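"""Protein contact networks: topology, spectral modules, cartography.

A protein contact network (PCN) places a node on every Cα and an edge
between residues whose Cα–Cα distance falls inside a window — 4 to 8 Å
by default, which excludes covalently bonded sequence neighbours
(~3.8 Å apart) while keeping significant non-covalent contacts. On
this unweighted graph the module computes degree, betweenness and
closeness centralities, the characteristic path length, a recursive
spectral (Fiedler-vector) bisection into modules, and the
Guimerà–Amaral node cartography built from the participation
coefficient P and the intramodule degree z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph

from .structures import CoarseStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ContactNetwork",
    "NetworkDescriptors",
    "ClusterPartition",
    "NodeCartography",
    "build_pcn",
    "descriptors",
    "spectral_clustering",
    "cartography",
    "classify_region",
]

#: Guimerà–Amaral hub threshold on the intramodule z-score.
HUB_Z = 2.5


@dataclass
class ContactNetwork:
    """Unweighted PCN adjacency over the residues of one structure."""

    adjacency: np.ndarray  # (N, N) 0/1, symmetric, zero diagonal
    window: tuple[float, float]
    structure: CoarseStructure | None = None

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class NetworkDescriptors:
    """Classical per-node PCN descriptors (unnormalized conventions).

    ``betweenness[i]`` counts, over unordered node pairs excluding i,
    the fraction of shortest paths through i. ``closeness[i]`` is the
    reciprocal of the summed shortest-path lengths from i to every
    other node.
    """

    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    characteristic_length: float


@dataclass
class ClusterPartition:
    """Module assignment from recursive spectral bisection."""

    labels: np.ndarray  # (N,) int cluster id, 0-based contiguous
    iterations: int
    fiedler_values: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


@dataclass
class NodeCartography:
    """Per-node participation coefficient, z-score and cartography region."""

    degree: np.ndarray
    intra_degree: np.ndarray  # k_si: links into the node's own cluster
    participation: np.ndarray  # P, NaN where degree = 0
    z_score: np.ndarray
    regions: list[str]  # "R1".."R7", "" where P undefined
    p_form: Literal["standard", "paper"]
    z_statistic: Literal["cluster", "network"]


def build_pcn(
    structure: CoarseStructure, window: tuple[float, float] = (4.0, 8.0)
) -> ContactNetwork:
    """Adjacency with an edge iff lower ≤ d(Cα_i, Cα_j) ≤ upper (closed window)."""
    lo, hi = window
    if not (0 <= lo < hi):
        raise ValueError(f"invalid distance window {window}")
    if len(structure) < 2:
        raise ValueError("PCN needs at least two residues")
    coords = structure.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    adj = ((dist >= lo) & (dist <= hi)).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    if adj.sum() == 0:
        raise ValueError("contact network has no edges for this window")
    return ContactNetwork(adjacency=adj, window=(float(lo), float(hi)), structure=structure)


def descriptors(net: ContactNetwork, largest_component: bool = False) -> NetworkDescriptors:
    """Degree, betweenness, closeness and characteristic length.

    The network must be connected; with ``largest_component=True`` a
    disconnected network is restricted to its largest component and the
    descriptors of excluded nodes are NaN.
    """
    n_comp, comp = csgraph.connected_components(net.adjacency, directed=False)
    mask = np.ones(net.n, dtype=bool)
    if n_comp > 1:
        if not largest_component:
            raise ValueError(
                f"contact network has {n_comp} components; pass largest_component=True "
                "to analyse the largest one"
            )
        keep = np.argmax(np.bincount(comp))
        mask = comp == keep
        logger.warning(
            "restricting descriptors to the largest component: %d of %d nodes",
            int(mask.sum()),
            net.n,
        )
    sub = net.adjacency[np.ix_(mask, mask)]
    g = nx.from_numpy_array(sub)
    m = sub.shape[0]

    betw_sub = nx.betweenness_centrality(g, normalized=False)
    sp = csgraph.shortest_path(sub, unweighted=True, directed=False)
    close_sub = 1.0 / sp.sum(axis=1)
    char_len = float(sp[np.triu_indices(m, k=1)].mean())

    degree = net.degree().astype(float)
    betw = np.full(net.n, np.nan)
    close = np.full(net.n, np.nan)
    idx = np.nonzero(mask)[0]
    betw[idx] = [betw_sub[i] for i in range(m)]
    close[idx] = close_sub
    degree[~mask] = np.nan
    return NetworkDescriptors(
        degree=degree,
        betweenness=betw,
        closeness=close,
        characteristic_length=char_len,
    )


def _fiedler_split(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Sign split of the Fiedler vector of L = D − Ad for one subgraph.

    Returns (boolean side mask, Fiedler value). The eigenvector sign is
    normalized (first nonzero component positive) and exact-zero
    components join the non-negative side, so splits are reproducible.
    """
    deg = adj.sum(axis=1)
    lap = np.diag(deg) - adj
    evals, evecs = scipy.linalg.eigh(lap)
    fiedler_val = float(evals[1])
    v2 = evecs[:, 1]
    nz = np.nonzero(np.abs(v2) > 1e-12)[0]
    if nz.size and v2[nz[0]] < 0:
        v2 = -v2
    side = v2 >= -1e-12  # zeros to the non-negative side
    return side, fiedler_val


def _component_split(adj: np.ndarray) -> np.ndarray:
    """Deterministic two-way split of a disconnected subgraph: the largest
    component (ties: smallest first node) versus the rest."""
    _, comp = csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(comp)
    order = sorted(range(sizes.size), key=lambda c: (-sizes[c], int(np.nonzero(comp == c)[0][0])))
    return comp == order[0]


def spectral_clustering(net: ContactNetwork, iterations: int = 2) -> ClusterPartition:
    """Recursive spectral bisection into at most 2^iterations modules.

    Each round splits every current module by the sign of the Fiedler
    vector (eigenvector of the second-smallest Laplacian eigenvalue) of
    its induced subgraph; a disconnected module splits by connected
    components first. Branches stop below two nodes or when a split
    fails to separate anything.
    """
    if iterations < 1:
        raise ValueError("iterations must be ≥ 1")
    groups: list[np.ndarray] = [np.arange(net.n)]
    fiedler_values: list[float] = []
    for _ in range(iterations):
        next_groups: list[np.ndarray] = []
        for nodes in groups:
            if nodes.size < 2:
                next_groups.append(nodes)
                continue
            sub = net.adjacency[np.ix_(nodes, nodes)].astype(float)
            n_comp, _ = csgraph.connected_components(sub, directed=False)
            if n_comp > 1:
                side = _component_split(sub)
                fiedler_values.append(0.0)
            else:
                side, fval = _fiedler_split(sub)
                fiedler_values.append(fval)
            if side.all() or not side.any():
                next_groups.append(nodes)
                continue
            next_groups.append(nodes[side])
            next_groups.append(nodes[~side])
        groups = next_groups
    labels = np.empty(net.n, dtype=int)
    # deterministic cluster ids: order groups by their smallest node index
    for cid, nodes in enumerate(sorted(groups, key=lambda g: int(g[0]))):
        labels[nodes] = cid
    return ClusterPartition(labels=labels, iterations=iterations, fiedler_values=fiedler_values)


def classify_region(p: float, z: float) -> str:
    """Guimerà–Amaral region from (P, z).

    Hubs (z > 2.5): R5 P < 0.3, R6 0.3 ≤ P < 0.75, R7 P ≥ 0.75.
    Non-hubs: R1 P < 0.05, R2 0.05 ≤ P < 0.625, R3 0.625 ≤ P < 0.8,
    R4 P ≥ 0.8 (nonhub kinless nodes, the allosteric-communicator class).
    """
    if np.isnan(p):
        return ""
    if z > HUB_Z:
        if p < 0.3:
            return "R5"
        if p < 0.75:
            return "R6"
        return "R7"
    if p < 0.05:
        return "R1"
    if p < 0.625:
        return "R2"
    if p < 0.8:
        return "R3"
    return "R4"


def cartography(
    net: ContactNetwork,
    partition: ClusterPartition,
    p_form: Literal["standard", "paper"] = "standard",
    z_statistic: Literal["cluster", "network"] = "cluster",
) -> NodeCartography:
    """Participation coefficient, intramodule z-score and R1–R7 regions.

    ``p_form='standard'`` uses the multi-module Guimerà sum
    P_i = 1 − Σ_s (k_si/k_i)²; ``'paper'`` keeps only the own-module
    term P_i = 1 − (k_si/k_i)². ``z_statistic='cluster'`` standardizes
    k_si against the intra-module degrees of the node's own cluster
    (population SD); ``'network'`` standardizes against all nodes.
    Nodes with k_i = 0 get NaN P and no region; an all-equal cluster
    (SD = 0) gets z = 0 with a warning.
    """
    if partition.labels.shape[0] != net.n:
        raise ValueError("partition does not cover the network")
    adj = net.adjacency
    k = adj.sum(axis=1).astype(float)
    n_clusters = partition.n_clusters
    # k_is: links from node i into cluster s
    membership = np.zeros((net.n, n_clusters))
    membership[np.arange(net.n), partition.labels] = 1.0
    k_is = adj @ membership  # (N, n_clusters)
    k_si = k_is[np.arange(net.n), partition.labels]

    with np.errstate(invalid="ignore", divide="ignore"):
        if p_form == "standard":
            p = 1.0 - ((k_is / k[:, None]) ** 2).sum(axis=1)
        elif p_form == "paper":
            p = 1.0 - (k_si / k) ** 2
        else:
            raise ValueError(f"unknown p_form {p_form!r}")
    p = np.where(k > 0, p, np.nan)

    z = np.zeros(net.n)
    if z_statistic == "cluster":
        for s in range(n_clusters):
            members = partition.members(s)
            mean = k_si[members].mean()
            sd = k_si[members].std()  # population SD
            if sd == 0:
                logger.warning("cluster %d has zero intra-degree SD; z set to 0", s)
                z[members] = 0.0
            else:
                z[members] = (k_si[members] - mean) / sd
    elif z_statistic == "network":
        mean = k_si.mean()
        sd = k_si.std()
        if sd == 0:
            logger.warning("network-wide intra-degree SD is zero; z set to 0")
        else:
            z = (k_si - mean) / sd
    else:
        raise ValueError(f"unknown z_statistic {z_statistic!r}")

    regions = [classify_region(float(pi), float(zi)) for pi, zi in zip(p, z)]
    return NodeCartography(
        degree=k.astype(int),
        intra_degree=k_si.astype(int),
        participation=p,
        z_score=z,
        regions=regions,
        p_form=p_form,
        z_statistic=z_statistic,
    )
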