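"""Markov model of signal propagation through residue contacts.

A random walk on the residue graph models how a perturbation diffuses
through a protein complex. The edge weights come from an affinity
matrix a_ij = N_ij/(N_i N_j): the number of heavy-atom contacts between
two residues within 4 Å, normalized by the residues' side-chain atom
counts. Hitting times H(i, j) — expected steps for a signal released at
residue j to first reach residue i — follow in closed form from the
Moore–Penrose pseudoinverse of the graph Laplacian, and the commute
time C(i, j) = H(i, j) + H(j, i) is the round trip. Residues at local
minima of the average commute time ⟨C(i)⟩ communicate fastest with the
rest of the complex and mark candidate allosteric sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .structures import CoarseStructure

__all__ = [
    "AffinityMatrix",
    "TransitionMatrix",
    "CommuteTimeMap",
    "DisconnectedGraphError",
    "affinity_matrix",
    "transition_matrix",
    "hitting_times",
    "allosteric_minima",
]


class DisconnectedGraphError(ValueError):
    """The contact graph is disconnected; hitting times are undefined."""


@dataclass
class AffinityMatrix:
    """Symmetric non-negative residue affinity a_ij with zero diagonal,
    and the per-residue contact density d_i = Σ_j a_ij."""

    a: np.ndarray
    atom_cutoff: float
    normalization: Literal["paper", "sqrt"]

    @property
    def d(self) -> np.ndarray:
        return self.a.sum(axis=1)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian diag(d) − a of the affinity graph."""
        return np.diag(self.d) - self.a


@dataclass
class TransitionMatrix:
    """Column-stochastic Markov matrix m_ij = a_ij / d_j: the probability
    that a signal at residue j moves to residue i in one step."""

    m: np.ndarray
    d: np.ndarray

    @property
    def n(self) -> int:
        return self.m.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution d/Σd of the contact random walk."""
        return self.d / self.d.sum()


@dataclass
class CommuteTimeMap:
    """Pairwise hitting/commute times in units of random-walk steps.

    ``hitting[i, j]`` is the expected number of steps for a walk started
    at j to first reach i; ``commute`` is its symmetrization.
    """

    hitting: np.ndarray
    laplacian_source: Literal["affinity", "gnm-kirchhoff"]

    @property
    def commute(self) -> np.ndarray:
        return self.hitting + self.hitting.T

    @property
    def average_commute(self) -> np.ndarray:
        """⟨C(i)⟩: row mean of the commute matrix excluding the diagonal."""
        c = self.commute
        n = c.shape[0]
        return (c.sum(axis=1) - np.diag(c)) / (n - 1)


def count_atom_contacts(
    structure: CoarseStructure,
    atom_cutoff: float = 4.0,
    sidechain_only: bool = False,
) -> np.ndarray:
    """N_ij: number of heavy-atom pairs (one atom from each residue) within
    ``atom_cutoff`` Å, for every residue pair. Diagonal is zero."""
    n = len(structure)
    coords_list = []
    owner = []
    for i in range(n):
        coords = structure.atom_coords[i]
        if sidechain_only:
            keep = [
                k
                for k, nm in enumerate(structure.atom_names[i])
                if nm not in {"N", "CA", "C", "O", "OXT"}
            ]
            coords = coords[keep] if keep else np.empty((0, 3))
        if coords.shape[0]:
            coords_list.append(coords)
            owner.extend([i] * coords.shape[0])
    if not coords_list:
        raise ValueError("structure has no heavy atoms")
    allc = np.vstack(coords_list)
    owner = np.asarray(owner)
    tree = cKDTree(allc)
    nij = np.zeros((n, n), dtype=int)
    for p, q in tree.query_pairs(r=atom_cutoff):
        i, j = owner[p], owner[q]
        if i != j:
            nij[i, j] += 1
            nij[j, i] += 1
    return nij


def affinity_matrix(
    structure: CoarseStructure,
    atom_cutoff: float = 4.0,
    normalization: Literal["paper", "sqrt"] = "paper",
    sidechain_only: bool = False,
) -> AffinityMatrix:
    """Residue affinity a_ij = N_ij/(N_i N_j) (default) or N_ij/√(N_i N_j).

    N_i is the residue's side-chain heavy-atom count, guarded to a
    minimum of 1 so glycine (no side-chain heavy atoms) still has
    finite affinities.
    """
    nij = count_atom_contacts(structure, atom_cutoff, sidechain_only=sidechain_only)
    if nij.sum() == 0:
        raise DisconnectedGraphError("no atom-atom contacts anywhere in the structure")
    ni = np.maximum(structure.sidechain_counts, 1).astype(float)
    if normalization == "paper":
        denom = np.outer(ni, ni)
    elif normalization == "sqrt":
        denom = np.sqrt(np.outer(ni, ni))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    a = nij / denom
    np.fill_diagonal(a, 0.0)
    return AffinityMatrix(a=a, atom_cutoff=atom_cutoff, normalization=normalization)


def transition_matrix(aff: AffinityMatrix) -> TransitionMatrix:
    """Column-stochastic m_ij = a_ij / d_j."""
    d = aff.d
    if np.any(d <= 0):
        bad = int(np.argmin(d))
        raise DisconnectedGraphError(
            f"residue at position {bad} (0-based) has zero contact density"
        )
    return TransitionMatrix(m=aff.a / d[None, :], d=d)


def _check_connected(laplacian: np.ndarray) -> None:
    evals = scipy.linalg.eigvalsh(laplacian)
    if evals[-1] <= 0 or np.sum(evals < 1e-10 * evals[-1]) != 1:
        raise DisconnectedGraphError(
            "affinity graph is disconnected: hitting times are undefined"
        )


def hitting_times(
    aff: AffinityMatrix,
    laplacian: np.ndarray | None = None,
    laplacian_source: Literal["affinity", "gnm-kirchhoff"] = "affinity",
) -> CommuteTimeMap:
    """Closed-form hitting times of the contact random walk.

    H(i, j) = Σ_k [Γ⁺_kj − Γ⁺_ij − Γ⁺_ki + Γ⁺_ii] d_k, with Γ⁺ the
    Moore–Penrose pseudoinverse of the chosen Laplacian. The default —
    the Laplacian diag(d) − a of the affinity graph itself — is the
    choice consistent with the transition matrix m_ij = a_ij/d_j (it
    reproduces Monte-Carlo first-passage times); passing the GNM
    Kirchhoff matrix instead is supported for comparison.
    """
    if laplacian is None:
        lap = aff.laplacian()
        laplacian_source = "affinity"
    else:
        lap = np.asarray(laplacian, float)
        if lap.shape != aff.a.shape:
            raise ValueError("laplacian shape does not match the affinity matrix")
    _check_connected(lap)
    g = scipy.linalg.pinvh(lap)
    d = aff.d
    s = g @ d  # s_i = Σ_k Γ⁺_ik d_k
    total = float(d.sum())
    gii = np.diag(g)
    # H[i, j] = s_j − total·g[i, j] − s_i + total·g[i, i]
    hit = s[None, :] - total * g - s[:, None] + total * gii[:, None]
    np.fill_diagonal(hit, 0.0)
    return CommuteTimeMap(hitting=hit, laplacian_source=laplacian_source)


def allosteric_minima(
    cmap: CommuteTimeMap,
    structure: CoarseStructure,
    window: int = 5,
) -> list[int]:
    """Candidate allosteric residues: strict local minima of ⟨C(i)⟩.

    Minima are detected per chain with a sliding window (default 5
    residues): position i qualifies if ⟨C(i)⟩ is strictly below every
    other value within ``window`` positions on the same chain (ties
    resolve to the lower index). Returned 0-based positions are ranked
    ascending by ⟨C(i)⟩, fastest communicators first.
    """
    avg = cmap.average_commute
    if avg.shape[0] != len(structure):
        raise ValueError("commute map size does not match the structure")
    half = window // 2
    minima: list[int] = []
    for sl in structure.chain_slices().values():
        vals = avg[sl]
        m = vals.shape[0]
        for i in range(m):
            lo, hi = max(0, i - half), min(m, i + half + 1)
            neighbourhood = vals[lo:hi]
            best = neighbourhood.min()
            if vals[i] > best:
                continue
            # strict minimum; ties go to the lowest index in the window
            if vals[i] == best and int(np.argmin(neighbourhood)) + lo != i:
                continue
            minima.append(sl.start + i)
    minima.sort(key=lambda i: (avg[i], i))
    return minima
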