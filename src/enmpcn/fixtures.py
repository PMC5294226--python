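"""Synthetic coarse-grained structures and stochastic oracles.

Everything here is deterministic given its arguments (and seed), so the
numerical machinery of the package — Kirchhoff/Hessian construction,
contact counting, random-walk hitting times, spectral clustering — can
be exercised and cross-checked without any real protein structure.

The toy tetramer emulates the architecture the analyses are aimed at: a
dimer-of-dimers complex of four helical chains (two longer "α"-like,
two shorter "β"-like) with an exact two-fold symmetry axis, so
symmetry-based assertions (mirror-equal fluctuation profiles, paired
allosteric minima, 2×2 block structure of slow-mode correlations) are
valid to machine precision. Synthetic side chains are 0–3 pseudo-atoms
per residue at fixed offsets, including glycine-like residues with no
side-chain heavy atoms, so atom-contact affinity machinery sees the
degenerate case it must guard against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .markov import TransitionMatrix
from .structures import CoarseStructure, ResidueKey

__all__ = [
    "ToyStructureSpec",
    "make_structure",
    "linear_chain",
    "helix_chain",
    "ring_chain",
    "toy_tetramer",
    "make_two_state_pair",
    "random_walk_hitting_oracle",
]

# residue-name cycle fixing the synthetic side-chain size: GLY has none
_SIDECHAIN_CYCLE = [("ALA", 1), ("GLY", 0), ("SER", 2), ("LEU", 3)]


@dataclass(frozen=True)
class ToyStructureSpec:
    """Declarative recipe for a synthetic structure."""

    kind: Literal["linear", "helix", "ring", "tetramer"] = "linear"
    n_residues: int = 10  # per chain
    spacing: float = 3.8  # Å between consecutive Cα (linear/ring)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least two residues per chain")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _assemble(
    chain_coords: dict[str, np.ndarray], start_resnum: int = 1
) -> CoarseStructure:
    """Build a CoarseStructure from per-chain Cα coordinates, attaching
    deterministic pseudo side-chain atoms."""
    residues: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    atom_names: list[list[str]] = []
    atom_coords: list[np.ndarray] = []
    side_names = ["CB", "CG", "CD"]
    for chain, ca in chain_coords.items():
        n = ca.shape[0]
        for i in range(n):
            resname, n_side = _SIDECHAIN_CYCLE[i % len(_SIDECHAIN_CYCLE)]
            residues.append(ResidueKey(chain, start_resnum + i, " ", resname))
            coords.append(ca[i])
            names = ["CA"]
            xyz = [ca[i]]
            # fixed offsets: radially away from the chain's local direction
            if n_side:
                axis = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
                axis = axis / (np.linalg.norm(axis) or 1.0)
                # any deterministic vector not parallel to axis
                ref = np.array([0.0, 0.0, 1.0])
                if abs(axis @ ref) > 0.9:
                    ref = np.array([1.0, 0.0, 0.0])
                perp = np.cross(axis, ref)
                perp /= np.linalg.norm(perp)
                perp2 = np.cross(axis, perp)
                for s in range(n_side):
                    offset = (1.2 + 0.9 * s) * perp + 0.4 * s * perp2
                    names.append(side_names[s])
                    xyz.append(ca[i] + offset)
            atom_names.append(names)
            atom_coords.append(np.array(xyz))
    return CoarseStructure(
        residues=residues,
        coords=np.array(coords),
        atom_names=atom_names,
        atom_coords=atom_coords,
        name="toy",
    )


def linear_chain(n: int = 10, spacing: float = 3.8, chain: str = "A") -> CoarseStructure:
    """Collinear Cα chain along x: with a 7 Å cutoff its Kirchhoff matrix
    is the path-graph Laplacian (for spacing in (3.5, 7])."""
    ca = np.zeros((n, 3))
    ca[:, 0] = spacing * np.arange(n)
    return _assemble({chain: ca})


def helix_chain(
    n: int = 12,
    chain: str = "A",
    radius: float = 2.3,
    rise: float = 1.5,
    turn_deg: float = 100.0,
    origin: np.ndarray | None = None,
) -> CoarseStructure:
    """Ideal α-helical Cα trace (radius 2.3 Å, rise 1.5 Å, 100°/residue)."""
    t = np.deg2rad(turn_deg) * np.arange(n)
    ca = np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])
    if origin is not None:
        ca = ca + np.asarray(origin, float)
    return _assemble({chain: ca})


def ring_chain(n: int = 12, spacing: float = 3.8, chain: str = "A") -> CoarseStructure:
    """Cα on a regular n-gon with the given edge length: every node is
    symmetry-equivalent, so fluctuation profiles must be flat."""
    radius = spacing / (2 * np.sin(np.pi / n))
    t = 2 * np.pi * np.arange(n) / n
    ca = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
    return _assemble({chain: ca})


def _helix_coords(n: int, radius: float = 2.3, rise: float = 1.5, turn_deg: float = 100.0) -> np.ndarray:
    t = np.deg2rad(turn_deg) * np.arange(n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def toy_tetramer(n_alpha: int = 14, n_beta: int = 12) -> CoarseStructure:
    """Four-helix dimer-of-dimers with exact two-fold symmetry.

    Chains A ("α1") and B ("β1") form one dimer; C and D are their exact
    images under a 180° rotation about the z axis, so the permutation
    A↔C, B↔D maps the coordinate set onto itself. The four helix axes
    sit at the corners of a square around z with inter-chain Cα
    distances in the contact range of both network models.
    """
    base_a = _helix_coords(n_alpha)
    base_b = _helix_coords(n_beta)
    # tight intra-dimer packing (2·dy) and a looser inter-dimer interface
    # (2·dx), so the counter-torsion of the dimers is a soft direction
    dx, dy = 5.2, 3.0
    a = base_a + np.array([dx, dy, 0.0])
    b = base_b @ _rot_z(90.0).T + np.array([dx, -dy, 0.5])
    rot = np.diag([-1.0, -1.0, 1.0])  # exact 180° about z: symmetry holds to the bit
    c = a @ rot.T
    d = b @ rot.T
    return _assemble({"A": a, "B": b, "C": c, "D": d})


def make_structure(spec: ToyStructureSpec) -> CoarseStructure:
    """Dispatch on the spec kind; same spec → identical coordinates."""
    if spec.kind == "linear":
        return linear_chain(spec.n_residues, spec.spacing)
    if spec.kind == "helix":
        return helix_chain(spec.n_residues)
    if spec.kind == "ring":
        return ring_chain(spec.n_residues, spec.spacing)
    if spec.kind == "tetramer":
        return toy_tetramer(n_alpha=spec.n_residues, n_beta=max(2, spec.n_residues - 2))
    raise ValueError(f"unknown structure kind {spec.kind!r}")


def make_two_state_pair(
    n_alpha: int = 14,
    n_beta: int = 12,
    angle_deg: float = 5.0,
) -> tuple[CoarseStructure, CoarseStructure]:
    """Two conformations of the toy tetramer differing by a rigid
    counter-rotation of the two dimers about the symmetry axis.

    The AB dimer rotates by +angle/2 and the CD dimer by −angle/2 about
    z, emulating the torsional quaternary transition of a
    dimer-of-dimers complex. For angle 0 the two states coincide.
    """
    state1 = toy_tetramer(n_alpha=n_alpha, n_beta=n_beta)
    slices = state1.chain_slices()
    rot_ab = _rot_z(angle_deg / 2.0)
    rot_cd = _rot_z(-angle_deg / 2.0)
    coords = state1.coords.copy()
    atom_coords = [a.copy() for a in state1.atom_coords]
    for chain, rot in (("A", rot_ab), ("B", rot_ab), ("C", rot_cd), ("D", rot_cd)):
        sl = slices[chain]
        coords[sl] = coords[sl] @ rot.T
        for i in range(sl.start, sl.stop):
            atom_coords[i] = atom_coords[i] @ rot.T
    state2 = CoarseStructure(
        residues=list(state1.residues),
        coords=coords,
        atom_names=[list(a) for a in state1.atom_names],
        atom_coords=atom_coords,
        name="toy-rotated",
    )
    return state1, state2


def random_walk_hitting_oracle(
    transition: TransitionMatrix,
    source: int,
    target: int,
    n_walks: int = 100_000,
    seed: int = 0,
    max_steps: int = 1_000_000,
) -> tuple[float, float]:
    """Monte-Carlo mean first-passage time from ``source`` to ``target``.

    Simulates ``n_walks`` independent walks of the column-stochastic
    chain (a walk at j moves to i with probability m[i, j]) and returns
    (mean steps, standard error). Serves as the independent stochastic
    oracle for the closed-form hitting times. Raises if any walk
    exceeds ``max_steps`` (disconnection suspicion).
    """
    m = transition.m
    n = m.shape[0]
    if not (0 <= source < n and 0 <= target < n):
        raise IndexError("source/target out of range")
    if source == target:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    # cumulative transition distribution per current state (column)
    cum = np.cumsum(m, axis=0)
    cum[-1, :] = 1.0  # guard rounding
    state = np.full(n_walks, source, dtype=np.int64)
    steps = np.zeros(n_walks, dtype=np.int64)
    active = np.arange(n_walks)
    total = 0
    while active.size:
        total += 1
        if total > max_steps:
            raise RuntimeError("random-walk step cap exceeded; graph may be disconnected")
        u = rng.random(active.size)
        cur = state[active]
        # vectorized categorical draw: for each active walk, first row where cum >= u
        nxt = (cum[:, cur] < u[None, :]).sum(axis=0)
        state[active] = nxt
        arrived = nxt == target
        steps[active[arrived]] = total
        active = active[~arrived]
    mean = float(steps.mean())
    sem = float(steps.std(ddof=1) / np.sqrt(n_walks))
    return mean, sem
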