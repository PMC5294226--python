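"""Elastic network models: GNM and ANM normal-mode analysis.

The Gaussian network model (GNM) connects Cα atoms within a cutoff
(7 Å by default) by springs of uniform force constant γ and works with
the N×N Kirchhoff (graph Laplacian) matrix; it predicts isotropic
fluctuation amplitudes and residue cross-correlations. The anisotropic
network model (ANM) uses a 13 Å cutoff and the 3N×3N Hessian of the
pairwise harmonic potential, giving fluctuation directions as well, at
the cost of six rigid-body zero modes instead of one.

Mode numbering is the field's usual one: "mode 1" is the slowest
non-rigid mode (smallest nonzero eigenvalue); "highest" modes are the
largest-eigenvalue ones used for hot-spot prediction. All mode indices
in this module's public API are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .structures import CoarseStructure, DeformationVector

__all__ = [
    "ElasticParams",
    "KirchhoffMatrix",
    "HessianMatrix",
    "ModeSet",
    "OverlapResult",
    "DegenerateStructureError",
    "build_kirchhoff",
    "build_hessian",
    "decompose",
    "square_fluctuations",
    "cross_correlation",
    "mode_shape",
    "hinge_sites",
    "mode_overlap",
    "overlap_matrix",
    "deformation_overlaps",
    "hotspots",
]


class DegenerateStructureError(ValueError):
    """Disconnected or geometrically degenerate network (wrong zero-mode count)."""


@dataclass(frozen=True)
class ElasticParams:
    """Spring and cutoff parameters shared by GNM and ANM.

    ``gamma`` and ``kT`` only set an overall scale; fluctuation profiles
    are reported in relative units (3kT/γ = 1 for GNM) unless the caller
    rescales. ``zero_tol`` is the relative eigenvalue threshold below
    which a mode is treated as a rigid-body zero mode.
    """

    gamma: float = 1.0
    kT: float = 1.0
    gnm_cutoff: float = 7.0
    anm_cutoff: float = 13.0
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.gnm_cutoff <= 0 or self.anm_cutoff <= 0:
            raise ValueError("gamma and cutoffs must be positive")
        if not (0 < self.zero_tol <= 1e-4):
            raise ValueError("zero_tol must be in (0, 1e-4]")


@dataclass
class KirchhoffMatrix:
    """GNM Kirchhoff (contact Laplacian) matrix: −1 off-diagonal for Cα
    pairs within the cutoff, row sums zero."""

    matrix: np.ndarray
    cutoff: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HessianMatrix:
    """ANM Hessian built from 3×3 super-elements −γ R̂ R̂ᵀ per contact."""

    matrix: np.ndarray  # (3N, 3N)
    cutoff: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ModeSet:
    """Nonzero normal modes of a Kirchhoff or Hessian matrix.

    ``eigenvalues`` are ascending and exclude the ``n_zero`` rigid-body
    modes; column ``k-1`` of ``eigenvectors`` is mode ``k`` (1-based,
    slowest first).
    """

    kind: Literal["GNM", "ANM"]
    eigenvalues: np.ndarray  # (n_modes,) ascending, nonzero only
    eigenvectors: np.ndarray  # (dim, n_modes), orthonormal columns
    n_zero: int
    n_residues: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector of mode ``k`` (1-based, 1 = slowest nonzero)."""
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode {k} out of range 1..{self.n_modes}")
        return self.eigenvectors[:, k - 1]

    def _resolve(self, mode_indices: Sequence[int] | None) -> np.ndarray:
        if mode_indices is None:
            return np.arange(self.n_modes)
        idx = np.asarray(list(mode_indices), dtype=int) - 1
        if idx.size == 0:
            raise ValueError("empty mode subset")
        if np.any(idx < 0) or np.any(idx >= self.n_modes):
            raise IndexError(f"mode indices must lie in 1..{self.n_modes}")
        return idx


@dataclass
class OverlapResult:
    """Per-mode overlaps of a deformation with ANM modes and the cumulative
    overlap CO(m) = sqrt(Σ_{k≤m} overlap_k²)."""

    overlaps: np.ndarray  # (n_modes,) absolute per-mode overlaps
    cumulative: np.ndarray  # (n_modes,) CO(m)
    best_mode: int  # 1-based mode with the largest overlap

    def cumulative_unrooted(self) -> np.ndarray:
        """Summed squared overlaps without the square root (alternative convention)."""
        return np.cumsum(self.overlaps**2)


def _pairwise_contacts(coords: np.ndarray, cutoff: float) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    contact = dist <= cutoff  # inclusive rule
    np.fill_diagonal(contact, False)
    return contact


def build_kirchhoff(
    structure: CoarseStructure, params: ElasticParams = ElasticParams()
) -> KirchhoffMatrix:
    """Γ_ij = −1 for Cα pairs within ``gnm_cutoff`` (inclusive), diagonal =
    contact degree; a Laplacian with row sums exactly zero."""
    if len(structure) < 2:
        raise ValueError("GNM needs at least two residues")
    contact = _pairwise_contacts(structure.coords, params.gnm_cutoff)
    gamma_mat = -contact.astype(float)
    np.fill_diagonal(gamma_mat, contact.sum(axis=1))
    return KirchhoffMatrix(matrix=gamma_mat, cutoff=params.gnm_cutoff)


def build_hessian(
    structure: CoarseStructure, params: ElasticParams = ElasticParams()
) -> HessianMatrix:
    """ANM Hessian: off-diagonal 3×3 block −γ (R⃗_ij R⃗_ijᵀ)/R_ij² for contacts
    within ``anm_cutoff``; diagonal blocks make each block row sum to zero."""
    n = len(structure)
    if n < 2:
        raise ValueError("ANM needs at least two residues")
    coords = structure.coords
    contact = _pairwise_contacts(coords, params.anm_cutoff)
    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in np.nonzero(contact[i])[0]:
            if j <= i:
                continue
            rij = coords[j] - coords[i]
            d2 = float(rij @ rij)
            block = -params.gamma * np.outer(rij, rij) / d2
            hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return HessianMatrix(matrix=hessian, cutoff=params.anm_cutoff)


def decompose(
    matrix: KirchhoffMatrix | HessianMatrix,
    params: ElasticParams = ElasticParams(),
) -> ModeSet:
    """Full eigendecomposition with zero-mode bookkeeping.

    Eigenvalues below ``zero_tol × λ_max`` are rigid-body modes and are
    excluded from every mode-indexed quantity. A connected GNM must have
    exactly one zero mode and a non-degenerate 3-D ANM exactly six;
    any other count raises :class:`DegenerateStructureError`.
    """
    if isinstance(matrix, KirchhoffMatrix):
        kind: Literal["GNM", "ANM"] = "GNM"
        expected_zero = 1
        n_res = matrix.n
    elif isinstance(matrix, HessianMatrix):
        kind = "ANM"
        expected_zero = 6
        n_res = matrix.n
    else:
        raise TypeError(f"cannot decompose {type(matrix).__name__}")
    mat = matrix.matrix
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    evals, evecs = scipy.linalg.eigh(mat)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise DegenerateStructureError("matrix has no positive eigenvalues")
    n_zero = int(np.sum(evals < params.zero_tol * lam_max))
    if n_zero != expected_zero:
        raise DegenerateStructureError(
            f"{kind} network has {n_zero} zero modes, expected {expected_zero} "
            f"({'disconnected network' if n_zero > expected_zero else 'over-constrained'})"
        )
    return ModeSet(
        kind=kind,
        eigenvalues=evals[n_zero:],
        eigenvectors=evecs[:, n_zero:],
        n_zero=n_zero,
        n_residues=n_res,
    )


def square_fluctuations(
    modes: ModeSet,
    mode_indices: Sequence[int] | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-residue square fluctuations from the selected modes.

    GNM: ⟨ΔR_i²⟩ = scale · Σ_k λ_k⁻¹ u_k[i]², with scale ≡ 3kT/γ.
    ANM: the three Cartesian components of each residue are summed and
    scale ≡ kT/γ. The default scale of 1 reports relative units; over
    all modes the GNM profile equals the Kirchhoff pseudoinverse diagonal.
    """
    idx = modes._resolve(mode_indices)
    inv_lam = 1.0 / modes.eigenvalues[idx]
    contrib = (modes.eigenvectors[:, idx] ** 2) @ inv_lam
    if modes.kind == "ANM":
        contrib = contrib.reshape(modes.n_residues, 3).sum(axis=1)
    return scale * contrib


def cross_correlation(
    modes: ModeSet, mode_indices: Sequence[int] | None = None
) -> np.ndarray:
    """Normalized GNM cross-correlation map C_ij over the selected modes.

    C_ij = ⟨ΔR_i·ΔR_j⟩ / sqrt(⟨ΔR_i²⟩⟨ΔR_j²⟩) from the mode partial sums;
    the diagonal is exactly 1. If a residue has zero partial fluctuation
    in the subset its entries are NaN (undefined), not zero.
    """
    if modes.kind != "GNM":
        raise ValueError("cross-correlation is defined for GNM mode sets")
    idx = modes._resolve(mode_indices)
    u = modes.eigenvectors[:, idx]
    cov = (u / modes.eigenvalues[idx]) @ u.T
    var = np.diag(cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(np.outer(var, var))
    corr[var <= 0, :] = np.nan
    corr[:, var <= 0] = np.nan
    ok = np.nonzero(var > 0)[0]
    corr[ok, ok] = 1.0  # exact, not up to rounding
    return corr


def mode_shape(modes: ModeSet, k: int) -> np.ndarray:
    """Signed per-residue shape of GNM mode ``k`` (its eigenvector)."""
    if modes.kind != "GNM":
        raise ValueError("mode shapes are per-residue GNM eigenvectors")
    return modes.mode(k)


def hinge_sites(
    structure: CoarseStructure,
    shape: np.ndarray,
    zero_band: float = 0.05,
) -> list[int]:
    """Hinge residues of a slow-mode shape: near-zero positions.

    A residue is a hinge if |u_i| < zero_band · max|u|, or if the shape
    changes sign between chain neighbours (the smaller-amplitude residue
    of the crossing pair is reported). Returns 0-based residue positions.
    """
    shape = np.asarray(shape, float)
    if shape.shape[0] != len(structure):
        raise ValueError("shape length must equal the residue count")
    amax = float(np.max(np.abs(shape)))
    if amax == 0:
        return []
    hinges: set[int] = set(np.nonzero(np.abs(shape) < zero_band * amax)[0].tolist())
    for i in range(len(structure) - 1):
        if structure.residues[i].chain != structure.residues[i + 1].chain:
            continue
        if shape[i] * shape[i + 1] < 0:
            hinges.add(i if abs(shape[i]) <= abs(shape[i + 1]) else i + 1)
    return sorted(hinges)


def mode_overlap(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute normalized inner product |û·v̂| of two mode vectors.

    Eigenvector sign is arbitrary, so the absolute value is reported.
    """
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def overlap_matrix(a: ModeSet, b: ModeSet, m: int) -> np.ndarray:
    """m×m matrix of |u_k·v_l| over the first m nonzero modes of each set."""
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError(
            "mode sets have different dimensionality; reduce both structures "
            "to their matched residues first"
        )
    m = min(m, a.n_modes, b.n_modes)
    return np.abs(a.eigenvectors[:, :m].T @ b.eigenvectors[:, :m])


def deformation_overlaps(modes: ModeSet, delta: DeformationVector | np.ndarray) -> OverlapResult:
    """Overlap of each ANM mode with an observed deformation Δr.

    Per-mode overlap |Δr·u_k|/|Δr|; the cumulative overlap
    CO(m) = sqrt(Σ_{k≤m} (Δr·u_k/|Δr|)²) reaches 1 over the complete
    nonzero basis.
    """
    dr = delta.delta_r if isinstance(delta, DeformationVector) else np.asarray(delta, float).ravel()
    if dr.shape[0] != modes.eigenvectors.shape[0]:
        raise ValueError(
            f"deformation has dimension {dr.shape[0]}, modes have "
            f"{modes.eigenvectors.shape[0]}; compute modes on the matched substructure"
        )
    norm = np.linalg.norm(dr)
    if norm == 0:
        raise ValueError("zero deformation: overlaps undefined")
    ov = np.abs(modes.eigenvectors.T @ dr) / norm
    co = np.sqrt(np.cumsum(ov**2))
    return OverlapResult(overlaps=ov, cumulative=co, best_mode=int(np.argmax(ov)) + 1)


def hotspots(
    structure: CoarseStructure,
    modes: ModeSet,
    n_high: int = 2,
    threshold_sd: float = 2.0,
) -> tuple[list[int], np.ndarray]:
    """Hot-spot residues from the highest-frequency modes.

    The square-fluctuation profile of the ``n_high`` largest-eigenvalue
    modes concentrates on tightly packed interface residues; hot spots
    are local maxima of that profile (within a chain) exceeding
    mean + ``threshold_sd``·SD. Returns (0-based positions, profile).
    """
    if n_high < 1:
        raise ValueError("n_high must be ≥ 1")
    high = list(range(modes.n_modes - n_high + 1, modes.n_modes + 1))
    profile = square_fluctuations(modes, mode_indices=high)
    thresh = profile.mean() + threshold_sd * profile.std()
    peaks: list[int] = []
    n = len(profile)
    for i in range(n):
        if profile[i] <= thresh:
            continue
        left_ok = (
            i == 0
            or structure.residues[i - 1].chain != structure.residues[i].chain
            or profile[i] > profile[i - 1]
        )
        right_ok = (
            i == n - 1
            or structure.residues[i + 1].chain != structure.residues[i].chain
            or profile[i] > profile[i + 1]
        )
        if left_ok and right_ok:
            peaks.append(i)
    return peaks, profile


def matched_mode_sets(
    a_struct: CoarseStructure,
    b_struct: CoarseStructure,
    kind: Literal["GNM", "ANM"] = "ANM",
    params: ElasticParams = ElasticParams(),
) -> tuple[ModeSet, ModeSet, list[tuple[int, int]]]:
    """Recompute two mode sets on the matched-residue intersection so that
    cross-structure overlaps are dimensionally consistent."""
    from .structures import match_residues

    matched = match_residues(a_struct, b_struct)
    sub_a = a_struct.subset([i for i, _ in matched])
    sub_b = b_struct.subset([j for _, j in matched])
    if kind == "ANM":
        ma = decompose(build_hessian(sub_a, params), params)
        mb = decompose(build_hessian(sub_b, params), params)
    else:
        ma = decompose(build_kirchhoff(sub_a, params), params)
        mb = decompose(build_kirchhoff(sub_b, params), params)
    return ma, mb, matched
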