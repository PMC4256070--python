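"""Gaussian and anisotropic elastic network models.

The Gaussian network model (GNM) reduces a structure to Cα nodes joined by
uniform springs within a distance cutoff (default 10 Å) and works with the
N×N Kirchhoff (graph Laplacian) matrix.  The anisotropic network model
(ANM) uses the 3N×3N Hessian of the harmonic pair potential (default
cutoff 15 Å).  Cross-correlations between residue fluctuations come from
the non-zero part of the spectrum:

* GNM:  <ΔRi·ΔRj> = 3 (kBT/γ) Σ_k λk⁻¹ [u_k u_kᵀ]_ij
* ANM:  <ΔRi·ΔRj> = (kBT/γ) Σ_k λk⁻¹ u_k[i]·u_k[j]

with kBT/γ = 1 Å² by default.  Mode numbering follows the convention that
"mode 1" is the slowest non-zero mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import NetworkError
from .structures import CoarseStructure, compute_contact_map

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetwork",
    "SpectralDecomposition",
    "build_kirchhoff",
    "build_hessian",
    "decompose",
    "gnm_correlation",
    "anm_correlation",
    "normalized_cross_correlation",
    "mode_contribution",
    "mode_shape",
    "degenerate_groups",
]

DEFAULT_GNM_CUTOFF = 10.0
DEFAULT_ANM_CUTOFF = 15.0
DEFAULT_KT_OVER_GAMMA = 1.0  # Å²


@dataclass
class ElasticNetwork:
    """Connectivity matrix of a GNM (Kirchhoff) or ANM (Hessian) network."""

    kind: str  # "GNM" | "ANM"
    matrix: np.ndarray
    cutoff: float
    kt_over_gamma: float
    n_nodes: int
    connected: bool
    structure: CoarseStructure | None = None


@dataclass
class SpectralDecomposition:
    """Eigen-decomposition with zero-mode bookkeeping.

    ``eigenvalues`` are ascending; column ``k`` of ``eigenvectors`` matches
    ``eigenvalues[k]``.  The first ``zero_mode_count`` modes are flagged as
    zero modes; paper-style mode 1 is ``eigenvalues[zero_mode_count]``.
    """

    kind: str
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_mode_count: int
    zero_tolerance: float
    kt_over_gamma: float
    n_nodes: int

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.zero_mode_count:]

    def mode_eigenvalue(self, k: int) -> float:
        """Eigenvalue of slow mode ``k`` (1-based, zero modes excluded)."""
        self._check_mode(k)
        return float(self.eigenvalues[self.zero_mode_count + k - 1])

    def mode_vector(self, k: int) -> np.ndarray:
        """Eigenvector of slow mode ``k`` (1-based, zero modes excluded)."""
        self._check_mode(k)
        return self.eigenvectors[:, self.zero_mode_count + k - 1]

    def _check_mode(self, k: int) -> None:
        n_nonzero = len(self.eigenvalues) - self.zero_mode_count
        if not 1 <= k <= n_nonzero:
            raise NetworkError(
                f"mode index {k} out of range 1..{n_nonzero} (zero modes excluded)"
            )


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def build_kirchhoff(
    s: CoarseStructure,
    cutoff: float = DEFAULT_GNM_CUTOFF,
    kt_over_gamma: float = DEFAULT_KT_OVER_GAMMA,
) -> ElasticNetwork:
    """Kirchhoff (Laplacian) matrix of the Cα contact graph at ``cutoff``.

    Off-diagonal entries are −1 exactly for pairs within the cutoff,
    diagonal entries are the node degrees.  A disconnected contact graph is
    reported with a warning (extra zero modes are then expected), not an
    error.
    """
    n = len(s)
    if n < 2:
        raise NetworkError("need at least 2 residues for a GNM network")
    cmap = compute_contact_map(s, cutoff, min_sequence_separation=1)
    gamma = np.zeros((n, n))
    for i, j in cmap.pairs:
        gamma[i, j] = gamma[j, i] = -1.0
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    import scipy.sparse.csgraph as csgraph

    n_comp, _ = csgraph.connected_components(-np.minimum(gamma, 0), directed=False)
    if n_comp > 1:
        logger.warning(
            "GNM contact graph has %d components; expect %d zero modes",
            n_comp,
            n_comp,
        )
    return ElasticNetwork("GNM", gamma, float(cutoff), kt_over_gamma, n, n_comp == 1, s)


def build_hessian(
    s: CoarseStructure,
    cutoff: float = DEFAULT_ANM_CUTOFF,
    kt_over_gamma: float = DEFAULT_KT_OVER_GAMMA,
) -> ElasticNetwork:
    """3N×3N ANM Hessian from the harmonic pair potential at ``cutoff``.

    The (i, j) off-diagonal 3×3 block for a contacting pair is
    ``-(d dᵀ)/|d|²`` with ``d`` the equilibrium inter-node vector; diagonal
    blocks make every block row sum to zero.
    """
    n = len(s)
    if n < 2:
        raise NetworkError("need at least 2 residues for an ANM network")
    coords = s.coords
    # collinearity check (rigid-body space > 6 if degenerate)
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        logger.warning("degenerate (collinear) geometry; rigid-body space exceeds 6")
    cmap = compute_contact_map(s, cutoff, min_sequence_separation=1)
    hess = np.zeros((3 * n, 3 * n))
    for i, j in cmap.pairs:
        d = coords[j] - coords[i]
        d2 = float(d @ d)
        if d2 == 0.0:
            raise NetworkError(f"coincident nodes {i} and {j}")
        block = -np.outer(d, d) / d2
        hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return ElasticNetwork("ANM", hess, float(cutoff), kt_over_gamma, n, True, s)


def decompose(
    net: ElasticNetwork, zero_tolerance: float | None = None
) -> SpectralDecomposition:
    """Full symmetric eigendecomposition with zero-mode flagging.

    ``zero_tolerance`` defaults to ``1e-8 × max eigenvalue`` (relative).
    An eigenvalue below ``-zero_tolerance`` indicates a construction bug
    and raises :class:`NetworkError`.
    """
    if not np.all(np.isfinite(net.matrix)):
        raise NetworkError("network matrix contains non-finite entries")
    evals, evecs = scipy.linalg.eigh(net.matrix)
    if zero_tolerance is None:
        zero_tolerance = 1e-8 * float(np.max(np.abs(evals)))
    if evals[0] < -zero_tolerance:
        raise NetworkError(
            f"negative eigenvalue {evals[0]:.3e} below tolerance; matrix not PSD"
        )
    zero_count = int(np.sum(evals <= zero_tolerance))
    evecs = _fix_eigenvector_signs(evecs)
    return SpectralDecomposition(
        kind=net.kind,
        eigenvalues=evals,
        eigenvectors=evecs,
        zero_mode_count=zero_count,
        zero_tolerance=float(zero_tolerance),
        kt_over_gamma=net.kt_over_gamma,
        n_nodes=net.n_nodes,
    )


def _mode_indices(d: SpectralDecomposition, mode_subset) -> np.ndarray:
    """Translate a 1-based slow-mode subset (or "all") to raw column indices."""
    n_nonzero = len(d.eigenvalues) - d.zero_mode_count
    if mode_subset == "all" or mode_subset is None:
        return np.arange(d.zero_mode_count, len(d.eigenvalues))
    modes = np.atleast_1d(np.asarray(mode_subset, dtype=int))
    if np.any(modes < 1) or np.any(modes > n_nonzero):
        raise NetworkError(
            f"mode subset {list(modes)} outside non-zero range 1..{n_nonzero} "
            "(zero modes cannot be requested)"
        )
    return d.zero_mode_count + modes - 1


def gnm_correlation(d: SpectralDecomposition, mode_subset="all") -> np.ndarray:
    """N×N matrix of <ΔRi·ΔRj> from the selected non-zero GNM modes."""
    if d.kind != "GNM":
        raise NetworkError("gnm_correlation requires a GNM decomposition")
    cols = _mode_indices(d, mode_subset)
    scale = 3.0 * d.kt_over_gamma
    u = d.eigenvectors[:, cols]
    inv = 1.0 / d.eigenvalues[cols]
    return scale * (u * inv) @ u.T


def anm_correlation(d: SpectralDecomposition, mode_subset="all") -> np.ndarray:
    """N×N matrix of <ΔRi·ΔRj> from the selected non-zero ANM modes.

    Entry (i, j) sums the dot products of the per-residue 3-vector blocks
    of each eigenvector, weighted by 1/λ; with all modes this equals the
    trace of the 3×3 blocks of the pseudoinverse Hessian (× kBT/γ).
    """
    if d.kind != "ANM":
        raise NetworkError("anm_correlation requires an ANM decomposition")
    cols = _mode_indices(d, mode_subset)
    n = d.n_nodes
    u = d.eigenvectors[:, cols].reshape(n, 3, len(cols))
    inv = 1.0 / d.eigenvalues[cols]
    # C_ij = scale * sum_k inv_k * sum_a u[i,a,k] u[j,a,k]
    return d.kt_over_gamma * np.einsum("iak,jak,k->ij", u, u, inv, optimize=True)


def mode_shape(d: SpectralDecomposition, k: int) -> np.ndarray:
    """Per-residue squared-fluctuation profile of slow mode ``k`` (1-based)."""
    lam = d.mode_eigenvalue(k)
    vec = d.mode_vector(k)
    if d.kind == "GNM":
        return 3.0 * d.kt_over_gamma * vec**2 / lam
    blocks = vec.reshape(d.n_nodes, 3)
    return d.kt_over_gamma * np.sum(blocks**2, axis=1) / lam


def normalized_cross_correlation(raw: np.ndarray) -> np.ndarray:
    """Normalize a correlation matrix to C_ij = raw_ij / √(raw_ii·raw_jj).

    Residues with zero (or negative) diagonal are excluded: their rows and
    columns are set to NaN and a warning is logged.  The retained diagonal
    is exactly 1.
    """
    raw = np.asarray(raw, dtype=float)
    diag = np.diag(raw).copy()
    bad = diag <= 0
    if bad.any():
        logger.warning(
            "excluding %d residue(s) with non-positive diagonal from "
            "normalized correlations",
            int(bad.sum()),
        )
        diag[bad] = np.nan
    denom = np.sqrt(np.outer(diag, diag))
    out = raw / denom
    np.fill_diagonal(out, np.where(bad, np.nan, 1.0))
    return out


def mode_contribution(
    d: SpectralDecomposition, k: int, convention: str = "inverse"
) -> float:
    """Percentage contribution of slow mode ``k`` to the overall motion.

    The default ``"inverse"`` convention weights each non-zero mode by the
    inverse of its eigenvalue (slow modes contribute most):
    ``100 λk⁻¹ / Σj λj⁻¹``.  The alternative ``"literal"`` convention
    weights by the eigenvalue itself (``100 λk / Σj λj``) and is provided
    for comparison only.
    """
    lam = d.mode_eigenvalue(k)
    nz = d.nonzero_eigenvalues
    if convention == "inverse":
        return float(100.0 * (1.0 / lam) / np.sum(1.0 / nz))
    if convention == "literal":
        return float(100.0 * lam / np.sum(nz))
    raise ValueError(f"unknown contribution convention {convention!r}")


def degenerate_groups(
    d: SpectralDecomposition, n_modes: int | None = None, rel_tol: float = 1e-6
) -> list[list[int]]:
    """Group slow modes whose eigenvalues are degenerate.

    Consecutive non-zero modes with relative eigenvalue gap below
    ``rel_tol`` are grouped.  Returns 1-based mode index groups for the
    first ``n_modes`` slow modes (default: all).
    """
    nz = d.nonzero_eigenvalues
    if n_modes is None:
        n_modes = len(nz)
    n_modes = min(n_modes, len(nz))
    groups: list[list[int]] = []
    for k in range(1, n_modes + 1):
        lam = nz[k - 1]
        if groups:
            prev = nz[groups[-1][-1] - 1]
            if abs(lam - prev) / max(abs(prev), 1e-300) < rel_tol:
                groups[-1].append(k)
                continue
        groups.append([k])
    return groups
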