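"""Simplified pore-radius profiling along a channel axis.

This is deliberately NOT a reimplementation of HOLE: at each position z
along the axis a deterministic on-axis probe computes

    radius(z) = min over atoms ( |p(z) - atom center| - vdW radius )

i.e. the largest sphere centered on the axis point that touches no atom.
An optional in-plane refinement locally maximizes that radius over small
lateral offsets (coarse grid then Nelder–Mead with a fixed iteration
cap), still fully deterministic.  Cα-only structures use a uniform
effective residue radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError
from .structures import CoarseStructure, symmetry_axis

logger = logging.getLogger(__name__)

__all__ = ["PoreProfile", "pore_radius_profile", "compare_profiles", "VDW_RADII"]

#: Standard element van der Waals radii (Å).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: Effective radius (Å) for a residue represented by its Cα alone.
CA_EFFECTIVE_RADIUS = 2.3

#: Atoms farther than this from a z sample (along the axis) do not make the
#: sample "supported"; beyond it the sample is marked missing.
SLAB_HALF_WIDTH = 10.0


@dataclass
class PoreProfile:
    """Pore radius as a function of position along the channel axis."""

    z: np.ndarray
    radius: np.ndarray
    axis: np.ndarray
    origin: np.ndarray
    step: float
    missing: np.ndarray = None  # samples with no atoms in lateral reach
    clamped: np.ndarray = None  # samples whose raw radius was negative
    centers: np.ndarray = None  # refined in-plane probe centers (n, 3)

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.radius = np.asarray(self.radius, float)
        if np.any(np.diff(self.z) <= 0):
            raise AnalysisError("z samples must be strictly increasing")
        if self.missing is None:
            self.missing = np.zeros(len(self.z), dtype=bool)
        if self.clamped is None:
            self.clamped = np.zeros(len(self.z), dtype=bool)

    def min_radius(self) -> tuple[float, float]:
        """(z, radius) of the constriction among supported samples."""
        ok = ~self.missing
        if not ok.any():
            raise AnalysisError("profile has no supported samples")
        idx = np.argmin(np.where(ok, self.radius, np.inf))
        return float(self.z[idx]), float(self.radius[idx])


def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return a, e1, e2


def _probe_radius(point: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(centers - point, axis=1) - radii))


def pore_radius_profile(
    s: CoarseStructure,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    z_range: tuple[float, float] | None = None,
    step: float = 1.0,
    refine: bool = False,
    vdw_radii: dict[str, float] | None = None,
    ca_radius: float = CA_EFFECTIVE_RADIUS,
) -> PoreProfile:
    """Pore radius at each z along the axis.

    Uses the heavy-atom side store when present, otherwise the Cα trace
    with a uniform ``ca_radius``.  ``axis`` defaults to the assembly's
    principal symmetry axis, ``origin`` to the centroid, and ``z_range`` to
    the structure's extent along the axis ± 5 Å.  Samples with no atom
    within ``SLAB_HALF_WIDTH`` along the axis are marked missing; negative
    radii (blocked pore) are clamped to 0 and flagged.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    vdw = dict(VDW_RADII)
    if vdw_radii:
        vdw.update({k.upper(): v for k, v in vdw_radii.items()})
    if s.atoms is not None and len(s.atoms) > 0:
        centers = np.asarray(s.atoms.coords, float)
        radii = np.array(
            [vdw.get(str(e).upper(), 1.7) for e in s.atoms.elements], float
        )
    else:
        centers = s.coords
        radii = np.full(len(s), float(ca_radius))
    if axis is None:
        axis = symmetry_axis(s)
    a, e1, e2 = _axis_frame(axis)
    if origin is None:
        origin = s.coords.mean(axis=0)
    origin = np.asarray(origin, float)
    z_atoms = (centers - origin) @ a
    if z_range is None:
        z_range = (float(z_atoms.min()) - 5.0, float(z_atoms.max()) + 5.0)
    z_samples = np.arange(z_range[0], z_range[1] + 0.5 * step, step)
    radius = np.zeros(len(z_samples))
    missing = np.zeros(len(z_samples), dtype=bool)
    clamped = np.zeros(len(z_samples), dtype=bool)
    probe_centers = np.zeros((len(z_samples), 3))
    for idx, z in enumerate(z_samples):
        p = origin + z * a
        if not np.any(np.abs(z_atoms - z) <= SLAB_HALF_WIDTH):
            missing[idx] = True
            probe_centers[idx] = p
            continue
        if refine:
            p = _refine_center(p, e1, e2, centers, radii)
        r = _probe_radius(p, centers, radii)
        if r < 0:
            clamped[idx] = True
            r = 0.0
        radius[idx] = r
        probe_centers[idx] = p
    if clamped.any():
        logger.info("%d pore sample(s) clamped to radius 0", int(clamped.sum()))
    return PoreProfile(
        z=z_samples, radius=radius, axis=a, origin=origin, step=float(step),
        missing=missing, clamped=clamped, centers=probe_centers,
    )


def _refine_center(
    p: np.ndarray, e1: np.ndarray, e2: np.ndarray,
    centers: np.ndarray, radii: np.ndarray,
    grid_extent: float = 2.0, grid_step: float = 1.0, maxiter: int = 60,
) -> np.ndarray:
    """Locally maximize the probe radius over in-plane offsets."""
    from scipy.optimize import minimize

    offsets = np.arange(-grid_extent, grid_extent + 0.5 * grid_step, grid_step)
    best, best_val = np.zeros(2), -np.inf
    for dx in offsets:
        for dy in offsets:
            val = _probe_radius(p + dx * e1 + dy * e2, centers, radii)
            if val > best_val:
                best, best_val = np.array([dx, dy]), val
    res = minimize(
        lambda xy: -_probe_radius(p + xy[0] * e1 + xy[1] * e2, centers, radii),
        best,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4},
    )
    xy = res.x if -res.fun >= best_val else best
    return p + xy[0] * e1 + xy[1] * e2


def compare_profiles(a: PoreProfile, b: PoreProfile) -> dict:
    """Per-z radius differences (b − a) and the change at a's constriction.

    ``b`` is linearly resampled onto ``a``'s grid over the overlapping z
    range; disjoint ranges are an error.
    """
    lo = max(a.z[0], b.z[0])
    hi = min(a.z[-1], b.z[-1])
    if lo >= hi:
        raise AnalysisError("profiles cover disjoint z ranges")
    mask = (a.z >= lo) & (a.z <= hi) & ~a.missing
    z = a.z[mask]
    b_ok = ~b.missing
    b_resampled = np.interp(z, b.z[b_ok], b.radius[b_ok])
    diff = b_resampled - a.radius[mask]
    # constriction of a within the overlap
    idx = int(np.argmin(a.radius[mask]))
    return {
        "z": z,
        "difference": diff,
        "constriction_z": float(z[idx]),
        "constriction_radius_a": float(a.radius[mask][idx]),
        "constriction_radius_b": float(b_resampled[idx]),
        "constriction_change": float(diff[idx]),
        "mean_change": float(np.mean(diff)),
    }
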