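"""Interpretation of elastic-network spectra.

Hinge detection on per-mode fluctuation profiles, pairing of GNM modes
with the ANM modes whose profiles they match, grouped "motions",
eigenvector edge conformations, rigid in-plane rotation angles of
annotated domains, and comparison of full vs. domain-deleted variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .elastic import SpectralDecomposition
from .errors import AnalysisError, NetworkError
from .structures import CoarseStructure

logger = logging.getLogger(__name__)

__all__ = [
    "MotionGroup",
    "EdgeConformations",
    "detect_hinges",
    "associate_modes",
    "edge_conformations",
    "domain_rotation_angle",
    "compare_variants",
    "domain_correlation_summary",
]

#: Default grouping of slow GNM modes into "motions": the slowest
#: non-degenerate mode alone, then the next degenerate groups.
DEFAULT_MOTION_GROUPS: dict[str, list[int]] = {
    "I": [1],
    "II": [2, 3, 4],
    "III": [5, 6],
}


@dataclass
class MotionGroup:
    """A named group of GNM modes with its matched ANM mode and profile."""

    label: str
    gnm_modes: list[int]
    shape: np.ndarray  # per-residue squared fluctuations (non-negative)
    anm_mode: int | None = None
    anm_score: float | None = None
    hinge_ranges: list[tuple[str, int, int]] = field(default_factory=list)
    domain_correlation_summary: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.asarray(self.shape) < 0):
            raise AnalysisError("motion shape must be non-negative")


@dataclass
class EdgeConformations:
    """± eigenvector displacements about the equilibrium structure."""

    plus: CoarseStructure
    minus: CoarseStructure
    mode: int
    amplitude: float


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]
    return out


def detect_hinges(
    shape: np.ndarray,
    window: int = 5,
    floor_quantile: float = 0.1,
    chain_ids: np.ndarray | None = None,
    res_numbers: np.ndarray | None = None,
) -> list[tuple[str, int, int]]:
    """Hinge ranges: local-minimum runs of the smoothed fluctuation profile.

    The profile is smoothed with a moving average of ``window`` residues
    per chain; maximal runs of residues that are local minima and whose
    smoothed value is at or below the ``floor_quantile`` of the chain's
    profile are returned as ``(chain, start_resnum, end_resnum)``.
    Scaling the profile uniformly does not change the result.
    """
    shape = np.asarray(shape, dtype=float)
    n = len(shape)
    if n <= window:
        raise AnalysisError(f"profile length {n} must exceed window {window}")
    if chain_ids is None:
        chain_ids = np.full(n, "A")
    if res_numbers is None:
        res_numbers = np.arange(1, n + 1)
    ranges: list[tuple[str, int, int]] = []
    for chain in dict.fromkeys(chain_ids):
        mask = chain_ids == chain
        prof = shape[mask]
        nums = np.asarray(res_numbers)[mask]
        if np.ptp(prof) == 0:
            logger.warning("flat fluctuation profile on chain %s; no hinges", chain)
            continue
        sm = _moving_average(prof, window)
        floor = np.quantile(sm, floor_quantile)
        m = len(sm)
        is_min = np.zeros(m, dtype=bool)
        for i in range(m):
            lo, hi = max(0, i - 1), min(m, i + 2)
            neighborhood = sm[lo:hi]
            is_min[i] = sm[i] <= neighborhood.min() + 1e-15 * max(1.0, abs(sm[i]))
        # interior minima only: endpoints are trivial minima of half-windows
        is_min[0] = is_min[-1] = False
        candidate = is_min & (sm <= floor + 1e-12 * max(1.0, abs(floor)))
        start = None
        for i in range(m):
            if candidate[i] and start is None:
                start = i
            elif not candidate[i] and start is not None:
                ranges.append((str(chain), int(nums[start]), int(nums[i - 1])))
                start = None
        if start is not None:
            ranges.append((str(chain), int(nums[start]), int(nums[m - 1])))
    return ranges


def associate_modes(
    gnm_shapes: dict[str, np.ndarray] | list[np.ndarray],
    anm_shapes: dict[int, np.ndarray] | list[np.ndarray],
) -> list[dict]:
    """Match each GNM profile with the ANM profile it best correlates with.

    Pearson correlation of per-residue profiles; ties break toward the
    slower (lower-index) ANM mode.  Constant profiles have undefined
    similarity and are reported with ``score=None``.
    """
    if isinstance(gnm_shapes, list):
        gnm_shapes = {str(i + 1): s for i, s in enumerate(gnm_shapes)}
    if isinstance(anm_shapes, list):
        anm_shapes = {i + 1: s for i, s in enumerate(anm_shapes)}
    if not gnm_shapes or not anm_shapes:
        raise AnalysisError("need at least one profile on each side")
    out = []
    for g_label, g in gnm_shapes.items():
        g = np.asarray(g, dtype=float)
        if np.ptp(g) == 0:
            out.append({"gnm": g_label, "anm": None, "score": None})
            continue
        best_mode, best_score = None, -np.inf
        for a_idx in sorted(anm_shapes):
            a = np.asarray(anm_shapes[a_idx], dtype=float)
            if np.ptp(a) == 0:
                continue
            r = float(np.corrcoef(g, a)[0, 1])
            if r > best_score + 1e-12:  # strict improvement; ties keep slower mode
                best_mode, best_score = a_idx, r
        out.append(
            {
                "gnm": g_label,
                "anm": best_mode,
                "score": None if best_mode is None else best_score,
            }
        )
    return out


def edge_conformations(
    s: CoarseStructure,
    d: SpectralDecomposition,
    mode: int,
    amplitude: float | None = None,
    max_displacement: float = 2.0,
) -> EdgeConformations:
    """Structures displaced by ± amplitude × (ANM eigenvector of ``mode``).

    With ``amplitude=None`` the amplitude is chosen so that the largest
    per-residue displacement is ``max_displacement`` Å.
    """
    if d.kind != "ANM":
        raise NetworkError("edge conformations require an ANM decomposition")
    vec = d.mode_vector(mode).reshape(len(s), 3)
    if amplitude is None:
        max_norm = float(np.max(np.linalg.norm(vec, axis=1)))
        amplitude = max_displacement / max_norm if max_norm > 0 else 0.0
    if not np.isfinite(amplitude):
        raise AnalysisError("amplitude must be finite")
    plus = s.with_coords(s.coords + amplitude * vec)
    minus = s.with_coords(s.coords - amplitude * vec)
    return EdgeConformations(plus=plus, minus=minus, mode=mode, amplitude=float(amplitude))


def domain_rotation_angle(
    reference: CoarseStructure,
    displaced: CoarseStructure,
    domain: str,
    axis: np.ndarray,
    origin: np.ndarray | None = None,
) -> float:
    """Signed least-squares in-plane rotation (degrees) of a domain.

    The rotation of the domain's Cα set about ``axis`` (right-handed sign
    convention) that best maps the reference onto the displaced structure,
    considering only components perpendicular to the axis.
    """
    mask = reference.annotation_mask(domain)
    if mask.sum() < 3:
        raise AnalysisError(f"domain {domain!r} has fewer than 3 residues")
    if len(displaced) != len(reference):
        raise AnalysisError("reference and displaced structures differ in residue set")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if origin is None:
        origin = reference.coords.mean(axis=0)
    u = reference.coords[mask] - origin
    v = displaced.coords[mask] - origin
    u_perp = u - np.outer(u @ axis, axis)
    v_perp = v - np.outer(v @ axis, axis)
    cross = np.cross(u_perp, v_perp) @ axis
    dot = np.sum(u_perp * v_perp, axis=1)
    return float(np.degrees(np.arctan2(cross.sum(), dot.sum())))


def domain_correlation_summary(
    normalized: np.ndarray,
    s: CoarseStructure,
    domains: list[str],
) -> dict[tuple[str, str], float]:
    """Mean normalized cross-correlation over residue pairs spanning domains."""
    out: dict[tuple[str, str], float] = {}
    masks = {lab: s.annotation_mask(lab) for lab in domains}
    for i, a in enumerate(domains):
        for b in domains[i:]:
            block = normalized[np.ix_(masks[a], masks[b])]
            out[(a, b)] = float(np.nanmean(block))
    return out


def compare_variants(
    full: list[MotionGroup],
    reduced: list[MotionGroup],
    mapping: dict[int, int],
) -> dict:
    """Compare motion profiles of a full structure and a reduced variant.

    ``mapping`` sends residue indices of the full structure to indices of
    the reduced one (shared residues only).  For labels present in both
    variants the Pearson correlation of the shapes on shared residues is
    reported; labels present in only one variant are flagged.
    """
    if not mapping:
        raise AnalysisError("empty residue correspondence")
    full_idx = np.fromiter(mapping.keys(), dtype=int)
    red_idx = np.fromiter(mapping.values(), dtype=int)
    full_by_label = {g.label: g for g in full}
    red_by_label = {g.label: g for g in reduced}
    report = {
        "per_motion": {},
        "only_in_full": sorted(set(full_by_label) - set(red_by_label)),
        "only_in_reduced": sorted(set(red_by_label) - set(full_by_label)),
    }
    for label in sorted(set(full_by_label) & set(red_by_label)):
        a = np.asarray(full_by_label[label].shape)[full_idx]
        b = np.asarray(red_by_label[label].shape)[red_idx]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            report["per_motion"][label] = None
        else:
            report["per_motion"][label] = float(np.corrcoef(a, b)[0, 1])
    return report
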