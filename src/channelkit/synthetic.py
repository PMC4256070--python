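"""Deterministic synthetic fixtures for every analysis stage.

Generators cover: toy elastic networks with closed-form spectra (rings and
chains), C4-symmetric four-chain helical bundles standing in for a
tetrameric channel, coupling tables with a planted true-contact fraction,
and conservation tracks with a planted burial correlation.  Every
generator derives a private random stream from ``(seed, kind)`` so
fixtures built from one master seed are independent and bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Any

import numpy as np

from .errors import AnalysisError, StructureError
from .quality import BurialProfile, ResidueTrack
from .structures import CoarseStructure, ContactMap, assemble_homotetramer

__all__ = [
    "GeneratorSpec",
    "make_ring",
    "make_chain",
    "make_helix_bundle_tetramer",
    "make_coupling_table",
    "make_conservation_track",
    "rewire_contact_map",
]

#: Ideal α-helix geometry used by the bundle generator.
HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TURN_DEG = 100.0  # degrees per residue


@dataclass(frozen=True)
class GeneratorSpec:
    """Echoable provenance record for a generated fixture."""

    kind: str
    parameters: dict[str, Any]
    seed: int

    def as_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "parameters": dict(self.parameters)}


def _rng(seed: int, kind: str) -> np.random.Generator:
    """Stream derived from (seed, kind); crc32 keeps the derivation stable."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(kind.encode())]))


def make_ring(n: int, spacing: float = 3.8) -> CoarseStructure:
    """``n`` nodes equally spaced on a circle (nearest-neighbor = spacing).

    With a GNM cutoff just above the spacing this is a cycle graph whose
    Laplacian spectrum is the closed form 2 − 2cos(2πk/n).
    """
    if n < 3:
        raise StructureError("ring needs n >= 3")
    radius = spacing / (2.0 * np.sin(np.pi / n))
    theta = 2.0 * np.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
    return CoarseStructure(["A"] * n, np.arange(1, n + 1), coords)


def make_chain(n: int, spacing: float = 3.8) -> CoarseStructure:
    """``n`` collinear nodes along x (path-graph GNM substrate)."""
    if n < 2:
        raise StructureError("chain needs n >= 2")
    coords = np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])
    return CoarseStructure(["A"] * n, np.arange(1, n + 1), coords)


def make_helix_bundle_tetramer(
    residues_per_chain: int = 60,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
    bundle_radius: float = 8.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    turn_deg: float = HELIX_TURN_DEG,
) -> CoarseStructure:
    """Four ideal helical Cα traces with exact C4 symmetry about z.

    The upper half of each chain is annotated "TM" and the lower half
    "cytosolic" so domain-level analyses can be exercised.  ``noise_sigma``
    adds an identical (seed-driven) perturbation to each chain, preserving
    the C4 symmetry.
    """
    if residues_per_chain < 10:
        raise StructureError("need at least 10 residues per chain")
    rng = _rng(seed, "helix_bundle")
    i = np.arange(residues_per_chain)
    phase = np.radians(turn_deg) * i
    local = np.column_stack(
        [
            bundle_radius + radius * np.cos(phase),
            radius * np.sin(phase),
            rise * i - rise * (residues_per_chain - 1) / 2.0,
        ]
    )
    if noise_sigma > 0:
        local = local + rng.normal(0.0, noise_sigma, size=local.shape)
    half = residues_per_chain // 2
    monomer = CoarseStructure(
        ["A"] * residues_per_chain,
        np.arange(1, residues_per_chain + 1),
        local,
        annotations={
            "TM": {"A": [(half + 1, residues_per_chain)]},
            "cytosolic": {"A": [(1, half)]},
        },
    )
    bundle = assemble_homotetramer(monomer, symmetry_order=4, axis=(0, 0, 1))
    d_min = _min_interchain_distance(bundle)
    if d_min < 1.0:
        raise StructureError(
            f"chains overlap (min inter-chain distance {d_min:.2f} Å < 1 Å); "
            "increase bundle_radius"
        )
    return bundle


def _min_interchain_distance(s: CoarseStructure) -> float:
    from scipy.spatial import cKDTree

    d_min = np.inf
    chains = s.chains()
    for a_idx in range(len(chains)):
        for b_idx in range(a_idx + 1, len(chains)):
            pa = s.coords[s.chain_mask(chains[a_idx])]
            pb = s.coords[s.chain_mask(chains[b_idx])]
            d, _ = cKDTree(pb).query(pa, k=1)
            d_min = min(d_min, float(np.min(d)))
    return d_min


def make_coupling_table(
    cmap: ContactMap,
    n_pairs: int,
    precision: float,
    L: int,
    seed: int = 0,
    min_separation: int = 5,
):
    """Coupling table with a planted fraction of true contacts.

    ``round(precision * n_pairs)`` pairs are drawn from the map's contact
    pairs (collapsed to residue numbering, any chain realization) and the
    rest from non-contact pairs; strengths descend with the rank order
    shuffled independently of contact status, so top-2L/3 selection is a
    fair subsample.  Pairs with sequence separation below
    ``min_separation`` are never drawn.
    """
    from .couplings import CouplingTable

    if not 0.0 <= precision <= 1.0:
        raise AnalysisError("precision must be in [0, 1]")
    rng = _rng(seed, "coupling_table")
    numbers = sorted({int(n) for n in cmap.res_numbers})
    contact = {
        p for p in cmap.number_pairs() if abs(p[0] - p[1]) >= min_separation
    }
    universe = {
        (a, b)
        for ai, a in enumerate(numbers)
        for b in numbers[ai + 1:]
        if abs(a - b) >= min_separation
    }
    non_contact = sorted(universe - contact)
    contact = sorted(contact)
    n_true = int(round(precision * n_pairs))
    n_false = n_pairs - n_true
    if n_true > len(contact) or n_false > len(non_contact):
        raise AnalysisError(
            f"cannot plant {n_true} contacts / {n_false} non-contacts: only "
            f"{len(contact)} / {len(non_contact)} available"
        )
    chosen_true = [contact[k] for k in rng.choice(len(contact), n_true, replace=False)]
    chosen_false = [
        non_contact[k] for k in rng.choice(len(non_contact), n_false, replace=False)
    ]
    pairs = chosen_true + chosen_false
    order = rng.permutation(n_pairs)
    strengths = np.sort(rng.random(n_pairs))[::-1]  # descending
    entries = np.array(
        [(pairs[k][0], pairs[k][1], strengths[rank]) for rank, k in enumerate(order)],
        dtype=float,
    )
    return CouplingTable(entries, domain_tag="other", L=L)


def make_conservation_track(
    burial: BurialProfile, rho: float, seed: int = 0
) -> ResidueTrack:
    """Conservation grades 1–9 with Spearman correlation ≈ ``rho`` to burial.

    A rank blend: standardized burial ranks mixed with Gaussian noise in
    proportion rho : sqrt(1 − rho²), then re-ranked and binned into nine
    equal-count grades.  At |rho| = 1 the grades are an exactly monotone
    function of burial (the 9-grade binning still introduces rank ties).
    """
    if not -1.0 <= rho <= 1.0:
        raise AnalysisError("rho must be in [-1, 1]")
    rng = _rng(seed, "conservation_track")
    n = len(burial)
    from scipy.stats import rankdata

    # jitter only to break burial-count ties, not to add noise
    base = rankdata(burial.burial + rng.uniform(-1e-9, 1e-9, n))
    x = (base - base.mean()) / max(base.std(), 1e-12)
    if abs(rho) == 1.0:
        z = np.sign(rho) * x
    else:
        z = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    ranks = rankdata(z, method="ordinal")
    grades = np.clip(np.ceil(ranks * 9.0 / n), 1, 9).astype(int)
    return ResidueTrack("conservation", grades.astype(float), source=f"planted rho={rho}")


def rewire_contact_map(
    cmap: ContactMap, fraction: float, seed: int = 0
) -> ContactMap:
    """Decoy map with ``fraction`` of the pairs rewired to random non-pairs.

    The result is flagged synthetic: its pairs no longer satisfy the
    distance-cutoff invariant of maps built from structures.
    """
    if not 0.0 <= fraction <= 1.0:
        raise AnalysisError("fraction must be in [0, 1]")
    rng = _rng(seed, "rewire")
    pairs = sorted(cmap.pairs)
    n_rewire = int(round(fraction * len(pairs)))
    drop_idx = set(rng.choice(len(pairs), n_rewire, replace=False).tolist())
    kept = [p for k, p in enumerate(pairs) if k not in drop_idx]
    n = len(cmap.res_numbers)
    existing = set(pairs)
    new_pairs: list[tuple[int, int]] = []
    while len(new_pairs) < n_rewire:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        p = (min(int(i), int(j)), max(int(i), int(j)))
        if p in existing or p in new_pairs:
            continue
        new_pairs.append(p)
    return cmap.replace_pairs(kept + new_pairs, synthetic=True)
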