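"""Locating and dissecting a user-supplied cone-channel model structure.

The heterotetrameric cone-channel model (two CNGA3 + two CNGB3 subunits)
is published supplementary data and is not redistributed with this
package.  Drop the PDB file at ``data/cone_channel_model.pdb`` in the
repository root (or point ``CHANNELKIT_CHANNEL_MODEL`` at it) to enable
the worked-example analyses; everything else runs on synthetic fixtures.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .errors import StructureError
from .structures import (
    CoarseStructure,
    assemble_homotetramer,
    symmetry_axis,
)

__all__ = [
    "channel_model_path",
    "identify_subunit_chains",
    "build_homotetramer_from_assembly",
]

ENV_VAR = "CHANNELKIT_CHANNEL_MODEL"
DEFAULT_RELPATH = Path("data") / "cone_channel_model.pdb"


def channel_model_path(root: str | Path | None = None) -> Path | None:
    """Path of the cone-channel model PDB if available, else None."""
    env = os.environ.get(ENV_VAR)
    if env and Path(env).exists():
        return Path(env)
    root = Path(root) if root is not None else Path.cwd()
    for base in (root, *root.parents):
        candidate = base / DEFAULT_RELPATH
        if candidate.exists():
            return candidate
    return None


def identify_subunit_chains(s: CoarseStructure) -> dict[str, list[str]]:
    """Split chains into CNGA3-like ("A3") and CNGB3-like ("B3") subunits.

    Marker residues of the two paralogs are used: a CNGA3 chain carries
    L361 and F385, a CNGB3 chain carries R403 and F427 at the homologous
    pore positions.  Chains matching neither pattern raise.
    """
    groups: dict[str, list[str]] = {"A3": [], "B3": []}
    for chain in s.chains():
        try:
            is_a3 = (
                s.res_names[s.residue_index(chain, 361)] == "LEU"
                and s.res_names[s.residue_index(chain, 385)] == "PHE"
            )
        except StructureError:
            is_a3 = False
        except Exception:
            is_a3 = False
        try:
            is_b3 = s.res_names[s.residue_index(chain, 403)] == "ARG"
        except Exception:
            is_b3 = False
        if is_a3 and not is_b3:
            groups["A3"].append(chain)
        elif is_b3 and not is_a3:
            groups["B3"].append(chain)
        else:
            raise StructureError(
                f"chain {chain!r} matches neither subunit marker pattern"
            )
    return groups


def build_homotetramer_from_assembly(
    s: CoarseStructure, chain: str
) -> CoarseStructure:
    """C4-symmetrize one chain of an assembly about its symmetry axis.

    The assembly is re-framed so its principal symmetry axis is z through
    the centroid, the selected chain is extracted, and four copies are
    related by 90° rotations.  This approximates a homotetramer built from
    one subunit of a heterotetrameric model.
    """
    axis = symmetry_axis(s)
    centroid = s.coords.mean(axis=0)
    z = axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    frame = np.column_stack([x, y, z])  # world -> frame via frame.T
    mask = s.chain_mask(chain)
    if not mask.any():
        raise StructureError(f"no chain {chain!r} in assembly")
    monomer = s.subset(mask)
    local = (monomer.coords - centroid) @ frame
    monomer = monomer.with_coords(local)
    return assemble_homotetramer(monomer, symmetry_order=4, axis=(0.0, 0.0, 1.0))
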