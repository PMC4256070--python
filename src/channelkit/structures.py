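"""Cα-level structure handling.

A :class:`CoarseStructure` is an ordered list of residues, each carrying a
chain identifier, residue number, insertion code, 3-letter residue name and
the Cα coordinate.  Heavy atoms other than Cα are kept in an optional side
store so that pore profiling can use them; they play no role in the elastic
networks or contact maps.

PDB reading/writing is delegated to :mod:`biotite`; everything downstream is
plain numpy.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import SelectorError, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomStore",
    "CoarseStructure",
    "ContactMap",
    "read_calpha_structure",
    "write_pdb",
    "write_multimodel_pdb",
    "ca_distance",
    "compute_contact_map",
    "delete_domain",
    "assemble_homotetramer",
    "symmetry_axis",
]


@dataclass(frozen=True)
class AtomStore:
    """Side store of heavy atoms (incl. Cα) for pore profiling.

    Arrays are aligned with each other, not with the residue list.
    """

    names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    chain_ids: np.ndarray
    res_numbers: np.ndarray

    def __len__(self) -> int:
        return len(self.names)


class CoarseStructure:
    """Ordered Cα-level model of one or more chains.

    Parameters
    ----------
    chain_ids, res_numbers, icodes, res_names :
        Per-residue identity arrays. ``(chain_id, res_number, icode)``
        triples must be unique.
    coords :
        (N, 3) Cα coordinates in Å.
    annotations :
        Optional map ``label -> chain_id -> [(start, end), ...]`` of
        inclusive residue-number ranges (e.g. domain boundaries).
    atoms :
        Optional :class:`AtomStore` with all heavy atoms.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        res_numbers: Sequence[int],
        coords: np.ndarray,
        res_names: Sequence[str] | None = None,
        icodes: Sequence[str] | None = None,
        annotations: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]] | None = None,
        atoms: AtomStore | None = None,
    ):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_numbers = np.asarray(res_numbers, dtype=int)
        self.coords = np.asarray(coords, dtype=float)
        n = len(self.chain_ids)
        if n == 0:
            raise StructureError("structure must contain at least one residue")
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self.res_names = (
            np.asarray(res_names, dtype="U3")
            if res_names is not None
            else np.full(n, "ALA", dtype="U3")
        )
        self.icodes = (
            np.asarray(icodes, dtype="U1")
            if icodes is not None
            else np.full(n, "", dtype="U1")
        )
        if len(self.res_names) != n or len(self.icodes) != n:
            raise StructureError("identity arrays have inconsistent lengths")

        keys = list(zip(self.chain_ids, self.res_numbers, self.icodes))
        if len(set(keys)) != n:
            seen, dups = set(), []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise StructureError(f"duplicate residue identities: {dups[:10]}")
        self._index = {k: i for i, k in enumerate(keys)}

        self.annotations: dict[str, dict[str, list[tuple[int, int]]]] = {}
        if annotations:
            for label, per_chain in annotations.items():
                self.annotations[label] = {
                    c: [tuple(r) for r in ranges] for c, ranges in per_chain.items()
                }
            self._validate_annotations()
        self.atoms = atoms

    # -- basic protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.chain_ids)

    def __repr__(self) -> str:
        return (
            f"<CoarseStructure {len(self)} residues, "
            f"{len(self.chains())} chain(s)>"
        )

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(c)
        return out

    def residue_index(self, chain: str, number: int, icode: str = "") -> int:
        """Index of the residue ``(chain, number, icode)``; raises SelectorError."""
        try:
            return self._index[(chain, int(number), icode)]
        except KeyError:
            raise SelectorError(
                f"residue selector (chain={chain!r}, number={number}, "
                f"icode={icode!r}) does not resolve"
            ) from None

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_ids == chain

    # -- annotations ---------------------------------------------------

    def _validate_annotations(self) -> None:
        chains = set(self.chains())
        for label, per_chain in self.annotations.items():
            for chain, ranges in per_chain.items():
                if chain not in chains:
                    raise StructureError(
                        f"annotation {label!r} references absent chain {chain!r}"
                    )
                nums = self.res_numbers[self.chain_mask(chain)]
                for start, end in ranges:
                    if not np.any((nums >= start) & (nums <= end)):
                        raise StructureError(
                            f"annotation {label!r} range {start}-{end} on chain "
                            f"{chain!r} matches no residue"
                        )

    def annotation_mask(self, label: str) -> np.ndarray:
        """Boolean mask of residues covered by annotation ``label``."""
        if label not in self.annotations:
            raise StructureError(f"no annotation named {label!r}")
        mask = np.zeros(len(self), dtype=bool)
        for chain, ranges in self.annotations[label].items():
            cm = self.chain_mask(chain)
            for start, end in ranges:
                mask |= cm & (self.res_numbers >= start) & (self.res_numbers <= end)
        return mask

    def annotate(self, label: str, per_chain: Mapping[str, Sequence[tuple[int, int]]]) -> None:
        self.annotations[label] = {
            c: [tuple(r) for r in ranges] for c, ranges in per_chain.items()
        }
        self._validate_annotations()

    # -- derived copies ------------------------------------------------

    def with_coords(self, coords: np.ndarray) -> "CoarseStructure":
        """Copy with replaced Cα coordinates (atom side store dropped)."""
        return CoarseStructure(
            self.chain_ids.copy(),
            self.res_numbers.copy(),
            np.asarray(coords, dtype=float),
            self.res_names.copy(),
            self.icodes.copy(),
            annotations=self.annotations,
        )

    def subset(self, mask: np.ndarray) -> "CoarseStructure":
        """Copy restricted to residues where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise StructureError("subset would remove every residue")
        kept_chains = set(np.unique(self.chain_ids[mask]))
        annotations: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for label, per_chain in self.annotations.items():
            kept_nums = {
                c: set(self.res_numbers[mask & self.chain_mask(c)])
                for c in kept_chains
            }
            new_per_chain = {}
            for chain, ranges in per_chain.items():
                if chain not in kept_chains:
                    continue
                kept = [
                    (s, e)
                    for (s, e) in ranges
                    if any(s <= n <= e for n in kept_nums[chain])
                ]
                if kept:
                    new_per_chain[chain] = kept
            if new_per_chain:
                annotations[label] = new_per_chain
        atoms = None
        if self.atoms is not None:
            kept_keys = {
                (c, n)
                for c, n in zip(self.chain_ids[mask], self.res_numbers[mask])
            }
            amask = np.array(
                [
                    (c, n) in kept_keys
                    for c, n in zip(self.atoms.chain_ids, self.atoms.res_numbers)
                ],
                dtype=bool,
            )
            atoms = AtomStore(
                self.atoms.names[amask],
                self.atoms.elements[amask],
                self.atoms.coords[amask],
                self.atoms.chain_ids[amask],
                self.atoms.res_numbers[amask],
            )
        return CoarseStructure(
            self.chain_ids[mask],
            self.res_numbers[mask],
            self.coords[mask],
            self.res_names[mask],
            self.icodes[mask],
            annotations=annotations,
            atoms=atoms,
        )


@dataclass
class ContactMap:
    """Symmetric set of residue-pair contacts at a stated Cα cutoff.

    ``pairs`` holds index pairs ``(i, j)`` with ``i < j`` into the residue
    order of the source structure; ``chain_relation`` labels each pair
    ``"intra"`` or ``"inter"``.  The residue identity arrays are copied from
    the source so that pairs can be re-expressed in residue numbering even
    after the structure is gone.
    """

    pairs: set[tuple[int, int]]
    cutoff: float
    chain_relation: dict[tuple[int, int], str]
    res_chain_ids: np.ndarray
    res_numbers: np.ndarray
    min_sequence_separation: int = 1
    synthetic: bool = False

    @property
    def n_intra(self) -> int:
        return sum(1 for v in self.chain_relation.values() if v == "intra")

    @property
    def n_inter(self) -> int:
        return sum(1 for v in self.chain_relation.values() if v == "inter")

    def __len__(self) -> int:
        return len(self.pairs)

    def number_pairs(self, relation: str | None = None) -> set[tuple[int, int]]:
        """Contact pairs expressed as unordered residue-number pairs.

        With ``relation`` set to ``"intra"`` or ``"inter"`` only that class
        is returned; chains are collapsed, so a number pair is present if
        any chain realization of it is in contact.
        """
        out: set[tuple[int, int]] = set()
        for (i, j), rel in self.chain_relation.items():
            if relation is not None and rel != relation:
                continue
            a, b = int(self.res_numbers[i]), int(self.res_numbers[j])
            out.add((min(a, b), max(a, b)))
        return out

    def replace_pairs(
        self, pairs: Iterable[tuple[int, int]], synthetic: bool = True
    ) -> "ContactMap":
        """Copy with a different pair set (used for synthetic decoy maps)."""
        pairs = {(min(i, j), max(i, j)) for i, j in pairs}
        rel = {
            p: ("intra" if self.res_chain_ids[p[0]] == self.res_chain_ids[p[1]] else "inter")
            for p in pairs
        }
        return ContactMap(
            pairs,
            self.cutoff,
            rel,
            self.res_chain_ids,
            self.res_numbers,
            self.min_sequence_separation,
            synthetic=synthetic,
        )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_DEFAULT_ANNOTATIONS_DOC = """Shipped channel-domain defaults (overridable):
TM = 161-410, cytosolic = 410-610, hinge reference 401-407, S1 = 170-186."""

#: Default domain boundaries for CNG-like channel subunits, applied per chain
#: when requested.  All values are residue numbers (inclusive).
CHANNEL_DOMAIN_DEFAULTS: dict[str, tuple[int, int]] = {
    "TM": (161, 410),
    "cytosolic": (410, 610),
    "S1": (170, 186),
    "hinge_reference": (401, 407),
}


def _as_text(pdb_source) -> io.StringIO:
    if hasattr(pdb_source, "read"):
        return io.StringIO(pdb_source.read())
    text = str(pdb_source)
    if "\n" in text or text.lstrip().startswith(("ATOM", "HETATM", "MODEL", "HEADER", "REMARK", "TITLE", "CRYST")):
        return io.StringIO(text)
    # treat as path
    with open(text) as fh:
        return io.StringIO(fh.read())


def read_calpha_structure(pdb_source, model_index: int = 1) -> CoarseStructure:
    """Read a PDB file/text into a :class:`CoarseStructure`.

    ``model_index`` is 1-based.  Alternate locations are resolved to the
    highest-occupancy conformer (ties: first encountered).  All heavy atoms
    are retained in the atom side store; the residue list holds one entry
    per Cα.
    """
    pdb = PDBFile.read(_as_text(pdb_source))
    try:
        array = pdb.get_structure(model=model_index, altloc="occupancy")
    except Exception as exc:  # biotite raises on bad model index
        raise StructureError(
            f"cannot read model {model_index} from PDB input: {exc}"
        ) from exc
    array = array[array.element != "H"]
    ca = array[(array.atom_name == "CA") & (array.element == "C")]
    if ca.array_length() == 0:
        raise StructureError(
            f"no Cα (atom name CA) records found in model {model_index}"
        )
    keys = list(zip(ca.chain_id, ca.res_id, ca.ins_code))
    if len(set(keys)) != len(keys):
        seen, dups = set(), []
        for k in keys:
            if k in seen:
                dups.append(k)
            seen.add(k)
        raise StructureError(f"duplicate Cα records for residues: {dups[:10]}")
    atoms = AtomStore(
        names=np.asarray(array.atom_name),
        elements=np.asarray(array.element),
        coords=np.asarray(array.coord, dtype=float),
        chain_ids=np.asarray(array.chain_id),
        res_numbers=np.asarray(array.res_id, dtype=int),
    )
    return CoarseStructure(
        chain_ids=np.asarray(ca.chain_id),
        res_numbers=np.asarray(ca.res_id, dtype=int),
        coords=np.asarray(ca.coord, dtype=float),
        res_names=np.asarray(ca.res_name),
        icodes=np.asarray(ca.ins_code),
        atoms=atoms,
    )


def _to_atom_array(s: CoarseStructure) -> bst.AtomArray:
    n = len(s)
    array = bst.AtomArray(n)
    array.chain_id = s.chain_ids.astype("U4")
    array.res_id = s.res_numbers
    array.ins_code = s.icodes.astype("U1")
    array.res_name = s.res_names.astype("U5")
    array.atom_name = np.full(n, "CA", dtype="U6")
    array.element = np.full(n, "C", dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    array.coord = s.coords.astype(np.float32)
    return array


def write_pdb(s: CoarseStructure, path) -> None:
    """Write the Cα trace as a standard single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(str(path))


def write_multimodel_pdb(structures: Sequence[CoarseStructure], path) -> None:
    """Write several same-topology Cα traces as a multi-MODEL PDB file."""
    if not structures:
        raise StructureError("no structures to write")
    ref = structures[0]
    stack = bst.stack([_to_atom_array(ref)] * len(structures))
    for m, s in enumerate(structures):
        if len(s) != len(ref):
            raise StructureError("models differ in residue count")
        stack.coord[m] = s.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def ca_distance(
    s: CoarseStructure,
    a: tuple[str, int] | tuple[str, int, str],
    b: tuple[str, int] | tuple[str, int, str],
) -> float:
    """Euclidean Cα–Cα distance (Å) between two residue selectors.

    Selectors are ``(chain, number)`` or ``(chain, number, icode)``.
    """
    ia = s.residue_index(*a)
    ib = s.residue_index(*b)
    return float(np.linalg.norm(s.coords[ia] - s.coords[ib]))


def compute_contact_map(
    s: CoarseStructure, cutoff: float, min_sequence_separation: int = 1
) -> ContactMap:
    """All residue pairs with Cα distance ≤ ``cutoff``.

    Same-chain pairs must additionally satisfy
    ``|Δ residue_number| >= min_sequence_separation``; inter-chain pairs are
    always eligible.  The boundary convention is inclusive (≤ cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial import cKDTree

    tree = cKDTree(s.coords)
    raw = tree.query_pairs(r=float(cutoff))
    pairs: set[tuple[int, int]] = set()
    relation: dict[tuple[int, int], str] = {}
    for i, j in raw:
        i, j = (i, j) if i < j else (j, i)
        same_chain = s.chain_ids[i] == s.chain_ids[j]
        if same_chain and abs(int(s.res_numbers[i]) - int(s.res_numbers[j])) < min_sequence_separation:
            continue
        pairs.add((i, j))
        relation[(i, j)] = "intra" if same_chain else "inter"
    return ContactMap(
        pairs,
        float(cutoff),
        relation,
        s.chain_ids.copy(),
        s.res_numbers.copy(),
        min_sequence_separation,
    )


# ---------------------------------------------------------------------------
# Derived structures
# ---------------------------------------------------------------------------

def delete_domain(
    s: CoarseStructure,
    ranges: Mapping[str, Sequence[tuple[int, int]]] | str,
) -> CoarseStructure:
    """Remove the residues in ``ranges`` (or a named annotation) from ``s``.

    ``ranges`` maps chain id to inclusive (start, end) residue-number
    ranges, or names an annotation label on ``s``.  Chains emptied by the
    deletion are dropped with a warning; emptying the whole structure is an
    error.
    """
    if isinstance(ranges, str):
        mask_del = s.annotation_mask(ranges)
    else:
        if not ranges or all(len(r) == 0 for r in ranges.values()):
            raise StructureError("empty deletion range set")
        mask_del = np.zeros(len(s), dtype=bool)
        for chain, chain_ranges in ranges.items():
            cm = s.chain_mask(chain)
            for start, end in chain_ranges:
                mask_del |= cm & (s.res_numbers >= start) & (s.res_numbers <= end)
    keep = ~mask_del
    if not keep.any():
        raise StructureError("deletion would remove every residue")
    lost_chains = set(s.chains()) - set(np.unique(s.chain_ids[keep]))
    if lost_chains:
        logger.warning("deletion emptied chain(s) %s entirely", sorted(lost_chains))
    return s.subset(keep)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, sn = np.cos(angle), np.sin(angle)
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + sn * K + (1 - c) * np.outer(axis, axis)


def assemble_homotetramer(
    monomer: CoarseStructure,
    symmetry_order: int = 4,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> CoarseStructure:
    """Replicate a single-chain monomer by Cn symmetry about ``axis``.

    Chains are labeled A, B, C, … in rotation order.  The axis passes
    through the origin of the monomer's coordinate frame.
    """
    if len(monomer.chains()) != 1:
        raise StructureError(
            f"monomer must have exactly one chain, got {monomer.chains()}"
        )
    if symmetry_order < 2:
        raise StructureError("symmetry_order must be >= 2")
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if symmetry_order > len(alphabet):
        raise StructureError("symmetry_order too large for chain labeling")
    chain_ids, res_numbers, res_names, icodes, coords = [], [], [], [], []
    for k in range(symmetry_order):
        R = _rotation_matrix(np.asarray(axis, float), 2 * np.pi * k / symmetry_order)
        chain_ids.append(np.full(len(monomer), alphabet[k], dtype="U4"))
        res_numbers.append(monomer.res_numbers)
        res_names.append(monomer.res_names)
        icodes.append(monomer.icodes)
        coords.append(monomer.coords @ R.T)
    annotations: dict[str, dict[str, list[tuple[int, int]]]] = {}
    src_chain = monomer.chains()[0]
    for label, per_chain in monomer.annotations.items():
        if src_chain in per_chain:
            annotations[label] = {
                alphabet[k]: list(per_chain[src_chain]) for k in range(symmetry_order)
            }
    return CoarseStructure(
        np.concatenate(chain_ids),
        np.concatenate(res_numbers),
        np.vstack(coords),
        np.concatenate(res_names),
        np.concatenate(icodes),
        annotations=annotations,
    )


def symmetry_axis(s: CoarseStructure) -> np.ndarray:
    """Principal symmetry axis of an assembly (unit vector).

    Computed as the gyration-tensor eigenvector whose eigenvalue is most
    separated from the other two; for a Cn-symmetric assembly the two
    in-plane moments coincide and the unique one marks the symmetry axis.
    """
    x = s.coords - s.coords.mean(axis=0)
    gyr = x.T @ x / len(s)
    evals, evecs = np.linalg.eigh(gyr)
    seps = [
        min(abs(evals[i] - evals[j]) for j in range(3) if j != i) for i in range(3)
    ]
    axis = evecs[:, int(np.argmax(seps))]
    # deterministic orientation: largest-magnitude component positive
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis
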