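"""Evaluation of structural models against ranked evolutionary couplings.

Coupling tables (residue i, residue j, strength) are consumed as plain
TSV, ranked, truncated to the strongest floor(2L/3) pairs, and overlaid on
Cα contact maps.  For tetramer pairing, a coupled residue-number pair
counts as in contact if ANY chain realization of it (intra-chain in any
chain, or inter-chain) is in contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import TableError, AnalysisError
from .structures import CoarseStructure, ContactMap, compute_contact_map

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingTable",
    "OverlayResult",
    "read_coupling_table",
    "select_top",
    "overlay_contacts",
    "cutoff_scan",
    "compare_models",
]

#: Default intra-chain sequence-separation filter for coupling evaluation.
DEFAULT_MIN_SEPARATION = 5


@dataclass
class CouplingTable:
    """Ranked residue-pair couplings in query numbering.

    ``entries`` rows are (i, j, strength) with i < j.  ``L`` is the
    alignment/query length used for top-fraction selection (e.g. 240 for a
    TM domain, 197 for a cytosolic domain).
    """

    entries: np.ndarray  # structured or (n, 3) float array [i, j, strength]
    domain_tag: str = "other"
    L: int | None = None

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.size == 0:
            e = e.reshape(0, 3)
        if e.ndim != 2 or e.shape[1] != 3:
            raise TableError("entries must be an (n, 3) array of (i, j, strength)")
        if not np.all(np.isfinite(e[:, 2])):
            raise TableError("coupling strengths must be finite")
        ii = np.minimum(e[:, 0], e[:, 1])
        jj = np.maximum(e[:, 0], e[:, 1])
        if np.any(ii == jj):
            raise TableError("self-couplings (i == j) are not allowed")
        e = np.column_stack([ii, jj, e[:, 2]])
        keys = list(zip(ii.astype(int), jj.astype(int)))
        if len(set(keys)) != len(keys):
            raise TableError("duplicate unordered pairs in coupling table")
        if self.L is not None and self.L <= 0:
            raise TableError("L must be positive")
        self.entries = e

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in self.entries[:, :2]]

    @property
    def strengths(self) -> np.ndarray:
        return self.entries[:, 2]


@dataclass
class OverlayResult:
    """Outcome of overlaying couplings on a contact map."""

    selected: int
    in_contact: int
    classification: dict[tuple[int, int], str]  # contact intra|contact inter|non-contact
    cutoff: float
    unmapped: list[tuple[int, int]] = field(default_factory=list)
    in_contact_intra_only: int = 0

    @property
    def fraction(self) -> float:
        return self.in_contact / self.selected if self.selected else 0.0

    @property
    def fraction_intra_only(self) -> float:
        return self.in_contact_intra_only / self.selected if self.selected else 0.0


def read_coupling_table(
    tsv_source,
    numbering_offset: int = 0,
    domain_tag: str = "other",
    L: int | None = None,
) -> CouplingTable:
    """Parse a 3-column (i, j, strength) TSV, applying a numbering offset.

    An optional single header line is tolerated.  Duplicate unordered
    pairs are collapsed keeping the maximum strength (warned).  Malformed
    rows raise :class:`TableError` naming the line.
    """
    if hasattr(tsv_source, "read"):
        text = tsv_source.read()
    else:
        text = str(tsv_source)
        if "\t" not in text and "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    rows: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise TableError(f"line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            i = int(float(fields[0]))
            j = int(float(fields[1]))
            strength = float(fields[2])
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise TableError(
                f"line {lineno}: non-numeric field in {fields[:3]!r}"
            ) from None
        if not np.isfinite(strength):
            raise TableError(f"line {lineno}: non-finite strength")
        rows.append((i + numbering_offset, j + numbering_offset, strength))
    if not rows:
        raise TableError("coupling table contains no data rows")
    best: dict[tuple[int, int], float] = {}
    dup = 0
    for i, j, strength in rows:
        key = (min(i, j), max(i, j))
        if key in best:
            dup += 1
            best[key] = max(best[key], strength)
        else:
            best[key] = strength
    if dup:
        logger.warning("collapsed %d duplicate coupling pair(s), keeping max strength", dup)
    entries = np.array([(i, j, v) for (i, j), v in best.items()], dtype=float)
    return CouplingTable(entries, domain_tag=domain_tag, L=L)


def select_top(
    t: CouplingTable,
    fraction_numerator: int = 2,
    fraction_denominator: int = 3,
) -> CouplingTable:
    """Keep the floor(numerator·L/denominator) strongest couplings.

    Boundary ties are broken deterministically by (smaller i, then smaller
    j).  For L = 240 this retains exactly 160 pairs.
    """
    if t.L is None:
        raise TableError("coupling table has no L; cannot select a top fraction")
    count = (fraction_numerator * t.L) // fraction_denominator
    if len(t) < count:
        raise TableError(
            f"need at least {count} couplings for top-{fraction_numerator}/"
            f"{fraction_denominator} selection with L={t.L}, got {len(t)}"
        )
    order = sorted(
        range(len(t)),
        key=lambda k: (-t.entries[k, 2], t.entries[k, 0], t.entries[k, 1]),
    )
    keep = sorted(order[:count])
    return CouplingTable(t.entries[keep], domain_tag=t.domain_tag, L=t.L)


def overlay_contacts(
    t: CouplingTable,
    cmap: ContactMap,
    pairing: str = "tetramer",
    min_separation: int | None = DEFAULT_MIN_SEPARATION,
) -> OverlayResult:
    """Classify each coupling pair against the contact map.

    ``pairing="tetramer"`` counts a pair as in contact if any intra- or
    inter-chain realization is in the map; ``pairing="monomer"`` uses
    intra-chain realizations only.  Couplings with intra-chain sequence
    separation below ``min_separation`` are dropped from the evaluation
    (set ``min_separation=None`` to disable).  Coupling residues absent
    from the structure are flagged unmapped and excluded from the
    denominator.
    """
    if pairing not in ("monomer", "tetramer"):
        raise ValueError(f"unknown pairing {pairing!r}")
    intra = cmap.number_pairs("intra")
    inter = cmap.number_pairs("inter")
    known_numbers = set(int(n) for n in cmap.res_numbers)
    classification: dict[tuple[int, int], str] = {}
    unmapped: list[tuple[int, int]] = []
    n_contact = 0
    n_intra_only = 0
    selected = 0
    for i, j in t.pairs:
        if min_separation is not None and abs(i - j) < min_separation:
            continue
        if i not in known_numbers or j not in known_numbers:
            unmapped.append((i, j))
            continue
        selected += 1
        key = (min(i, j), max(i, j))
        if key in intra:
            classification[key] = "contact intra"
            n_contact += 1
            n_intra_only += 1
        elif pairing == "tetramer" and key in inter:
            classification[key] = "contact inter"
            n_contact += 1
        else:
            classification[key] = "non-contact"
    if unmapped:
        logger.warning(
            "%d coupling pair(s) reference residues absent from the structure; "
            "excluded from the denominator", len(unmapped)
        )
    return OverlayResult(
        selected=selected,
        in_contact=n_contact,
        classification=classification,
        cutoff=cmap.cutoff,
        unmapped=unmapped,
        in_contact_intra_only=n_intra_only,
    )


def cutoff_scan(
    t: CouplingTable,
    s: CoarseStructure,
    cutoffs: Sequence[float],
    pairing: str = "tetramer",
    min_separation: int | None = DEFAULT_MIN_SEPARATION,
) -> dict[float, float]:
    """Overlay fraction at each contact cutoff (non-decreasing in cutoff)."""
    cutoffs = list(cutoffs)
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    if sorted(cutoffs) != cutoffs:
        raise ValueError("cutoffs must be ascending")
    out: dict[float, float] = {}
    for c in cutoffs:
        cmap = compute_contact_map(s, c, min_sequence_separation=1)
        out[float(c)] = overlay_contacts(
            t, cmap, pairing=pairing, min_separation=min_separation
        ).fraction
    return out


def compare_models(
    t: CouplingTable,
    maps: Sequence[tuple[str, ContactMap]],
    pairing: str = "tetramer",
    min_separation: int | None = DEFAULT_MIN_SEPARATION,
) -> dict:
    """Rank candidate models by coupling-overlay fraction.

    Returns the ranking (stable for ties) and, for every non-top model,
    the coupled pairs that are in contact in the top-ranked model but not
    in that model.
    """
    if len(maps) < 2:
        raise AnalysisError("need at least 2 contact maps to compare models")
    results = []
    for name, cmap in maps:
        res = overlay_contacts(t, cmap, pairing=pairing, min_separation=min_separation)
        results.append((name, res))
    ranking = sorted(results, key=lambda nr: -nr[1].fraction)
    top_name, top_res = ranking[0]
    top_contacts = {
        p for p, c in top_res.classification.items() if c.startswith("contact")
    }
    rescued: dict[str, list[tuple[int, int]]] = {}
    for name, res in ranking[1:]:
        theirs = {p for p, c in res.classification.items() if c.startswith("contact")}
        rescued[name] = sorted(top_contacts - theirs)
    return {
        "ranking": [(name, res.fraction) for name, res in ranking],
        "best": top_name,
        "contacts_only_in_best": rescued,
        "results": dict(results),
    }
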