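"""Conservation/hydrophobicity-vs-burial model scoring.

The expectation that a sound model buries conserved residues in the core
and exposes variable ones is turned into a rank-correlation score: the
Spearman correlation between a per-residue track (conservation grades 1–9
or hydrophobicity values) and a Cα neighbor-count burial proxy.  Decoys
are ranked by that score.  An entropy-based fallback converts an MSA into
conservation grades when no precomputed track is available.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .errors import AnalysisError, TableError
from .structures import CoarseStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueTrack",
    "BurialProfile",
    "burial_profile",
    "pattern_agreement_score",
    "rank_decoys",
    "entropy_conservation_fallback",
    "read_residue_track",
    "tm_hydrophobicity_score",
]


@dataclass
class ResidueTrack:
    """Per-residue scalar track (conservation grades or hydrophobicity)."""

    kind: str  # "conservation" | "hydrophobicity"
    values: np.ndarray
    residue_keys: list[tuple[str, int]] | None = None  # (chain, resnum), optional
    source: str = "<memory>"
    flagged: np.ndarray | None = None  # e.g. gap-majority MSA columns

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "conservation":
            v = self.values[np.isfinite(self.values)]
            if v.size and (np.any(v < 1) or np.any(v > 9) or np.any(v != np.round(v))):
                raise TableError("conservation grades must be integers in [1, 9]")
        if self.residue_keys is not None and len(self.residue_keys) != len(self.values):
            raise TableError("residue_keys and values lengths differ")

    def __len__(self) -> int:
        return len(self.values)

    def align_to(self, s: CoarseStructure) -> np.ndarray:
        """Track values in the residue order of ``s`` (NaN where absent)."""
        if self.residue_keys is None:
            if len(self.values) != len(s):
                raise AnalysisError(
                    f"track length {len(self.values)} does not match structure "
                    f"({len(s)} residues) and no residue keys are present"
                )
            return self.values
        lookup = dict(zip(self.residue_keys, self.values))
        out = np.full(len(s), np.nan)
        for idx, (c, n) in enumerate(zip(s.chain_ids, s.res_numbers)):
            out[idx] = lookup.get((str(c), int(n)), np.nan)
        return out


@dataclass
class BurialProfile:
    """Cα neighbor count within ``radius`` Å for each residue."""

    burial: np.ndarray
    radius: float

    def __post_init__(self):
        self.burial = np.asarray(self.burial, dtype=float)
        if np.any(self.burial < 0):
            raise AnalysisError("burial counts must be non-negative")

    def __len__(self) -> int:
        return len(self.burial)


def burial_profile(s: CoarseStructure, radius: float = 10.0) -> BurialProfile:
    """Count Cα neighbors within ``radius`` Å of each residue (self excluded)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    from scipy.spatial import cKDTree

    tree = cKDTree(s.coords)
    counts = np.array(
        [len(tree.query_ball_point(p, r=radius)) - 1 for p in s.coords], dtype=float
    )
    return BurialProfile(counts, float(radius))


def pattern_agreement_score(
    track: ResidueTrack | np.ndarray, burial: BurialProfile | np.ndarray
) -> float | None:
    """Spearman rank correlation between a residue track and burial.

    For conservation, a positive score means conserved residues are more
    buried (the expected pattern for a sound model).  Residues with
    missing track values are excluded.  Returns ``None`` when either input
    is constant (undefined correlation).
    """
    values = track.values if isinstance(track, ResidueTrack) else np.asarray(track, float)
    bur = burial.burial if isinstance(burial, BurialProfile) else np.asarray(burial, float)
    if len(values) != len(bur):
        raise AnalysisError(
            f"track ({len(values)}) and burial ({len(bur)}) lengths differ"
        )
    mask = np.isfinite(values) & np.isfinite(bur)
    v, b = values[mask], bur[mask]
    if len(v) < 2 or np.ptp(v) == 0 or np.ptp(b) == 0:
        logger.warning("constant track or burial; agreement score undefined")
        return None
    rho = spearmanr(v, b).statistic
    return float(rho)


def rank_decoys(
    decoys: Sequence[CoarseStructure],
    track: ResidueTrack,
    radius: float = 10.0,
) -> list[tuple[int, float | None]]:
    """Sort decoys by conservation-burial agreement, best first.

    All decoys must share one residue set.  Returns (input index, score)
    pairs sorted by score descending; ties and undefined scores keep input
    order (undefined sorts last).
    """
    if not decoys:
        raise AnalysisError("need at least one decoy")
    ref = decoys[0]
    ref_keys = list(zip(ref.chain_ids, ref.res_numbers, ref.icodes))
    for d in decoys[1:]:
        keys = list(zip(d.chain_ids, d.res_numbers, d.icodes))
        if keys != ref_keys:
            extra = set(keys) - set(ref_keys)
            missing = set(ref_keys) - set(keys)
            raise AnalysisError(
                f"decoy residue set mismatch: extra={sorted(extra)[:5]}, "
                f"missing={sorted(missing)[:5]}"
            )
    scored = []
    for idx, d in enumerate(decoys):
        aligned = track.align_to(d)
        score = pattern_agreement_score(aligned, burial_profile(d, radius).burial)
        scored.append((idx, score))
    return sorted(
        scored, key=lambda t: (-(t[1] if t[1] is not None else -np.inf), t[0])
    )


# ---------------------------------------------------------------------------
# Track I/O and fallbacks
# ---------------------------------------------------------------------------

def read_residue_track(tsv_source, kind: str = "conservation") -> ResidueTrack:
    """Read a (residue_number, value) or (chain, residue_number, value) TSV."""
    if hasattr(tsv_source, "read"):
        text = tsv_source.read()
    else:
        text = str(tsv_source)
        if "\t" not in text and "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    keys: list[tuple[str, int]] = []
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if len(fields) >= 3:
                keys.append((fields[0], int(float(fields[1]))))
                values.append(float(fields[2]))
            elif len(fields) == 2:
                keys.append(("A", int(float(fields[0]))))
                values.append(float(fields[1]))
            else:
                raise ValueError
        except ValueError:
            if lineno == 1:
                continue
            raise TableError(f"line {lineno}: malformed track row {fields!r}") from None
    if not values:
        raise TableError("track contains no data rows")
    return ResidueTrack(kind, np.asarray(values), residue_keys=keys, source=str(tsv_source)[:60])


_GAP_CHARS = set("-.")


def entropy_conservation_fallback(msa) -> ResidueTrack:
    """Conservation grades 1–9 from per-column normalized Shannon entropy.

    Accepts FASTA text, a path, or a list of aligned sequences.  Entropy is
    computed over non-gap characters and normalized by ln(20); low entropy
    maps to grade 9 (conserved).  Columns with a gap majority are flagged.
    """
    seqs = _parse_alignment(msa)
    if len(seqs) < 2:
        raise TableError("need at least 2 aligned sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise TableError(f"ragged alignment: row lengths {sorted(lengths)}")
    ncol = lengths.pop()
    if ncol == 0:
        raise TableError("empty alignment")
    grades = np.zeros(ncol)
    flagged = np.zeros(ncol, dtype=bool)
    for col in range(ncol):
        chars = [s[col].upper() for s in seqs]
        residues = [c for c in chars if c not in _GAP_CHARS]
        flagged[col] = len(residues) * 2 < len(chars)
        if not residues:
            grades[col] = 1
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        entropy = float(-np.sum(p * np.log(p)))
        normalized = min(entropy / np.log(20.0), 1.0)
        grades[col] = int(np.clip(9 - np.floor(normalized * 9), 1, 9))
    return ResidueTrack("conservation", grades, flagged=flagged, source="entropy-fallback")


def _parse_alignment(msa) -> list[str]:
    if isinstance(msa, (list, tuple)):
        return [str(s) for s in msa]
    text = str(msa)
    if not text.lstrip().startswith(">") and "\n" not in text:
        with open(text) as fh:
            text = fh.read()
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise TableError("no sequences parsed from FASTA input")
    return [str(r.seq) for r in records]


def tm_hydrophobicity_score(
    s: CoarseStructure,
    track: ResidueTrack,
    axis: np.ndarray,
    tm_label: str = "TM",
) -> float | None:
    """Spearman correlation of hydrophobicity with radial distance from the
    pore axis, over annotated TM residues.

    Lipid-facing residues lie far from the axis; a membrane-compatible
    model therefore scores positively (hydrophobic outside, polar near the
    pore/core).
    """
    mask = s.annotation_mask(tm_label)
    if mask.sum() < 3:
        raise AnalysisError(f"too few residues annotated {tm_label!r}")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rel = s.coords[mask] - s.coords.mean(axis=0)
    radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
    values = track.align_to(s)[mask]
    return pattern_agreement_score(values, radial)
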