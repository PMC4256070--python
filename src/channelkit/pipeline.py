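"""End-to-end orchestration: structure → networks → motions → reports.

All outputs are flat text (TSV tables and PDB models).  Each table starts
with a header comment naming the producing operation and the hash of the
effective configuration, and reruns with identical config and inputs are
byte-identical (fixed eigenvector sign convention, seeded generators).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import elastic, modes, couplings, quality, pore
from .errors import ChannelkitError
from .structures import (
    CoarseStructure,
    read_calpha_structure,
    symmetry_axis,
    compute_contact_map,
    write_multimodel_pdb,
    CHANNEL_DOMAIN_DEFAULTS,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_dynamics", "run_model_evaluation", "load_config"]


@dataclass
class RunConfig:
    """Effective parameters of a pipeline run; unset keys take defaults."""

    structure: str | None = None
    coupling_tables: list[str] = field(default_factory=list)
    conservation_track: str | None = None
    output_dir: str = "channelkit_out"
    gnm_cutoff: float = elastic.DEFAULT_GNM_CUTOFF
    anm_cutoff: float = elastic.DEFAULT_ANM_CUTOFF
    kt_over_gamma: float = elastic.DEFAULT_KT_OVER_GAMMA
    zero_tolerance: float | None = None
    contribution_convention: str = "inverse"
    contact_cutoff: float = 12.0
    cutoff_scan: list[float] = field(default_factory=lambda: [10, 11, 12, 13, 14, 15])
    coupling_min_separation: int = couplings.DEFAULT_MIN_SEPARATION
    coupling_L: int | None = None
    pairing: str = "tetramer"
    n_slow_modes: int = 6
    motion_groups: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in modes.DEFAULT_MOTION_GROUPS.items()}
    )
    hinge_window: int = 5
    hinge_floor_quantile: float = 0.1
    edge_max_displacement: float = 2.0
    pore_step: float = 1.0
    pore_refine: bool = False
    burial_radius: float = 10.0
    annotate_channel_domains: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results go does not change them
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    """Config file (YAML) overrides defaults; keyword flags override both."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ChannelkitError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _load_structure(cfg: RunConfig) -> CoarseStructure:
    if cfg.structure is None:
        raise ChannelkitError("no structure path configured")
    path = Path(cfg.structure)
    if not path.exists():
        raise ChannelkitError(f"structure file not found: {path}")
    s = read_calpha_structure(str(path))
    if cfg.annotate_channel_domains:
        for label in ("TM", "cytosolic"):
            start, end = CHANNEL_DOMAIN_DEFAULTS[label]
            s.annotate(label, {c: [(start, end)] for c in s.chains()})
    return s


def _write_table(path: Path, header_cols: list[str], rows, operation: str, cfg: RunConfig):
    with open(path, "w") as fh:
        fh.write(f"# produced_by: {operation}\n# config_hash: {cfg.config_hash()}\n")
        fh.write("\t".join(header_cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.8g}"
    return str(v)


def _echo_config(cfg: RunConfig, out: Path) -> None:
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def run_dynamics(cfg: RunConfig, structure: CoarseStructure | None = None) -> dict:
    """GNM/ANM analysis bundle: spectra, fluctuations, correlations,
    motions, hinges, edge conformations and pore profiles.

    Returns a summary dict; all artifacts are written under
    ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, out)
    t0 = time.time()
    stage = "load_structure"
    try:
        s = structure if structure is not None else _load_structure(cfg)
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "gnm"
        gnm = elastic.build_kirchhoff(s, cfg.gnm_cutoff, cfg.kt_over_gamma)
        d_gnm = elastic.decompose(gnm, cfg.zero_tolerance)
        stage = "anm"
        anm = elastic.build_hessian(s, cfg.anm_cutoff, cfg.kt_over_gamma)
        d_anm = elastic.decompose(anm, cfg.zero_tolerance)
        logger.info("stage anm done (%.1fs)", time.time() - t0)

        stage = "spectra"
        n_report = min(30, len(d_gnm.nonzero_eigenvalues))
        contrib = [
            elastic.mode_contribution(d_gnm, k, cfg.contribution_convention)
            for k in range(1, n_report + 1)
        ]
        _write_table(
            out / "gnm_spectrum.tsv",
            ["mode", "eigenvalue", "contribution_pct"],
            [
                (k, d_gnm.mode_eigenvalue(k), contrib[k - 1])
                for k in range(1, n_report + 1)
            ],
            "gnm_spectrum",
            cfg,
        )
        msf = np.diag(elastic.gnm_correlation(d_gnm, "all"))
        _write_table(
            out / "gnm_msf.tsv",
            ["chain", "residue", "msf"],
            list(zip(s.chain_ids, s.res_numbers, msf)),
            "gnm_msf",
            cfg,
        )

        stage = "correlations"
        raw = elastic.gnm_correlation(d_gnm, "all")
        norm = elastic.normalized_cross_correlation(raw)
        np.savetxt(
            out / "gnm_normalized_correlation.tsv",
            norm,
            delimiter="\t",
            fmt="%.6f",
            header=f"produced_by: gnm_normalized_correlation config_hash: {cfg.config_hash()}",
        )

        stage = "motions"
        n_nonzero = len(d_gnm.nonzero_eigenvalues)
        anm_shapes = {
            k: elastic.mode_shape(d_anm, k)
            for k in range(1, min(20, len(d_anm.nonzero_eigenvalues)) + 1)
        }
        motion_rows, motion_groups = [], []
        domains = [d for d in ("TM", "cytosolic") if d in s.annotations]
        for label, gnm_modes in cfg.motion_groups.items():
            gnm_modes = [k for k in gnm_modes if k <= n_nonzero]
            if not gnm_modes:
                continue
            shape = np.mean([elastic.mode_shape(d_gnm, k) for k in gnm_modes], axis=0)
            pairing = modes.associate_modes({label: shape}, anm_shapes)[0]
            hinges = modes.detect_hinges(
                shape, cfg.hinge_window, cfg.hinge_floor_quantile,
                s.chain_ids, s.res_numbers,
            )
            group = modes.MotionGroup(
                label=label, gnm_modes=gnm_modes, shape=shape,
                anm_mode=pairing["anm"], anm_score=pairing["score"],
                hinge_ranges=hinges,
            )
            if domains:
                group.domain_correlation_summary = modes.domain_correlation_summary(
                    norm, s, domains
                )
            motion_groups.append(group)
            motion_rows.append(
                (
                    label,
                    ",".join(map(str, gnm_modes)),
                    pairing["anm"] if pairing["anm"] is not None else "NA",
                    f"{pairing['score']:.4f}" if pairing["score"] is not None else "NA",
                    ";".join(f"{c}:{a}-{b}" for c, a, b in hinges) or "none",
                )
            )
        _write_table(
            out / "motions.tsv",
            ["motion", "gnm_modes", "anm_mode", "similarity", "hinges"],
            motion_rows,
            "motions",
            cfg,
        )

        stage = "edge_conformations"
        axis = symmetry_axis(s)
        edge_results = {}
        for group in motion_groups:
            if group.anm_mode is None:
                continue
            edge = modes.edge_conformations(
                s, d_anm, group.anm_mode, max_displacement=cfg.edge_max_displacement
            )
            write_multimodel_pdb(
                [edge.plus, edge.minus], out / f"edge_motion_{group.label}.pdb"
            )
            edge_results[group.label] = edge

        stage = "pore"
        ca_only = s.with_coords(s.coords)  # drop atom store: compare like with like
        base_profile = pore.pore_radius_profile(
            ca_only, axis=axis, step=cfg.pore_step, refine=cfg.pore_refine
        )
        _write_table(
            out / "pore_profile_equilibrium.tsv",
            ["z", "radius", "missing"],
            list(zip(base_profile.z, base_profile.radius, base_profile.missing.astype(int))),
            "pore_profile",
            cfg,
        )
        pore_changes = {}
        for label, edge in edge_results.items():
            for tag, conf in (("plus", edge.plus), ("minus", edge.minus)):
                prof = pore.pore_radius_profile(
                    conf, axis=axis, step=cfg.pore_step, refine=cfg.pore_refine
                )
                cmp = pore.compare_profiles(base_profile, prof)
                pore_changes[(label, tag)] = cmp["constriction_change"]
        _write_table(
            out / "pore_changes.tsv",
            ["motion", "edge", "constriction_radius_change"],
            [(lab, tag, v) for (lab, tag), v in pore_changes.items()],
            "pore_changes",
            cfg,
        )
        logger.info("stage pore done (%.1fs)", time.time() - t0)

        return {
            "structure": s,
            "gnm": d_gnm,
            "anm": d_anm,
            "contributions": contrib,
            "motion_groups": motion_groups,
            "edge_conformations": edge_results,
            "pore_changes": pore_changes,
            "output_dir": str(out),
        }
    except ChannelkitError:
        logger.error("pipeline stage %r failed", stage)
        raise


def run_model_evaluation(
    cfg: RunConfig,
    structures: dict[str, CoarseStructure] | None = None,
    coupling_tables: list | None = None,
) -> dict:
    """Coupling overlays, cutoff scans and conservation-burial scores."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, out)
    stage = "load_inputs"
    try:
        if structures is None:
            structures = {"model": _load_structure(cfg)}
        if coupling_tables is None:
            coupling_tables = [
                couplings.read_coupling_table(p, L=cfg.coupling_L)
                for p in cfg.coupling_tables
            ]
        if not coupling_tables and cfg.conservation_track is None:
            raise ChannelkitError("need at least one coupling table or a track")

        report: dict = {"overlays": {}, "scans": {}, "scores": {}}
        stage = "overlay"
        rows = []
        for t_idx, table in enumerate(coupling_tables):
            selected = couplings.select_top(table) if table.L else table
            for name, s in structures.items():
                cmap = compute_contact_map(s, cfg.contact_cutoff)
                res = couplings.overlay_contacts(
                    selected, cmap, pairing=cfg.pairing,
                    min_separation=cfg.coupling_min_separation,
                )
                report["overlays"][(t_idx, name)] = res
                rows.append(
                    (t_idx, name, res.selected, res.in_contact,
                     res.fraction, res.fraction_intra_only, cfg.contact_cutoff)
                )
            stage = "cutoff_scan"
            for name, s in structures.items():
                report["scans"][(t_idx, name)] = couplings.cutoff_scan(
                    selected, s, cfg.cutoff_scan, pairing=cfg.pairing,
                    min_separation=cfg.coupling_min_separation,
                )
            if len(structures) >= 2:
                stage = "compare_models"
                maps = [
                    (name, compute_contact_map(s, cfg.contact_cutoff))
                    for name, s in structures.items()
                ]
                report["model_ranking"] = couplings.compare_models(
                    selected, maps, pairing=cfg.pairing,
                    min_separation=cfg.coupling_min_separation,
                )
        _write_table(
            out / "coupling_overlays.tsv",
            ["table", "model", "selected", "in_contact", "fraction",
             "fraction_intra_only", "cutoff"],
            rows,
            "coupling_overlays",
            cfg,
        )

        stage = "conservation"
        if cfg.conservation_track is not None:
            track = quality.read_residue_track(cfg.conservation_track)
            score_rows = []
            for name, s in structures.items():
                bur = quality.burial_profile(s, cfg.burial_radius)
                score = quality.pattern_agreement_score(track.align_to(s), bur.burial)
                report["scores"][name] = score
                score_rows.append((name, score if score is not None else "NA"))
            _write_table(
                out / "conservation_scores.tsv",
                ["model", "agreement_score"],
                score_rows,
                "conservation_scores",
                cfg,
            )
        return report
    except ChannelkitError:
        logger.error("pipeline stage %r failed", stage)
        raise
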