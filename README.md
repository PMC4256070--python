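# channelkit

Coarse-grained structure evaluation and dynamics analysis for tetrameric
ion channels:

- **Elastic network models** — Gaussian (GNM, Kirchhoff matrix, 10 Å
  cutoff) and anisotropic (ANM, Hessian, 15 Å cutoff) networks with full
  spectral decomposition, zero-mode bookkeeping, residue cross-correlations
  (`3 kBT/γ · Γ⁺` / trace-of-blocks `H⁺`), per-mode fluctuation profiles
  and inverse-eigenvalue mode contributions.
- **Mode interpretation** — hinge detection on smoothed per-mode profiles,
  GNM↔ANM mode association by profile correlation, ± eigenvector edge
  conformations, signed in-plane domain rotation angles, and comparison of
  full vs. domain-deleted variants.
- **Evolutionary-coupling evaluation** — ranked (i, j, strength) tables,
  top-floor(2L/3) selection, contact-map overlays with intra/inter-chain
  realization semantics, cutoff scans and discrimination between
  alternative models.
- **Conservation/hydrophobicity-vs-burial scoring** — Spearman agreement
  between per-residue tracks (ConSurf-style grades 1–9, hydrophobicity
  scales) and a Cα neighbor-count burial proxy; decoy ranking; an MSA
  entropy fallback for conservation grades.
- **Pore profiling** — a deterministic simplified on-axis probe (not
  HOLE): `radius(z) = min over atoms (|p(z) − center| − vdW)`, with
  optional in-plane refinement, plus profile comparison between
  equilibrium and mode-displaced conformations.
- **Synthetic fixtures** — rings/chains with closed-form spectra,
  C4-symmetric helix-bundle tetramers, coupling tables with planted
  precision, conservation tracks with planted burial correlation; all
  bit-reproducible from a seed.

## CLI

```bash
# full dynamics bundle (spectra, MSF, correlations, motions, hinges,
# edge-conformation PDBs, pore profiles)
channelkit dynamics --structure model.pdb --out out/ --annotate-channel-domains

# model evaluation against coupling tables and conservation tracks
channelkit evaluate --structure final=model.pdb --structure alt=alt.pdb \
    --couplings tm_couplings.tsv --coupling-l 240 --out eval/

# synthetic fixtures (PDB/TSV plus a provenance sidecar)
channelkit synth helix_bundle --out bundle.pdb --n 40
channelkit synth coupling_table --out couplings.tsv --precision 0.75

# Cα–Cα distance between chain:residue selectors
channelkit distance model.pdb A:361 A:385
```

All outputs are flat text (TSV + PDB); each table header names the
producing operation and the effective-config hash, and reruns with the
same config are byte-identical.

## Layout

```
src/channelkit/
  structures.py   Cα structures, PDB I/O, contact maps, assemblies
  elastic.py      GNM/ANM construction, decomposition, correlations
  modes.py        hinges, mode association, edge conformations, rotations
  couplings.py    coupling tables, top-2L/3 selection, overlays, ranking
  quality.py      burial profiles, agreement scores, decoy ranking, MSA fallback
  pore.py         simplified pore-radius profiling
  synthetic.py    seeded fixture generators
  pipeline.py     end-to-end orchestration (RunConfig, report bundles)
  reference.py    locating/dissecting a user-supplied channel model
  cli.py          click CLI (dynamics / evaluate / synth / distance)
tests/            pytest suite incl. test_acceptance.py (one test per criterion)
scripts/acceptance.py
```
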