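import numpy as np
import pytest

from channelkit.structures import CoarseStructure
from channelkit import synthetic


def random_structure(n: int, seed: int, n_chains: int = 1, box: float = 30.0,
                     min_dist: float = 1.5) -> CoarseStructure:
    """Random point cloud split into chains, with coincident points rejected."""
    rng = np.random.default_rng(seed)
    coords = []
    while len(coords) < n:
        p = rng.uniform(0, box, 3)
        if all(np.linalg.norm(p - q) >= min_dist for q in coords[-20:]):
            coords.append(p)
    coords = np.asarray(coords)
    per = n // n_chains
    chain_ids = []
    res_numbers = []
    for c in range(n_chains):
        count = per if c < n_chains - 1 else n - per * (n_chains - 1)
        chain_ids += [chr(ord("A") + c)] * count
        res_numbers += list(range(1, count + 1))
    return CoarseStructure(chain_ids, res_numbers, coords)


@pytest.fixture(scope="session")
def bundle():
    """Shared C4-symmetric helix-bundle tetramer (40 residues per chain)."""
    return synthetic.make_helix_bundle_tetramer(residues_per_chain=40, seed=7)


@pytest.fixture(scope="session")
def bundle_gnm(bundle):
    from channelkit import build_kirchhoff, decompose

    return decompose(build_kirchhoff(bundle))


@pytest.fixture(scope="session")
def bundle_anm(bundle):
    from channelkit import build_hessian, decompose

    return decompose(build_hessian(bundle))
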