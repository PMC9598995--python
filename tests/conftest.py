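import numpy as np
import pytest

from bindfeat import fixtures as fx
from bindfeat.features import distance_map


@pytest.fixture(scope="session")
def helix10():
    """A 10-residue ideal-helix structure."""
    return fx.synth_structure(10, "ideal_helix", seed=1, protein_id="helix10")


@pytest.fixture(scope="session")
def chain25():
    """A 25-residue perturbed chain with profile and DSSP records."""
    s = fx.synth_structure(25, "perturbed_chain", seed=2, protein_id="chain25")
    profile, raw = fx.synth_profile(25, seed=3, protein_id="chain25")
    records = fx.synth_dssp(s, seed=4)
    return s, profile, raw, records


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A written 4-protein fixture directory (PDB + HHM + DSSP + labels)."""
    d = tmp_path_factory.mktemp("fixtures")
    fx.write_fixture_dir(d, n_proteins=4, length_range=(15, 40), seed=7)
    return d


def random_coords_dmap(seed, length, spread=10.0):
    """Distance map of i.i.d. uniform random points (test helper)."""
    rng = np.random.default_rng(seed)
    s = fx.synth_structure(length, "perturbed_chain", seed=seed)
    xyz = rng.uniform(0, spread, size=(length, 3))
    from bindfeat.structio import ProteinStructure, Residue
    residues = [
        Residue(i + 1, s.residues[i].aa, tuple(xyz[i])) for i in range(length)
    ]
    return distance_map(ProteinStructure(f"rnd{seed}", residues))
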