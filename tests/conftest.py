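import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tmdock import DensityParams, make_jitter_ensemble, make_toy_dimer


@pytest.fixture(scope="session")
def ridge_dimer():
    return make_toy_dimer("ridge_groove", seed=1)


@pytest.fixture(scope="session")
def bundle_dimer():
    return make_toy_dimer("bundle", seed=1)


@pytest.fixture(scope="session")
def coarse_density_params():
    """Reduced-resolution density settings used for whole-pipeline tests."""
    return DensityParams(grid_spacing=1.5, kernel_sigma=1.8, padding=6.0)


@pytest.fixture(scope="session")
def ridge_surfaces(ridge_dimer, coarse_density_params):
    """Receptor and ligand isosurfaces of the ridge/groove dimer."""
    from tmdock import build_density_map, extract_isosurface

    p = coarse_density_params
    rec_ens = make_jitter_ensemble(ridge_dimer.receptor, 0.3, 5, seed=11)
    lig_ens = make_jitter_ensemble(ridge_dimer.ligand, 0.3, 5, seed=12)
    rec_map = build_density_map(ridge_dimer.receptor, rec_ens, p)
    lig_map = build_density_map(ridge_dimer.ligand, lig_ens, p)
    rec_surf = extract_isosurface(rec_map, p.isovalue)
    lig_surf = extract_isosurface(lig_map, p.isovalue)
    return rec_surf, lig_surf


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.512   7.298  -4.800  1.00  0.00           C
END
"""


@pytest.fixture()
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


def random_structure(n_atoms: int, seed: int, spread: float = 10.0):
    """A random-coordinate carbon structure with one residue per atom."""
    from tmdock import StructureModel

    rng = np.random.default_rng(seed)
    return StructureModel(
        chain_ids=np.full(n_atoms, "A"),
        residue_numbers=np.arange(1, n_atoms + 1),
        residue_names=np.full(n_atoms, "ALA"),
        atom_names=np.full(n_atoms, "CA"),
        elements=np.full(n_atoms, "C"),
        coords=rng.uniform(-spread, spread, (n_atoms, 3)),
    )
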