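import numpy as np
import pytest

from icbind import CrosslinkConstant, LigandSpec, ReceptorProfile
from icbind.synthetic_data import default_ligands, default_receptor_panel


@pytest.fixture
def panel():
    return default_receptor_panel()


@pytest.fixture
def ligands():
    return default_ligands()


@pytest.fixture
def kx():
    return CrosslinkConstant(1e-10)


@pytest.fixture
def bivalent_ic():
    return LigandSpec("ic", valency=2, kd_alpha=1e-8, kd_betagamma=5e-7)


@pytest.fixture
def two_ligand_setup():
    """Minimal identifiable setup: one fixed-affinity anchor + one inferred ligand."""
    ligs = {
        "control_ic": LigandSpec("control_ic", 2, 1e-8, 5e-7),
        "biased_ic": LigandSpec("biased_ic", 2, 1e-8, 3e-5),
    }
    return ligs, default_receptor_panel()


def write_pdb(path, atoms):
    """Write a minimal synthetic PDB file: atoms = [(chain, resseq, x, y, z), ...]."""
    lines = []
    for i, (chain, resseq, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
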