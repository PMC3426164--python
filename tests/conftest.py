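import numpy as np
import pytest

import latticefit as lf

LATTICE_NAMES = ["SQR", "CUB", "FCC", "210"]
MODES = [lf.BACKBONE, lf.SIDE_CHAIN]


@pytest.fixture(params=LATTICE_NAMES)
def lattice(request):
    return lf.make_lattice(request.param)


def peptide_pdb(residues, chain="A"):
    """Hand-build fixed-column PDB text from (resname, resnum, {atom: xyz})."""
    lines = []
    serial = 0
    for name, num, atoms in residues:
        for aname, xyz in atoms.items():
            serial += 1
            el = aname[0] if aname[0] not in "0123456789" else aname[1]
            lines.append(
                f"ATOM  {serial:5d} {aname:^4s}{name:>4s} {chain}{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {el:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def ala_tripeptide():
    """Three complete ALA residues spaced ~3.8 Å along x."""
    res = []
    for i in range(3):
        x = 3.8 * i
        res.append((
            "ALA", i + 1,
            {
                "N": (x - 0.5, 1.0, 0.0),
                "CA": (x, 0.0, 0.0),
                "C": (x + 0.5, -1.0, 0.0),
                "O": (x + 0.5, -2.0, 0.0),
                "CB": (x, 1.0, 1.5),
            },
        ))
    return peptide_pdb(res)


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0.0, 10.0, 3)
    return R, t
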