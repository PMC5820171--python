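import numpy as np
import pytest

from pocketassess.assessment import background_from_structures
from pocketassess.microenvironment import Featurizer
from pocketassess.synthetic_data import generate_reference, perturb_model

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.759   7.096  -4.973  1.00 10.00           C
ATOM      4  O   ALA A   1      13.164   7.776  -5.920  1.00 10.00           O
ATOM      5  CB  ALA A   1      12.131   4.654  -4.864  1.00 10.00           C
ATOM      6  N   SER A   2      13.263   7.214  -3.749  1.00 10.00           N
ATOM      7  CA  SER A   2      14.344   8.143  -3.444  1.00 10.00           C
ATOM      8  C   SER A   2      15.618   7.772  -4.194  1.00 10.00           C
ATOM      9  O   SER A   2      16.101   6.644  -4.072  1.00 10.00           O
ATOM     10  CB  SER A   2      14.634   8.166  -1.940  1.00 10.00           C
ATOM     11  OG  SER A   2      13.519   8.672  -1.223  1.00 10.00           O
ATOM     12  N   ASP A   3      16.173   8.733  -4.930  1.00 10.00           N
ATOM     13  CA  ASP A   3      17.401   8.504  -5.686  1.00 10.00           C
ATOM     14  C   ASP A   3      18.573   8.203  -4.752  1.00 10.00           C
ATOM     15  O   ASP A   3      19.436   7.387  -5.087  1.00 10.00           O
ATOM     16  CB  ASP A   3      17.743   9.719  -6.557  1.00 10.00           C
ATOM     17  CG  ASP A   3      16.724   9.958  -7.668  1.00 10.00           C
ATOM     18  OD1 ASP A   3      16.303   9.001  -8.355  1.00 10.00           O
ATOM     19  OD2 ASP A   3      16.339  11.128  -7.870  1.00 10.00           O
END
"""

HEME_LIKE_HETATM = (
    "HETATM   20 FE   HEM A 101      15.000   9.000  -6.000  1.00 15.00          FE\n"
)


@pytest.fixture
def three_res_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RES_PDB)
    return path


@pytest.fixture
def three_res_with_het_pdb(tmp_path):
    path = tmp_path / "three_het.pdb"
    path.write_text(THREE_RES_PDB.replace("END\n", HEME_LIKE_HETATM + "END\n"))
    return path


@pytest.fixture(scope="session")
def featurizer():
    return Featurizer()


@pytest.fixture(scope="session")
def reference_and_site():
    return generate_reference(60, with_ligand=True, seed=1, site_size=8)


@pytest.fixture(scope="session")
def background(reference_and_site, featurizer):
    reference, _ = reference_and_site
    decoys = [perturb_model(reference, sigma, 0.0, None, seed=500 + i)
              for i, sigma in enumerate([0.3, 0.6, 1.0, 1.5])]
    return background_from_structures([reference] + decoys, featurizer,
                                      n_pairs=200, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
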