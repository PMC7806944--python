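import numpy as np
import pytest

from abfekit import anchorgeom, synthsampler

#: SMILES of the bromodomain test ligand, 2-methyl-5-(methylamino)-6-phenyl-
#: pyridazin-3(2H)-one (16 heavy atoms).
PYRIDAZINONE_SMILES = "O=C1C=C(NC)C(c2ccccc2)=NN1C"

ETHANE_MOLBLOCK = """ethane
  synth

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5400    0.0000    0.0000 C   0  0
   -0.4000    0.9000    0.4000 H   0  0
   -0.4000   -0.9000    0.4000 H   0  0
   -0.4000    0.0000   -1.0000 H   0  0
    1.9400    0.9000   -0.4000 H   0  0
    1.9400   -0.9000   -0.4000 H   0  0
    1.9400    0.0000    1.0000 H   0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
  2  7  1  0
  2  8  1  0
M  END
"""

BENZENE_MOLBLOCK = """benzene
  synth

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0
    0.6950    1.2037    0.0000 C   0  0
   -0.6950    1.2037    0.0000 C   0  0
   -1.3900    0.0000    0.0000 C   0  0
   -0.6950   -1.2037    0.0000 C   0  0
    0.6950   -1.2037    0.0000 C   0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
"""

BAD_BOND_MOLBLOCK = """broken
  synth

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5400    0.0000    0.0000 C   0  0
  1  9  1  0
M  END
"""


@pytest.fixture(scope="session")
def synthetic_fixture():
    return synthsampler.make_synthetic_complex(seed=11)


@pytest.fixture(scope="session")
def built_anchors(synthetic_fixture):
    fx = synthetic_fixture
    frame, anchors = anchorgeom.build_anchor_set(
        fx.complex, fx.reference, fx.P1, fx.P2, fx.P3, fx.zone, fx.ligand_resname
    )
    assert anchors is not None
    return frame, anchors, fx
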