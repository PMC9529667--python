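import numpy as np
import pytest

from photofoot import HelixSpec, build_helix
from photofoot.structure_io import AtomRecord, NucleotideRecord

# a literal two-residue PDB fixture (values asserted verbatim in tests)
MINIMAL_PDB = """\
REMARK   2 RESOLUTION.    2.10 ANGSTROMS.
ATOM      1  P    DT A   1       1.000   2.000   3.000  1.00 10.00           P
ATOM      2  C1'  DT A   1       2.500   2.000   3.000  1.00 20.00           C
ATOM      3  C5   DT A   1       3.000   4.000   5.000  1.00 30.00           C
ATOM      4  C6   DT A   1       3.000   4.000   7.000  1.00 40.00           C
ATOM      5  P    DC A   2       4.000   5.000   6.000  1.00 50.00           P
ATOM      6  C1'  DC A   2       5.500   5.000   6.000  1.00 60.00           C
ATOM      7  C5   DC A   2       6.000   7.000   8.000  1.00 70.00           C
ATOM      8  C6   DC A   2       6.000   7.000  10.000  1.00 80.00           C
TER
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture(scope="session")
def helix_record():
    """Noise-free 147-mer with twist and B-factor modulation at 10 bp."""
    spec = HelixSpec(n_bp=147, twist_amp=2.0, period=10.0, bfactor_amp=5.0,
                     bfactor_period=10.0, seed=11)
    record, truth = build_helix(spec)
    return spec, record, truth


def make_residue(chain_id="A", seq_index=0, base="T", atoms=None):
    """Hand-build a NucleotideRecord from {name: (xyz, bfactor)}."""
    atoms = atoms or {}
    recs = {
        name: AtomRecord(name=name, position=np.asarray(xyz, float), bfactor=b)
        for name, (xyz, b) in atoms.items()
    }
    return NucleotideRecord(chain_id=chain_id, seq_index=seq_index, base=base,
                            atoms=recs)
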