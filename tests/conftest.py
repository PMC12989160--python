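import numpy as np
import pytest

from missdriver.io import AAindexEntry, ProteinSequence, StructureModel


@pytest.fixture
def toy_index1():
    """Kyte-Doolittle hydropathy as an index1 entry (real public values)."""
    values = {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    }
    return AAindexEntry(accession="KYTJ820101", kind="index1", values=values)


@pytest.fixture
def toy_index3():
    """Tiny symmetric contact-potential table used in hand-arithmetic checks."""
    cells = {("A", "Q"): 2.0, ("A", "R"): 1.0, ("C", "Q"): 5.0, ("C", "R"): 4.0,
             ("A", "C"): 3.0}
    values = {}
    for (a, b), v in cells.items():
        values[(a, b)] = v
        values[(b, a)] = v
    return AAindexEntry(accession="TOYCP00001", kind="index3", values=values)


def single_atom_residue(number, name, xyz, bfactor=90.0, atom="CA"):
    return (number, name, [(atom, xyz[0], xyz[1], xyz[2], bfactor)])


@pytest.fixture
def two_residue_model_factory():
    """StructureModel with two single-atom residues a given distance apart."""

    def make(distance, numbers=(1, 5)):
        return StructureModel(
            protein_id="toy",
            model_id="0",
            residues=[
                single_atom_residue(numbers[0], "ALA", (0.0, 0.0, 0.0)),
                single_atom_residue(numbers[1], "GLY", (distance, 0.0, 0.0)),
            ],
        )

    return make


@pytest.fixture
def helix_model():
    """A 12-residue jitter-free helical model parsed back through the reader."""
    from missdriver.io import read_structure
    from missdriver.synthgen import gen_structure

    seq = ProteinSequence("helix", "ACDEFGHIKLMN")
    text = gen_structure(seq, jitter=0.0, plddt=np.full(12, 88.0))
    import tempfile, os

    fd, path = tempfile.mkstemp(suffix=".pdb")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        return read_structure(path, protein_id="helix")[0]
    finally:
        os.unlink(path)
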