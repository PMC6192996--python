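import numpy as np
import pytest

from enzstab.synthetic import (ToyAtomSpec, ToyResidueSpec, ToyStructureSpec,
                               build_toy_structure)


def make_ca_structure(sequence, positions, b=20.0, chain_count=1, seqid_start=1):
    """Calpha-only toy structure: one residue per letter of ``sequence``."""
    residues = tuple(
        ToyResidueSpec(_three(letter), seqid_start + i,
                       (ToyAtomSpec("CA", tuple(pos), b=b),))
        for i, (letter, pos) in enumerate(zip(sequence, positions)))
    spec = ToyStructureSpec(residues=residues, chains=chain_count)
    return build_toy_structure(spec)[0]


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _three(letter):
    return _ONE_TO_THREE[letter]


def random_ca_positions(n, seed=0, spacing=3.8):
    """A meandering chain of n pseudo-Calpha positions."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(steps * spacing, axis=0)


@pytest.fixture
def active_site_wt():
    """His75 mimic: imidazole NE2 3.2 A from a Thr backbone O; the
    catalytic Glu carboxylate is out of polar-contact range."""
    spec = ToyStructureSpec(residues=(
        ToyResidueSpec("HIS", 75, (
            ToyAtomSpec("CA", (0.0, 4.0, 0.0)),
            ToyAtomSpec("NE2", (0.0, 0.0, 0.0)),
            ToyAtomSpec("ND1", (1.3, 0.8, 0.0)),
        )),
        ToyResidueSpec("THR", 116, (
            ToyAtomSpec("CA", (2.0, -5.0, 0.0)),
            ToyAtomSpec("O", (0.0, -3.2, 0.0)),       # backbone carbonyl
            ToyAtomSpec("OG1", (4.0, -6.0, 0.0)),
        )),
        ToyResidueSpec("GLU", 349, (
            ToyAtomSpec("CA", (7.0, 4.0, 0.0)),
            ToyAtomSpec("OE1", (6.0, 0.0, 0.0)),
            ToyAtomSpec("OE2", (7.2, 0.6, 0.0)),
        )),
    ), id="wt_site")
    return build_toy_structure(spec)[0]


@pytest.fixture
def active_site_variant():
    """Arg75 mimic: guanidinium NH1 2.9 A from the catalytic Glu OE1."""
    spec = ToyStructureSpec(residues=(
        ToyResidueSpec("ARG", 75, (
            ToyAtomSpec("CA", (0.0, 4.0, 0.0)),
            ToyAtomSpec("NE", (-1.0, 1.0, 0.0)),
            ToyAtomSpec("NH1", (0.0, 0.0, 0.0)),
            ToyAtomSpec("NH2", (-1.5, -0.8, 0.0)),
        )),
        ToyResidueSpec("THR", 116, (
            ToyAtomSpec("CA", (2.0, -5.0, 0.0)),
            ToyAtomSpec("O", (0.0, -3.1, 0.0)),
        )),
        ToyResidueSpec("GLU", 349, (
            ToyAtomSpec("CA", (3.5, 4.0, 0.0)),
            ToyAtomSpec("OE1", (2.9, 0.0, 0.0)),
            ToyAtomSpec("OE2", (3.8, 1.0, 0.0)),
        )),
    ), id="variant_site")
    return build_toy_structure(spec)[0]
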