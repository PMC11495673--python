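import numpy as np
import pytest

from pairsite import ModelConfig, SyntheticSpec, make_complex, make_dataset
from pairsite.structure_io import AtomRecord, ProteinStructure, ResidueRecord


def make_residue(atom_coords, seq_index=0, aa="G", chain="A", names=None, elements=None):
    """A residue from bare coordinates (helper for geometry tests)."""
    atom_coords = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    names = names or [f"C{i}" if i else "CA" for i in range(len(atom_coords))]
    elements = elements or ["C"] * len(atom_coords)
    atoms = [AtomRecord(name=n, element=e, coords=c)
             for n, e, c in zip(names, elements, atom_coords)]
    return ResidueRecord(aa_code=aa, chain_id=chain, seq_index=seq_index, atoms=atoms)


def make_backbone_residue(n, ca, c, seq_index=0, aa="A", chain="A"):
    """A residue with explicit N/CA/C backbone positions (plus an O atom)."""
    atoms = [
        AtomRecord(name="N", element="N", coords=n),
        AtomRecord(name="CA", element="C", coords=ca),
        AtomRecord(name="C", element="C", coords=c),
    ]
    return ResidueRecord(aa_code=aa, chain_id=chain, seq_index=seq_index, atoms=atoms)


def line_structure(xs, aa="G"):
    """Single-CA residues along the x axis at the given coordinates."""
    residues = [make_residue([[x, 0.0, 0.0]], seq_index=i, aa=aa)
                for i, x in enumerate(xs)]
    return ProteinStructure(residues=residues, source_id="line")


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(n_ligand=12, n_receptor=15, interface_size=3,
                         contact_distance=4.5, separation=20.0, jitter=0.2, seed=7)


@pytest.fixture(scope="session")
def fixture_complex(default_spec):
    return make_complex(default_spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Eight standardized planted-interface complexes (5/1/2 split)."""
    return make_dataset(8, seed=5, k=6, split=(0.625, 0.125, 0.25))


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(k=6, embed_dim=32, d_model=16, d_k=8, n_heads=2,
                       n_conv_layers=1, n_gat_layers=1, ffn_hidden=16,
                       dropout=0.0, seed=0, epochs=2)
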