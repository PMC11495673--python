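"""Per-residue node features: sequence embeddings + 16 physicochemical descriptors.

Every residue is described by the concatenation of (i) an embedding vector
from a protein language model and (ii) a 16-dimensional physicochemical
vector.  Twelve of those channels are sequence-level scale lookups (pinned
published scales shipped as ``data/physicochem_scales.tsv``); the remaining
four are structure-derived: solvent-accessible surface area (Shrake–Rupley,
probe 1.4 Å), relative SASA (normalized by a per-residue-type reference
maximum), side-chain volume, and residue depth (mean distance of a
residue's heavy atoms to the nearest solvent-exposed atom).

Embeddings come through a provider contract so the heavyweight language
model never has to run inside this package: precomputed matrices can be
loaded from file, and the synthetic-fixture module supplies a deterministic
surrogate for tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmbeddingError, FeatureError
from .structure_io import ProteinStructure, THREE_TO_ONE

__all__ = [
    "EmbeddingProvider",
    "PrecomputedEmbeddingProvider",
    "NodeFeatureMatrix",
    "NodeFeatureStats",
    "load_physicochem_table",
    "physicochemical_features",
    "embed_sequence",
    "assemble_node_features",
    "standardize_node_features",
    "PHYSICOCHEM_COLUMNS",
    "N_PHYSICOCHEM",
]

_DATA_DIR = Path(__file__).parent / "data"

# Fixed column order of the 16-dim physicochemical vector.
PHYSICOCHEM_COLUMNS = (
    "hydrophilicity",
    "flexibility",
    "accessibility",
    "turns",
    "exposed_surface",
    "antigenicity",
    "net_charge_index",
    "polarizability",
    "hydrophobicity_h1",
    "hydrophobicity_h2",
    "polarity_p1",
    "polarity_p2",
    "sasa",
    "relative_sasa",
    "side_chain_volume",
    "residue_depth",
)
N_PHYSICOCHEM = len(PHYSICOCHEM_COLUMNS)
_SCALE_COLUMNS = PHYSICOCHEM_COLUMNS[:12]

_EXPOSED_SASA_THRESHOLD = 0.1  # Å²; atoms above this count as solvent-exposed


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Deterministic per-residue embedding source.

    ``embed(sequence)`` must return an ``N × dim`` matrix and must return
    bitwise-identical output for identical input sequences.
    """

    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray: ...


class PrecomputedEmbeddingProvider:
    """Adapter for embedding matrices computed offline (e.g. by a 1024-dim
    protein language model) and stored in an ``.npz`` archive.

    The archive holds one array per structure id plus a companion
    ``<id>__seq`` 0-d string array so matrices can be looked up by sequence.
    """

    def __init__(self, path, name: str = "precomputed"):
        self.name = name
        self._by_seq: dict[str, np.ndarray] = {}
        with np.load(path, allow_pickle=False) as archive:
            ids = [k for k in archive.files if not k.endswith("__seq")]
            for key in ids:
                seq_key = f"{key}__seq"
                if seq_key not in archive.files:
                    raise EmbeddingError(
                        f"provider {name!r}: archive entry {key!r} has no companion sequence"
                    )
                self._by_seq[str(archive[seq_key])] = np.asarray(archive[key], dtype=float)
        if not self._by_seq:
            raise EmbeddingError(f"provider {name!r}: empty embedding archive {path}")
        dims = {m.shape[1] for m in self._by_seq.values()}
        if len(dims) != 1:
            raise EmbeddingError(f"provider {name!r}: inconsistent embedding dims {dims}")
        self.dim = dims.pop()

    def embed(self, sequence: str) -> np.ndarray:
        try:
            mat = self._by_seq[sequence]
        except KeyError:
            raise EmbeddingError(
                f"provider {self.name!r}: no precomputed embedding for sequence "
                f"of length {len(sequence)}"
            ) from None
        if mat.shape[0] != len(sequence):
            raise EmbeddingError(
                f"provider {self.name!r}: stored matrix has {mat.shape[0]} rows "
                f"for a {len(sequence)}-residue sequence"
            )
        return mat

    @staticmethod
    def save(path, entries: dict[str, tuple[str, np.ndarray]]) -> None:
        """Write ``{structure_id: (sequence, matrix)}`` to an ``.npz`` archive."""
        arrays = {}
        for sid, (seq, mat) in entries.items():
            arrays[sid] = np.asarray(mat, dtype=float)
            arrays[f"{sid}__seq"] = np.asarray(seq)
        np.savez(path, **arrays)


@dataclass
class NodeFeatureMatrix:
    """N × d_node node features: embedding columns first, then the 16
    physicochemical channels."""

    matrix: np.ndarray
    embed_dim: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("node-feature matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("node-feature matrix contains non-finite entries")
        if self.matrix.shape[1] != self.embed_dim + N_PHYSICOCHEM:
            raise ValueError(
                f"d_node must be embed_dim + {N_PHYSICOCHEM}; got "
                f"{self.matrix.shape[1]} with embed_dim {self.embed_dim}"
            )

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    @property
    def d_node(self) -> int:
        return self.matrix.shape[1]


_TABLE_CACHE: Optional[dict] = None


def load_physicochem_table() -> dict[str, dict[str, float]]:
    """Load the pinned per-amino-acid scale table: {column: {aa: value}}."""
    global _TABLE_CACHE
    if _TABLE_CACHE is not None:
        return _TABLE_CACHE
    path = _DATA_DIR / "physicochem_scales.tsv"
    table: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts[1:]
                table = {col: {} for col in header}
                continue
            aa = parts[0]
            for col, val in zip(header, parts[1:]):
                table[col][aa] = float(val)
    _TABLE_CACHE = table
    return table


def _scale_value(table: dict, col: str, aa: str) -> float:
    values = table[col]
    if aa in values:
        return values[aa]
    # unknown residue: neutral value = mean over the 20 standard amino acids
    return float(np.mean(list(values.values())))


def embed_sequence(sequence: str, provider: EmbeddingProvider) -> np.ndarray:
    """Embed a sequence through a provider; row i belongs to residue i."""
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    try:
        mat = np.asarray(provider.embed(sequence), dtype=float)
    except EmbeddingError:
        raise
    except Exception as exc:
        raise EmbeddingError(f"provider {provider.name!r} failed: {exc}") from exc
    if mat.shape != (len(sequence), provider.dim):
        raise EmbeddingError(
            f"provider {provider.name!r} returned shape {mat.shape}, "
            f"expected {(len(sequence), provider.dim)}"
        )
    return mat


def _structure_to_biotite(structure: ProteinStructure):
    import biotite.structure as bst

    atoms = []
    for res in structure.residues:
        for a in res.heavy_atoms():
            atoms.append((res, a))
    arr = bst.AtomArray(len(atoms))
    for idx, (res, a) in enumerate(atoms):
        arr.chain_id[idx] = res.chain_id or "A"
        arr.res_id[idx] = res.seq_index + 1
        arr.res_name[idx] = "UNK"
        arr.atom_name[idx] = a.name
        arr.element[idx] = a.element
        arr.coord[idx] = a.coords
    owner = np.concatenate(
        [np.full(len(r.heavy_atoms()), i) for i, r in enumerate(structure.residues)]
    )
    return arr, owner


def _sasa_per_atom(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom SASA (Å², Shrake–Rupley, probe 1.4 Å) and atom→residue map."""
    import biotite.structure as bst

    arr, owner = _structure_to_biotite(structure)
    try:
        # element-based VdW radii: robust for synthetic and real structures alike
        atom_sasa = bst.sasa(arr, probe_radius=1.4, vdw_radii="Single", point_number=200)
    except Exception as exc:
        raise FeatureError(f"SASA computation failed: {exc}") from exc
    atom_sasa = np.nan_to_num(np.asarray(atom_sasa, dtype=float), nan=0.0)
    return atom_sasa, owner


def physicochemical_features(
    structure: ProteinStructure, sasa_backend: str = "shrake_rupley"
) -> np.ndarray:
    """N × 16 physicochemical descriptor matrix in PHYSICOCHEM_COLUMNS order."""
    if sasa_backend != "shrake_rupley":
        raise ValueError(f"unknown SASA backend {sasa_backend!r}")
    table = load_physicochem_table()
    n = len(structure)

    unknown = sorted({r.aa_code for r in structure.residues} - set(THREE_TO_ONE.values()))
    if unknown:
        warnings.warn(f"unknown residue codes {unknown}: using per-scale neutral values")

    atom_sasa, owner = _sasa_per_atom(structure)
    res_sasa = np.zeros(n)
    np.add.at(res_sasa, owner, atom_sasa)

    # residue depth: mean heavy-atom distance to the nearest solvent-exposed atom
    coords = np.concatenate(
        [[a.coords for a in r.heavy_atoms()] for r in structure.residues]
    )
    exposed = coords[atom_sasa > _EXPOSED_SASA_THRESHOLD]
    depth = np.zeros(n)
    if len(exposed):
        tree = cKDTree(exposed)
        d_atom, _ = tree.query(coords)
        np.add.at(depth, owner, d_atom)
        depth /= np.bincount(owner, minlength=n)

    out = np.zeros((n, N_PHYSICOCHEM))
    for i, res in enumerate(structure.residues):
        aa = res.aa_code
        for c, col in enumerate(_SCALE_COLUMNS):
            out[i, c] = _scale_value(table, col, aa)
        out[i, 12] = res_sasa[i]
        out[i, 13] = res_sasa[i] / _scale_value(table, "max_asa", aa)
        out[i, 14] = _scale_value(table, "side_chain_volume", aa)
        out[i, 15] = depth[i]
    return out


def assemble_node_features(embedding: np.ndarray, phychem: np.ndarray) -> NodeFeatureMatrix:
    """Concatenate embedding (first) and physicochemical channels per residue."""
    embedding = np.asarray(embedding, dtype=float)
    phychem = np.asarray(phychem, dtype=float)
    if embedding.shape[0] != phychem.shape[0]:
        raise ValueError(
            f"row mismatch: embedding has {embedding.shape[0]} residues, "
            f"physicochemical features have {phychem.shape[0]}"
        )
    if phychem.shape[1] != N_PHYSICOCHEM:
        raise ValueError(f"expected {N_PHYSICOCHEM} physicochemical channels, got {phychem.shape[1]}")
    return NodeFeatureMatrix(
        matrix=np.concatenate([embedding, phychem], axis=1),
        embed_dim=embedding.shape[1],
    )


@dataclass
class NodeFeatureStats:
    """Per-channel mean/scale for node-feature standardization."""

    mean: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeFeatureStats":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


def standardize_node_features(
    matrices: Sequence[NodeFeatureMatrix],
    stats: Optional[NodeFeatureStats] = None,
) -> tuple[list[NodeFeatureMatrix], NodeFeatureStats]:
    """Center/scale each node-feature channel; fit stats when none given."""
    stacked = np.concatenate([m.matrix for m in matrices], axis=0)
    if stats is None:
        mean = stacked.mean(axis=0)
        scale = stacked.std(axis=0)
        scale[scale < 1e-12] = 1.0
        stats = NodeFeatureStats(mean=mean, scale=scale)
    out = [
        NodeFeatureMatrix(matrix=(m.matrix - stats.mean) / stats.scale, embed_dim=m.embed_dim)
        for m in matrices
    ]
    return out, stats
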