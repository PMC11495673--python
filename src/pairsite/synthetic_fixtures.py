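"""Deterministic toy two-chain complexes with planted interfaces.

The generator builds a ligand and a receptor whose residues carry idealized
backbone atoms (N, Cα, C, O) on helical templates.  A chosen block of
residues on each side is planted as the interface: every planted
ligand–receptor pair has its closest heavy atoms within ``contact_distance``
(the planted blocks sit in two tight facing rows near the origin, a
deliberately compressed — not physically realistic — arrangement that makes
the contact margins provable), while every other cross-protein residue pair
is at least ``separation`` Å away (the non-interface "tails" are standard
helices far from the origin).  The expected pair-label matrix therefore
follows analytically from the construction and is returned alongside the
structures.

Interface membership is written into the sequence: planted residues draw
their amino-acid identity from a charged/polar alphabet and tail residues
from an apolar one (with a small flip probability), so the surrogate
embedding provider — whose first channel scores that alphabet — carries a
learnable signal.  The surrogate is a test-and-demo device standing in for
a real protein language model; see docs/methods.md.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SyntheticSpecError
from .graph_features import (
    DEFAULT_CONTACT_CUTOFF,
    EdgeFeatureStats,
    PairLabels,
    build_knn_graph,
    standardize_edge_features,
)
from .model_core import ComplexSample
from .node_features import (
    NodeFeatureStats,
    assemble_node_features,
    embed_sequence,
    physicochemical_features,
    standardize_node_features,
)
from .structure_io import AtomRecord, ProteinStructure, ResidueRecord, write_pdb

__all__ = [
    "SyntheticSpec",
    "SurrogateEmbedder",
    "DatasetSplits",
    "make_complex",
    "make_dataset",
    "surrogate_embedder",
    "write_fixture",
    "INTERFACE_ALPHABET",
    "TAIL_ALPHABET",
]

INTERFACE_ALPHABET = "HKRDE"        # charged/polar: marks planted residues
TAIL_ALPHABET = "ALVIFGSTMW"        # apolar: marks tail residues

_MIN_PLANT_SPACING = 0.8  # Å between planted Cα atoms of the same protein


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic complex."""

    n_ligand: int = 12
    n_receptor: int = 15
    interface_size: int = 3
    contact_distance: float = 4.5   # Å; planted pairs end up closer than this
    separation: float = 20.0        # Å; all other cross pairs at least this far
    jitter: float = 0.2             # Å; uniform coordinate noise
    seed: int = 0
    signal_flip_prob: float = 0.1   # chance a residue draws from the wrong alphabet

    def __post_init__(self):
        if not 1 <= self.interface_size <= min(self.n_ligand, self.n_receptor):
            raise SyntheticSpecError("need counts >= interface_size >= 1")
        if not self.contact_distance < DEFAULT_CONTACT_CUTOFF < self.separation:
            raise SyntheticSpecError(
                "need contact_distance < 6 Å cutoff < separation "
                f"(got {self.contact_distance}, {self.separation})"
            )
        if self.jitter < 0:
            raise SyntheticSpecError("jitter must be non-negative")


# backbone template relative to Cα, idealized bond geometry (Å)
_TEMPLATE = {
    "N": np.array([-1.458, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.525, 1.420, 0.0]),
    "O": np.array([1.200, 1.900, 0.950]),
}


def _rotation(phi: float, psi: float) -> np.ndarray:
    """Rotation about z by phi then about x by psi."""
    cz, sz = np.cos(phi), np.sin(phi)
    cx, sx = np.cos(psi), np.sin(psi)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rx @ rz


def _residue_atoms(ca: np.ndarray, orient_index: int, rng, jitter: float) -> list[AtomRecord]:
    rot = _rotation(1.9 * orient_index, 0.7 * orient_index)
    atoms = []
    for name, offset in _TEMPLATE.items():
        coords = ca + rot @ offset
        if jitter > 0:
            coords = coords + rng.uniform(-jitter, jitter, size=3)
        element = name[0]  # N, C, O
        atoms.append(AtomRecord(name=name, element=element, coords=coords))
    return atoms


def _helix_ca(n: int, base: np.ndarray, direction: float) -> np.ndarray:
    """Cα positions of an idealized helix along ±x (rise 1.5 Å, radius 2.3 Å)."""
    t = np.arange(n, dtype=float)
    x = base[0] + direction * 1.5 * t
    y = base[1] + 2.3 * np.cos(1.745 * t)
    z = base[2] + 2.3 * np.sin(1.745 * t)
    return np.column_stack([x, y, z])


def _plant_geometry(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Cα positions for the two facing planted rows; raises if infeasible."""
    m = spec.interface_size
    allowed = spec.contact_distance - 2.0 * np.sqrt(3.0) * spec.jitter
    if allowed <= 1.0:
        raise SyntheticSpecError(
            f"jitter {spec.jitter} leaves no contact margin at "
            f"contact_distance {spec.contact_distance}"
        )
    gap = 0.6 * allowed
    spread_max = float(np.sqrt(allowed**2 - gap**2))
    spacing = spread_max / max(m - 1, 1)
    if spacing < _MIN_PLANT_SPACING:
        raise SyntheticSpecError(
            f"interface_size {m} cannot fit within the contact margin "
            f"(spacing {spacing:.2f} Å < {_MIN_PLANT_SPACING} Å)"
        )
    xs = (np.arange(m) - (m - 1) / 2.0) * spacing
    lig = np.column_stack([xs, np.full(m, -gap / 2.0), np.zeros(m)])
    rec = np.column_stack([xs, np.full(m, +gap / 2.0), np.zeros(m)])
    return lig, rec


def _sequence(n: int, planted: np.ndarray, rng, flip_prob: float) -> str:
    seq = []
    for i in range(n):
        in_iface = bool(planted[i]) ^ (rng.random() < flip_prob)
        alphabet = INTERFACE_ALPHABET if in_iface else TAIL_ALPHABET
        seq.append(alphabet[rng.integers(len(alphabet))])
    return "".join(seq)


def _build_protein(
    n: int,
    planted_ca: np.ndarray,
    block_offset: int,
    tail_base: np.ndarray,
    tail_direction: float,
    chain_id: str,
    seq: str,
    rng,
    jitter: float,
    source_id: str,
) -> tuple[ProteinStructure, np.ndarray]:
    m = len(planted_ca)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[block_offset:block_offset + m] = True
    tail_ca = _helix_ca(n - m, tail_base, tail_direction)
    residues = []
    plant_i = tail_i = 0
    for i in range(n):
        if planted_mask[i]:
            ca = planted_ca[plant_i]
            plant_i += 1
        else:
            ca = tail_ca[tail_i]
            tail_i += 1
        residues.append(
            ResidueRecord(
                aa_code=seq[i],
                chain_id=chain_id,
                seq_index=i,
                atoms=_residue_atoms(ca, orient_index=i, rng=rng, jitter=jitter),
            )
        )
    return ProteinStructure(residues=residues, source_id=source_id), planted_mask


def make_complex(
    spec: SyntheticSpec,
) -> tuple[ProteinStructure, ProteinStructure, PairLabels]:
    """Build (ligand, receptor, expected pair labels) from a spec.

    Deterministic per seed.  The expected labels are the outer product of
    the two planted-block masks; the construction is verified numerically
    against the contact/separation margins and a
    :class:`SyntheticSpecError` is raised if they cannot be met.
    """
    rng = np.random.default_rng(spec.seed)
    lig_plant, rec_plant = _plant_geometry(spec)
    m = spec.interface_size
    off_l = int(rng.integers(0, spec.n_ligand - m + 1))
    off_r = int(rng.integers(0, spec.n_receptor - m + 1))

    pad = spec.separation + 12.0
    seq_l = None  # sequences drawn after offsets so the rng stream is fixed
    lig_mask_tmp = np.zeros(spec.n_ligand, dtype=bool)
    lig_mask_tmp[off_l:off_l + m] = True
    rec_mask_tmp = np.zeros(spec.n_receptor, dtype=bool)
    rec_mask_tmp[off_r:off_r + m] = True
    seq_l = _sequence(spec.n_ligand, lig_mask_tmp, rng, spec.signal_flip_prob)
    seq_r = _sequence(spec.n_receptor, rec_mask_tmp, rng, spec.signal_flip_prob)

    ligand, lig_mask = _build_protein(
        spec.n_ligand, lig_plant, off_l,
        tail_base=np.array([-pad, 0.0, 0.0]), tail_direction=-1.0,
        chain_id="A", seq=seq_l, rng=rng, jitter=spec.jitter,
        source_id=f"synthL{spec.seed}",
    )
    receptor, rec_mask = _build_protein(
        spec.n_receptor, rec_plant, off_r,
        tail_base=np.array([pad, 0.0, 0.0]), tail_direction=+1.0,
        chain_id="B", seq=seq_r, rng=rng, jitter=spec.jitter,
        source_id=f"synthR{spec.seed}",
    )

    expected = np.outer(lig_mask, rec_mask).astype(np.int8)
    _verify_margins(ligand, receptor, lig_mask, rec_mask, spec)
    return ligand, receptor, PairLabels(matrix=expected, cutoff=DEFAULT_CONTACT_CUTOFF)


def _verify_margins(ligand, receptor, lig_mask, rec_mask, spec) -> None:
    """Check the construction actually realizes the planted geometry."""
    def _min_dist_matrix(a: ProteinStructure, b: ProteinStructure) -> np.ndarray:
        out = np.zeros((len(a), len(b)))
        coords_b = [np.array([at.coords for at in r.heavy_atoms()]) for r in b.residues]
        for i, res in enumerate(a.residues):
            ca = np.array([at.coords for at in res.heavy_atoms()])
            for j, cb in enumerate(coords_b):
                out[i, j] = cdist(ca, cb).min()
        return out

    mins = _min_dist_matrix(ligand, receptor)
    planted = np.outer(lig_mask, rec_mask)
    if (mins[planted] > spec.contact_distance).any():
        raise SyntheticSpecError("planted pairs exceed contact_distance; spec infeasible")
    if (mins[~planted] < spec.separation).any():
        raise SyntheticSpecError("non-planted pairs violate separation; spec infeasible")


# ---------------------------------------------------------------------------
# surrogate embedding provider


class SurrogateEmbedder:
    """Deterministic hash-based embedding provider (test stand-in).

    Each residue's vector is derived from a keyed hash of its identity and
    a ±2 sequence window, so identical sequences always embed identically.
    When ``spec_aware`` is true the first channel scores membership of the
    interface-prone amino-acid alphabet, carrying the planted signal the
    training loop is expected to recover.
    """

    def __init__(self, spec_aware: bool = True, dim: int = 32, seed: int = 0,
                 signal_strength: float = 2.0):
        if dim < 2:
            raise ValueError("surrogate embedder needs dim >= 2")
        self.name = f"surrogate(dim={dim}, spec_aware={spec_aware})"
        self.dim = dim
        self.spec_aware = spec_aware
        self.seed = seed
        self.signal_strength = signal_strength

    def embed(self, sequence: str) -> np.ndarray:
        out = np.empty((len(sequence), self.dim))
        padded = "--" + sequence + "--"
        for i, aa in enumerate(sequence):
            window = padded[i:i + 5]
            key = f"{self.seed}|{window}".encode()
            digest = hashlib.blake2b(key, digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            out[i] = rng.standard_normal(self.dim) * 0.5
            if self.spec_aware:
                sign = 1.0 if aa in INTERFACE_ALPHABET else -1.0
                out[i, 0] = sign * self.signal_strength + 0.1 * out[i, 0]
        return out


def surrogate_embedder(spec_aware: bool = True, dim: int = 32, seed: int = 0,
                       signal_strength: float = 2.0) -> SurrogateEmbedder:
    """Factory mirroring the provider contract."""
    return SurrogateEmbedder(spec_aware=spec_aware, dim=dim, seed=seed,
                             signal_strength=signal_strength)


# ---------------------------------------------------------------------------
# datasets


@dataclass
class DatasetSplits:
    """Disjoint train/val/test splits plus the train-fitted feature stats."""

    train: list
    val: list
    test: list
    node_stats: Optional[NodeFeatureStats] = None
    edge_stats: Optional[EdgeFeatureStats] = None


def _sample_from_structures(
    complex_id, ligand, receptor, labels, k, embedder
) -> ComplexSample:
    from .structure_io import extract_sequence

    lg = build_knn_graph(ligand, k=k)
    rg = build_knn_graph(receptor, k=k)
    lf = assemble_node_features(
        embed_sequence(extract_sequence(ligand), embedder),
        physicochemical_features(ligand),
    )
    rf = assemble_node_features(
        embed_sequence(extract_sequence(receptor), embedder),
        physicochemical_features(receptor),
    )
    return ComplexSample(
        complex_id=complex_id,
        ligand_graph=lg, ligand_features=lf,
        receptor_graph=rg, receptor_features=rf,
        pair_labels=labels,
    )


def make_dataset(
    n_complexes: int,
    spec_template: Optional[SyntheticSpec] = None,
    seed: int = 0,
    k: int = 6,
    embedder=None,
    split: Sequence[float] = (0.6, 0.2, 0.2),
    standardize: bool = True,
) -> DatasetSplits:
    """Generate a split synthetic dataset of planted-interface complexes.

    Residue counts vary by ±3 around the template per complex; per-complex
    seeds derive from the master seed.  Feature-standardization statistics
    are fitted on the training split only and applied to all splits;
    class ratios in val/test are left untouched (no downsampling here).
    """
    if n_complexes < 3:
        raise ValueError("need at least 3 complexes to split")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    template = spec_template or SyntheticSpec()
    embedder = embedder or surrogate_embedder(seed=seed)

    samples = []
    for i in range(n_complexes):
        rng = np.random.default_rng([seed, i])
        spec_i = replace(
            template,
            n_ligand=template.n_ligand + int(rng.integers(-3, 4)),
            n_receptor=template.n_receptor + int(rng.integers(-3, 4)),
            seed=int(rng.integers(2**31)),
        )
        ligand, receptor, labels = make_complex(spec_i)
        samples.append(
            _sample_from_structures(f"cpx{i:03d}", ligand, receptor, labels, k, embedder)
        )

    n_train = int(round(split[0] * n_complexes))
    n_val = int(round(split[1] * n_complexes))
    train = samples[:n_train]
    val = samples[n_train:n_train + n_val]
    test = samples[n_train + n_val:]

    node_stats = edge_stats = None
    if standardize and train:
        _, node_stats = standardize_node_features([s.ligand_features for s in train]
                                                  + [s.receptor_features for s in train])
        _, edge_stats = standardize_edge_features([s.ligand_graph for s in train]
                                                  + [s.receptor_graph for s in train])
        for subset in (train, val, test):
            for s in subset:
                [s.ligand_features, s.receptor_features], _ = standardize_node_features(
                    [s.ligand_features, s.receptor_features], node_stats
                )
                [s.ligand_graph, s.receptor_graph], _ = standardize_edge_features(
                    [s.ligand_graph, s.receptor_graph], edge_stats
                )
    return DatasetSplits(train=train, val=val, test=test,
                         node_stats=node_stats, edge_stats=edge_stats)


def write_fixture(spec: SyntheticSpec, out_dir) -> None:
    """Write ligand.pdb, receptor.pdb and the expected labels as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ligand, receptor, labels = make_complex(spec)
    write_pdb(ligand, out_dir / "ligand.pdb")
    write_pdb(receptor, out_dir / "receptor.pdb")
    np.savetxt(out_dir / "expected_labels.tsv", labels.matrix, fmt="%d", delimiter="\t")
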