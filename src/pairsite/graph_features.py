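"""Residue graphs, edge features, and ground-truth interaction labels.

Each protein becomes a directed k-nearest-neighbor graph: node = residue,
and every residue receives edges from its k closest residues, where
closeness is the mean of all heavy-atom pair distances between the two
residues.  Every edge carries two features: that mean distance D (Å) and
the relative orientation θ (radians) between the residues' backbone planes
— the planes through each residue's N, Cα and carbonyl C atoms.  θ is the
arccos of the absolute normal dot product, so it lives in [0, π/2] and is
insensitive to the sign ambiguity of a plane normal.

Two residues of a complex are labeled as interacting when any pair of their
non-hydrogen atoms lies within the contact cutoff (6 Å by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, FeatureError, GraphError
from .structure_io import ProteinStructure, ResidueRecord

__all__ = [
    "ResidueGraph",
    "PairLabels",
    "EdgeFeatureStats",
    "mean_residue_distance",
    "residue_plane_normal",
    "relative_orientation",
    "build_knn_graph",
    "label_interactions",
    "interface_labels",
    "standardize_edge_features",
    "write_graph_tsv",
    "read_graph_tsv",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 6.0  # Å, non-hydrogen atoms
_COLLINEARITY_TOL = 1e-8


@dataclass
class ResidueGraph:
    """Directed k-NN residue graph with 2-dim edge features.

    ``edges[e] = (source j, target i)`` — information flows j → i, and every
    node has in-degree ``min(k, n_nodes - 1)``.  ``edge_features[e]`` is
    ``(D_ij, θ_ij)``.  ``degenerate_nodes`` lists residues whose backbone
    plane is undefined (missing N/Cα/C or collinear); their edges carry the
    graph-mean orientation instead.
    """

    n_nodes: int
    edges: np.ndarray          # (E, 2) int, columns (source, target)
    edge_features: np.ndarray  # (E, 2) float, columns (distance, orientation)
    k: int
    degenerate_nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=float).reshape(-1, 2)
        if len(self.edges) != len(self.edge_features):
            raise GraphError("edge and edge-feature counts differ")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg


@dataclass
class PairLabels:
    """Binary interaction labels: rows = ligand residues, cols = receptor."""

    matrix: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("pair-label matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("pair labels must be binary")

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def n_positive(self) -> int:
        return int(self.matrix.sum())


def _atom_coords(res: ResidueRecord, atom_filter: str) -> np.ndarray:
    if atom_filter == "heavy":
        atoms = res.heavy_atoms()
    elif atom_filter == "all":
        atoms = res.atoms
    else:
        raise ValueError(f"unknown atom filter {atom_filter!r}")
    if not atoms:
        raise FeatureError(
            f"residue {res.seq_index} ({res.aa_code}, chain {res.chain_id}): "
            f"no atoms pass filter {atom_filter!r}"
        )
    return np.array([a.coords for a in atoms], dtype=float)


def mean_residue_distance(
    r1: ResidueRecord, r2: ResidueRecord, atom_filter: str = "heavy"
) -> float:
    """Mean Euclidean distance over all selected atom pairs of two residues."""
    c1 = _atom_coords(r1, atom_filter)
    c2 = _atom_coords(r2, atom_filter)
    return float(cdist(c1, c2).mean())


def residue_plane_normal(res: ResidueRecord) -> np.ndarray:
    """Unit normal of the backbone plane through N, Cα and carbonyl C.

    Raises :class:`DegenerateGeometryError` when an atom is missing or the
    three atoms are collinear; callers substitute the graph-mean orientation.
    """
    pts = []
    for name in ("N", "CA", "C"):
        atom = res.get_atom(name)
        if atom is None:
            raise DegenerateGeometryError(
                f"residue {res.seq_index} ({res.aa_code}): missing backbone atom {name}"
            )
        pts.append(atom.coords)
    n_at, ca, c_at = pts
    normal = np.cross(n_at - ca, c_at - ca)
    norm = np.linalg.norm(normal)
    if norm < _COLLINEARITY_TOL:
        raise DegenerateGeometryError(
            f"residue {res.seq_index} ({res.aa_code}): collinear backbone atoms"
        )
    return normal / norm


def relative_orientation(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Angle in [0, π/2] between the two backbone-plane normals.

    Uses arccos of the absolute dot product, so anti-parallel normals give 0
    (plane normals are only defined up to sign).
    """
    n1 = residue_plane_normal(r1)
    n2 = residue_plane_normal(r2)
    return float(np.arccos(np.clip(abs(float(n1 @ n2)), 0.0, 1.0)))


def _mean_distance_matrix(structure: ProteinStructure, atom_filter: str) -> np.ndarray:
    """All-against-all mean residue distance, vectorized over atoms."""
    coords = []
    owner = []
    for i, res in enumerate(structure.residues):
        c = _atom_coords(res, atom_filter)
        coords.append(c)
        owner.append(np.full(len(c), i))
    allc = np.concatenate(coords)
    owner = np.concatenate(owner)
    n = len(structure)
    atom_d = cdist(allc, allc)
    sums = np.zeros((n, n))
    np.add.at(sums, (owner[:, None], owner[None, :]), atom_d)
    counts = np.bincount(owner, minlength=n).astype(float)
    return sums / (counts[:, None] * counts[None, :])


def build_knn_graph(
    structure: ProteinStructure, k: int, atom_filter: str = "heavy"
) -> ResidueGraph:
    """Directed k-NN graph by mean residue distance with (D, θ) edge features.

    Each node i receives edges from its ``min(k, N-1)`` nearest residues;
    equidistant candidates are broken toward the lower ``seq_index``.
    """
    n = len(structure)
    if n < 2:
        raise GraphError(f"need at least 2 residues to build a graph, got {n}")
    if k < 1:
        raise GraphError(f"k must be >= 1, got {k}")
    dmat = _mean_distance_matrix(structure, atom_filter)

    normals: list[Optional[np.ndarray]] = []
    degenerate = []
    for res in structure.residues:
        try:
            normals.append(residue_plane_normal(res))
        except DegenerateGeometryError:
            normals.append(None)
            degenerate.append(res.seq_index)

    k_eff = min(k, n - 1)
    edges = []
    dists = []
    for i in range(n):
        order = np.arange(n)
        cand = np.delete(order, i)
        # stable sort on distance keeps lower seq_index first on ties
        nearest = cand[np.argsort(dmat[i, cand], kind="stable")][:k_eff]
        for j in nearest:
            edges.append((j, i))
            dists.append(dmat[i, j])
    edges = np.array(edges, dtype=np.intp)
    dists = np.array(dists)

    thetas = np.full(len(edges), np.nan)
    for e, (j, i) in enumerate(edges):
        ni, nj = normals[i], normals[j]
        if ni is not None and nj is not None:
            thetas[e] = np.arccos(np.clip(abs(float(ni @ nj)), 0.0, 1.0))
    if np.isnan(thetas).any():
        fill = float(np.nanmean(thetas)) if not np.isnan(thetas).all() else 0.0
        thetas = np.where(np.isnan(thetas), fill, thetas)

    return ResidueGraph(
        n_nodes=n,
        edges=edges,
        edge_features=np.column_stack([dists, thetas]),
        k=k,
        degenerate_nodes=frozenset(degenerate),
    )


def label_interactions(
    ligand: ProteinStructure,
    receptor: ProteinStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> PairLabels:
    """Binary N_ligand × N_receptor contact map at the heavy-atom cutoff.

    Entry (i, j) is 1 iff the minimum non-hydrogen inter-atom distance
    between ligand residue i and receptor residue j is ≤ ``cutoff`` Å.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    lig_coords, lig_owner, lig_empty = _heavy_coords(ligand)
    rec_coords, rec_owner, rec_empty = _heavy_coords(receptor)
    for side, empties in (("ligand", lig_empty), ("receptor", rec_empty)):
        if empties:
            warnings.warn(
                f"{side} residues {sorted(empties)} have no non-hydrogen atoms; labeled 0"
            )
    n_l, n_r = len(ligand), len(receptor)
    matrix = np.zeros((n_l, n_r), dtype=np.int8)
    if len(lig_coords) and len(rec_coords):
        mins = np.full((n_l, n_r), np.inf)
        atom_d = cdist(lig_coords, rec_coords)
        np.minimum.at(mins, (lig_owner[:, None], rec_owner[None, :]), atom_d)
        matrix[mins <= cutoff] = 1
    return PairLabels(matrix=matrix, cutoff=float(cutoff))


def _heavy_coords(structure: ProteinStructure):
    coords, owner, empty = [], [], []
    for i, res in enumerate(structure.residues):
        heavy = res.heavy_atoms()
        if not heavy:
            empty.append(i)
            continue
        coords.extend(a.coords for a in heavy)
        owner.extend([i] * len(heavy))
    return np.array(coords, dtype=float).reshape(-1, 3), np.array(owner, dtype=np.intp), empty


def interface_labels(labels: PairLabels) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue interface membership: (ligand vector, receptor vector).

    A residue is part of the interface when it interacts with at least one
    residue of the partner protein.
    """
    lig = labels.matrix.any(axis=1).astype(np.int8)
    rec = labels.matrix.any(axis=0).astype(np.int8)
    return lig, rec


@dataclass
class EdgeFeatureStats:
    """Per-channel mean/scale used to standardize (D, θ) edge features."""

    mean: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "EdgeFeatureStats":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


def standardize_edge_features(
    graphs: Sequence[ResidueGraph],
    stats: Optional[EdgeFeatureStats] = None,
) -> tuple[list[ResidueGraph], EdgeFeatureStats]:
    """Center/scale each edge-feature channel; fit stats when none given.

    Stats fitted on a training set should be reused at prediction time;
    re-standardizing already-standardized graphs with freshly fitted stats
    is NOT a no-op and is the caller's responsibility to avoid.
    """
    all_feats = np.concatenate([g.edge_features for g in graphs], axis=0)
    if len(all_feats) == 0:
        raise FeatureError("no edges to standardize")
    if stats is None:
        mean = all_feats.mean(axis=0)
        scale = all_feats.std(axis=0)
        for c in range(scale.size):
            if scale[c] < 1e-12:
                warnings.warn(f"edge-feature channel {c} has zero variance; scale set to 1")
                scale[c] = 1.0
        stats = EdgeFeatureStats(mean=mean, scale=scale)
    out = []
    for g in graphs:
        feats = (g.edge_features - stats.mean) / stats.scale
        out.append(
            ResidueGraph(
                n_nodes=g.n_nodes,
                edges=g.edges.copy(),
                edge_features=feats,
                k=g.k,
                degenerate_nodes=g.degenerate_nodes,
            )
        )
    return out, stats


# -- tabular export ---------------------------------------------------------

def write_graph_tsv(graph: ResidueGraph, structure: ProteinStructure, out_dir) -> None:
    """Write ``edges.tsv`` (source, target, distance, orientation) and
    ``nodes.tsv`` (seq_index, chain_id, aa_code, degenerate) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("source\ttarget\tdistance\torientation\n")
        for (j, i), (d, t) in zip(graph.edges, graph.edge_features):
            fh.write(f"{j}\t{i}\t{d:.6f}\t{t:.6f}\n")
    with open(out_dir / "nodes.tsv", "w") as fh:
        fh.write("seq_index\tchain_id\taa_code\tdegenerate\n")
        for res in structure.residues:
            flag = int(res.seq_index in graph.degenerate_nodes)
            fh.write(f"{res.seq_index}\t{res.chain_id}\t{res.aa_code}\t{flag}\n")


def read_graph_tsv(in_dir, k: int) -> ResidueGraph:
    """Read a graph written by :func:`write_graph_tsv`."""
    in_dir = Path(in_dir)
    edges, feats = [], []
    with open(in_dir / "edges.tsv") as fh:
        next(fh)
        for line in fh:
            s, t, d, o = line.rstrip("\n").split("\t")
            edges.append((int(s), int(t)))
            feats.append((float(d), float(o)))
    degenerate = []
    n_nodes = 0
    with open(in_dir / "nodes.tsv") as fh:
        next(fh)
        for line in fh:
            idx, _chain, _aa, flag = line.rstrip("\n").split("\t")
            n_nodes += 1
            if int(flag):
                degenerate.append(int(idx))
    return ResidueGraph(
        n_nodes=n_nodes,
        edges=np.array(edges, dtype=np.intp),
        edge_features=np.array(feats, dtype=float),
        k=k,
        degenerate_nodes=frozenset(degenerate),
    )
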