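"""The pair-interaction network.

Two proteins are encoded by one shared-weight (Siamese) encoder — a stack of
1-D convolutions over the residue sequence followed by edge-aggregated graph
attention layers over the k-NN residue graph.  Sinusoidal positional
encodings are added, a multi-head cross-attention block exchanges
information between the partners (queries from one protein, keys/values
from the other, shared projection weights), and two output heads produce

* a pairwise interaction probability for every (ligand, receptor) residue
  pair, averaged over both concatenation orders so the prediction is
  invariant to which protein is called ligand; and
* a per-residue interface probability for each protein.

Everything runs on the package's numpy autodiff engine in float64, so a
fixed seed makes initialization, training, and evaluation exactly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from ._autograd import (
    Adam,
    Parameter,
    Tensor,
    concat,
    segment_softmax,
    segment_sum,
    softmax_rows,
)
from .graph_features import EdgeFeatureStats, PairLabels, ResidueGraph, interface_labels
from .node_features import N_PHYSICOCHEM, NodeFeatureMatrix, NodeFeatureStats

__all__ = [
    "ModelConfig",
    "ComplexSample",
    "PredictionResult",
    "PairInteractionModel",
    "positional_encoding",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
    "export_attention_tsv",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training loop.

    ``d_k`` defaults to ``d_model // n_heads`` so the concatenated heads
    match the model width.  ``pe_convention`` selects between the sinusoidal
    positional-encoding exponent ``i/d_model`` with 1-based dimension index
    (``"as_printed"``, the default) and the common ``2i/d_model`` variant
    (``"standard"``).
    """

    k: int = 10                      # k-NN neighbor count
    embed_dim: int = 32              # embedding provider dimensionality
    d_model: int = 32                # hidden width of the encoder
    d_k: Optional[int] = None        # per-head attention projection dim
    n_heads: int = 2
    n_conv_layers: int = 2
    n_gat_layers: int = 2
    ffn_hidden: int = 64
    conv_kernel: int = 3
    dropout: float = 0.1
    leaky_slope: float = 0.2
    seed: int = 0
    use_phychem: bool = True
    use_edge_features: bool = True
    use_positional: bool = True
    pe_convention: str = "as_printed"
    # training
    lr: float = 1e-3
    epochs: int = 40
    neg_ratio: int = 10              # negatives per positive during training
    resample_each_epoch: bool = True
    pairwise_loss_weight: float = 1.0
    interface_loss_weight: float = 1.0
    contact_cutoff: float = 6.0

    def __post_init__(self):
        if self.d_k is None:
            self.d_k = max(1, self.d_model // self.n_heads)
        for name in ("k", "embed_dim", "d_model", "d_k", "n_heads",
                     "n_conv_layers", "n_gat_layers", "ffn_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pe_convention not in ("as_printed", "standard"):
            raise ValueError(f"unknown pe_convention {self.pe_convention!r}")

    @property
    def d_node(self) -> int:
        return self.embed_dim + (N_PHYSICOCHEM if self.use_phychem else 0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ComplexSample:
    """One two-protein complex ready for the network."""

    complex_id: str
    ligand_graph: ResidueGraph
    ligand_features: NodeFeatureMatrix
    receptor_graph: ResidueGraph
    receptor_features: NodeFeatureMatrix
    pair_labels: PairLabels
    interface_l: np.ndarray = field(default=None)
    interface_r: np.ndarray = field(default=None)

    def __post_init__(self):
        n_l, n_r = self.pair_labels.shape
        if n_l != self.ligand_graph.n_nodes or n_l != self.ligand_features.n_residues:
            raise ValueError(f"{self.complex_id}: ligand label/graph/feature sizes differ")
        if n_r != self.receptor_graph.n_nodes or n_r != self.receptor_features.n_residues:
            raise ValueError(f"{self.complex_id}: receptor label/graph/feature sizes differ")
        lig, rec = interface_labels(self.pair_labels)
        if self.interface_l is None:
            self.interface_l = lig
        elif not np.array_equal(np.asarray(self.interface_l), lig):
            raise ValueError(f"{self.complex_id}: interface labels inconsistent with pair labels")
        if self.interface_r is None:
            self.interface_r = rec
        elif not np.array_equal(np.asarray(self.interface_r), rec):
            raise ValueError(f"{self.complex_id}: interface labels inconsistent with pair labels")

    def swapped(self) -> "ComplexSample":
        """The same complex with receptor and ligand roles exchanged."""
        return ComplexSample(
            complex_id=self.complex_id + "_swapped",
            ligand_graph=self.receptor_graph,
            ligand_features=self.receptor_features,
            receptor_graph=self.ligand_graph,
            receptor_features=self.ligand_features,
            pair_labels=PairLabels(self.pair_labels.matrix.T, self.pair_labels.cutoff),
        )


@dataclass
class PredictionResult:
    """Model outputs for one complex."""

    pair_probs: np.ndarray          # N_l × N_r in (0, 1)
    interface_probs_l: np.ndarray   # length N_l
    interface_probs_r: np.ndarray   # length N_r
    attention: dict                 # {"ligand_to_receptor": [per-head N_l × N_r], ...}

    def __post_init__(self):
        for arr in (self.pair_probs, self.interface_probs_l, self.interface_probs_r):
            if not ((arr > 0.0) & (arr < 1.0)).all():
                raise ValueError("probabilities must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# building blocks


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape if shape is not None else (fan_in, fan_out))


class _Linear:
    def __init__(self, rng, d_in, d_out, bias=True):
        self.W = Parameter(_glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class _Conv1dSame:
    """Same-padded 1-D convolution along the residue axis."""

    def __init__(self, rng, d_in, d_out, kernel):
        if kernel % 2 != 1:
            raise ValueError("conv kernel must be odd for same padding")
        self.kernel = kernel
        self.taps = [Parameter(_glorot(rng, d_in * kernel, d_out, shape=(d_in, d_out)))
                     for _ in range(kernel)]
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        n, d_in = x.shape
        half = self.kernel // 2
        pad = Tensor(np.zeros((half, d_in)))
        xp = concat([pad, x, pad], axis=0)
        out = None
        base = np.arange(n)
        for o, W in enumerate(self.taps):
            term = xp.gather_rows(base + o) @ W
            out = term if out is None else out + term
        return out + self.b

    def params(self):
        return list(self.taps) + [self.b]


class _LayerNorm:
    def __init__(self, d, eps=1e-5):
        self.g = Parameter(np.ones(d))
        self.b = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.g + self.b

    def params(self):
        return [self.g, self.b]


class _EdgeGATLayer:
    """Edge-aggregated graph attention over a directed edge list.

    For each edge j→i the attention logit is
    ``LeakyReLU(a · [W h_i ‖ W h_j ‖ W_e ξ_ji])``; coefficients are
    softmax-normalized over node i's in-neighborhood and the aggregated
    message is ``Σ_j α_ji (W h_j + W_e ξ_ji)``.  Nodes without in-edges pass
    through their own transformed features.
    """

    def __init__(self, rng, d, edge_dim, use_edge_features, leaky_slope):
        self.use_edges = use_edge_features
        self.slope = leaky_slope
        self.W = Parameter(_glorot(rng, d, d))
        self.We = Parameter(_glorot(rng, edge_dim, d)) if use_edge_features else None
        a_dim = 3 * d if use_edge_features else 2 * d
        self.a = Parameter(_glorot(rng, a_dim, 1))

    def __call__(self, h: Tensor, graph: ResidueGraph):
        n = graph.n_nodes
        wh = h @ self.W
        if graph.n_edges == 0:
            return wh, np.zeros(0), np.zeros(0, dtype=np.intp)
        src = graph.edges[:, 0]
        tgt = graph.edges[:, 1]
        wh_i = wh.gather_rows(tgt)
        wh_j = wh.gather_rows(src)
        parts = [wh_i, wh_j]
        if self.use_edges:
            we = Tensor(graph.edge_features) @ self.We
            parts.append(we)
        logits = (concat(parts, axis=1) @ self.a).reshape(-1).leaky_relu(self.slope)
        alpha = segment_softmax(logits, tgt, n)
        msg = wh_j + we if self.use_edges else wh_j
        agg = segment_sum(msg * alpha.reshape(-1, 1), tgt, n)
        deg = graph.in_degree()
        if (deg == 0).any():  # isolated nodes: self passthrough
            mask = Tensor((deg == 0).astype(float).reshape(-1, 1))
            agg = agg + wh * mask
        return agg, alpha, tgt

    def params(self):
        p = [self.W, self.a]
        if self.We is not None:
            p.append(self.We)
        return p


class _FFN:
    """Two hidden layers (ReLU then LeakyReLU) and a final linear logit."""

    def __init__(self, rng, d_in, hidden, slope):
        self.l1 = _Linear(rng, d_in, hidden)
        self.l2 = _Linear(rng, hidden, hidden)
        self.l3 = _Linear(rng, hidden, 1)
        self.slope = slope

    def __call__(self, x: Tensor, dropout: float = 0.0, rng=None) -> Tensor:
        h = self.l1(x).relu()
        h = _dropout(h, dropout, rng)
        h = self.l2(h).leaky_relu(self.slope)
        h = _dropout(h, dropout, rng)
        return self.l3(h).reshape(-1)

    def params(self):
        return self.l1.params() + self.l2.params() + self.l3.params()


def _dropout(x: Tensor, rate: float, rng) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate).astype(float) / (1.0 - rate)
    return x * Tensor(mask)


def positional_encoding(length: int, d_model: int, convention: str = "as_printed") -> np.ndarray:
    """Sinusoidal positional encodings, shape ``length × d_model``.

    With the default convention the dimension index i is 1-based and the
    frequency exponent is ``i/d_model`` for even i and ``(i-1)/d_model`` for
    odd i; entries are ``sin`` for even i and ``cos`` for odd i.  The
    ``"standard"`` convention uses the usual paired ``2i/d_model`` exponent.
    """
    if length < 1 or d_model < 1:
        raise ValueError("length and d_model must be >= 1")
    pos = np.arange(length, dtype=float)[:, None]
    pe = np.zeros((length, d_model))
    if convention == "as_printed":
        i = np.arange(1, d_model + 1, dtype=float)
        even = i % 2 == 0
        expo = np.where(even, i / d_model, (i - 1.0) / d_model)
        angle = pos / (10000.0 ** expo)[None, :]
        pe[:, even] = np.sin(angle[:, even])
        pe[:, ~even] = np.cos(angle[:, ~even])
    elif convention == "standard":
        i = np.arange(d_model, dtype=float)
        angle = pos / 10000.0 ** (2.0 * (i // 2) / d_model)[None, :]
        pe[:, 0::2] = np.sin(angle[:, 0::2])
        pe[:, 1::2] = np.cos(angle[:, 1::2])
    else:
        raise ValueError(f"unknown positional-encoding convention {convention!r}")
    return pe


class _CrossAttention:
    """Multi-head cross-attention with residual connection + layer norm.

    Projection weights are shared between the two proteins; each protein
    attends over the other (queries from itself, keys/values from the
    partner), heads are concatenated and projected back to ``d_model``.
    """

    def __init__(self, rng, d_model, d_k, n_heads, leaky_slope):
        self.d_k = d_k
        self.heads = [
            dict(
                Wq=Parameter(_glorot(rng, d_model, d_k)),
                Wk=Parameter(_glorot(rng, d_model, d_k)),
                Wv=Parameter(_glorot(rng, d_model, d_k)),
            )
            for _ in range(n_heads)
        ]
        self.Wo = Parameter(_glorot(rng, n_heads * d_k, d_model))
        self.norm = _LayerNorm(d_model)

    def _attend(self, P_self: Tensor, P_other: Tensor):
        outs, attns = [], []
        scale = 1.0 / np.sqrt(self.d_k)
        for head in self.heads:
            q = P_self @ head["Wq"]
            k = P_other @ head["Wk"]
            v = P_other @ head["Wv"]
            attn = softmax_rows((q @ k.T) * scale)
            outs.append(attn @ v)
            attns.append(attn)
        multi = concat(outs, axis=1) @ self.Wo
        return self.norm(P_self + multi), attns

    def __call__(self, P_l: Tensor, P_r: Tensor):
        M_l, attn_lr = self._attend(P_l, P_r)   # ligand attends over receptor
        M_r, attn_rl = self._attend(P_r, P_l)
        return M_l, M_r, {"ligand_to_receptor": attn_lr, "receptor_to_ligand": attn_rl}

    def params(self):
        p = []
        for head in self.heads:
            p.extend(head.values())
        p.append(self.Wo)
        p.extend(self.norm.params())
        return p


# ---------------------------------------------------------------------------
# the full model


class PairInteractionModel:
    """Siamese graph encoder + cross-attention + two classification heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        self.convs = []
        d_in = config.d_node
        for _ in range(config.n_conv_layers):
            self.convs.append(_Conv1dSame(rng, d_in, d, config.conv_kernel))
            d_in = d
        self.gat_layers = [
            _EdgeGATLayer(rng, d, edge_dim=2, use_edge_features=config.use_edge_features,
                          leaky_slope=config.leaky_slope)
            for _ in range(config.n_gat_layers)
        ]
        self.cross = _CrossAttention(rng, d, config.d_k, config.n_heads, config.leaky_slope)
        self.pair_ffn = _FFN(rng, 2 * d, config.ffn_hidden, config.leaky_slope)
        self.iface_ffn = _FFN(rng, d, config.ffn_hidden, config.leaky_slope)

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        p = []
        for c in self.convs:
            p.extend(c.params())
        for g in self.gat_layers:
            p.extend(g.params())
        p.extend(self.cross.params())
        p.extend(self.pair_ffn.params())
        p.extend(self.iface_ffn.params())
        return p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward ------------------------------------------------------------
    def _input_matrix(self, feats: NodeFeatureMatrix) -> Tensor:
        x = feats.matrix
        if not self.config.use_phychem:
            x = x[:, : feats.embed_dim]
        if x.shape[1] != self.config.d_node:
            raise ValueError(
                f"node features have {x.shape[1]} columns, config expects {self.config.d_node}"
            )
        return Tensor(x)

    def local_feature_extractor(self, feats: NodeFeatureMatrix,
                                dropout_rng=None) -> Tensor:
        """Stack of same-padded 1-D convolutions along the sequence."""
        h = self._input_matrix(feats)
        rate = self.config.dropout if dropout_rng is not None else 0.0
        for conv in self.convs:
            h = conv(h).relu()
            h = _dropout(h, rate, dropout_rng)
        return h

    def gat_stack(self, h: Tensor, graph: ResidueGraph, collect_attention=None) -> Tensor:
        """Graph-attention layers with residual connections between layers."""
        for layer in self.gat_layers:
            out, alpha, tgt = layer(h, graph)
            if collect_attention is not None:
                collect_attention.append((alpha.data.copy(), tgt.copy()))
            h = h + out
        return h

    def encode(self, graph: ResidueGraph, feats: NodeFeatureMatrix,
               dropout_rng=None, collect_attention=None) -> Tensor:
        h = self.local_feature_extractor(feats, dropout_rng)
        return self.gat_stack(h, graph, collect_attention)

    def siamese_encode(self, receptor, ligand, dropout_rng=None):
        """Encode both proteins with the shared encoder; returns (H_r, H_l)."""
        rg, rf = receptor
        lg, lf = ligand
        return self.encode(rg, rf, dropout_rng), self.encode(lg, lf, dropout_rng)

    def _positional(self, h: Tensor) -> Tensor:
        if not self.config.use_positional:
            return h
        pe = positional_encoding(h.shape[0], self.config.d_model, self.config.pe_convention)
        return h + Tensor(pe)

    def forward_tensors(self, sample: ComplexSample, dropout_rng=None):
        """Full forward pass keeping the autodiff tape.

        Returns pair probabilities (flat, row-major over the N_l × N_r
        grid), the two interface probability vectors, and the per-head
        cross-attention matrices.
        """
        H_r, H_l = self.siamese_encode(
            (sample.receptor_graph, sample.receptor_features),
            (sample.ligand_graph, sample.ligand_features),
            dropout_rng,
        )
        P_l = self._positional(H_l)
        P_r = self._positional(H_r)
        M_l, M_r, attn = self.cross(P_l, P_r)

        n_l, n_r = sample.pair_labels.shape
        idx_l = np.repeat(np.arange(n_l), n_r)
        idx_r = np.tile(np.arange(n_r), n_l)
        ml = M_l.gather_rows(idx_l)
        mr = M_r.gather_rows(idx_r)
        rate = self.config.dropout if dropout_rng is not None else 0.0
        o_rl = self.pair_ffn(concat([mr, ml], axis=1), rate, dropout_rng).sigmoid()
        o_lr = self.pair_ffn(concat([ml, mr], axis=1), rate, dropout_rng).sigmoid()
        pair_probs = (o_rl + o_lr) * 0.5

        iface_l = self.iface_ffn(M_l, rate, dropout_rng).sigmoid()
        iface_r = self.iface_ffn(M_r, rate, dropout_rng).sigmoid()
        return pair_probs, iface_l, iface_r, attn

    def predict(self, sample: ComplexSample) -> PredictionResult:
        """Deterministic evaluation-mode forward pass."""
        pair, il, ir, attn = self.forward_tensors(sample, dropout_rng=None)
        n_l, n_r = sample.pair_labels.shape
        return PredictionResult(
            pair_probs=pair.data.reshape(n_l, n_r).copy(),
            interface_probs_l=il.data.copy(),
            interface_probs_r=ir.data.copy(),
            attention={
                key: [a.data.copy() for a in mats] for key, mats in attn.items()
            },
        )


def forward(sample: ComplexSample, model: PairInteractionModel) -> PredictionResult:
    """Evaluate the full pipeline on one complex (evaluation mode)."""
    return model.predict(sample)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path,
    model: PairInteractionModel,
    node_stats: Optional[NodeFeatureStats] = None,
    edge_stats: Optional[EdgeFeatureStats] = None,
    history: Optional[dict] = None,
) -> None:
    """One archive holding config, parameters, and standardization stats."""
    meta = {
        "config": model.config.to_dict(),
        "node_stats": node_stats.to_dict() if node_stats else None,
        "edge_stats": edge_stats.to_dict() if edge_stats else None,
        "history": history,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    arrays["meta_json"] = np.asarray(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Returns (model, node_stats, edge_stats, history)."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta_json"]))
        model = PairInteractionModel(ModelConfig.from_dict(meta["config"]))
        params = model.params()
        for i, p in enumerate(params):
            stored = archive[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} has shape {stored.shape}")
            p.data = stored.astype(np.float64)
    node_stats = NodeFeatureStats.from_dict(meta["node_stats"]) if meta["node_stats"] else None
    edge_stats = EdgeFeatureStats.from_dict(meta["edge_stats"]) if meta["edge_stats"] else None
    return model, node_stats, edge_stats, meta.get("history")


def export_attention_tsv(result: PredictionResult, out_dir) -> None:
    """Write each cross-attention head as a TSV matrix for inspection."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for direction, mats in result.attention.items():
        for h, mat in enumerate(mats):
            np.savetxt(out_dir / f"attention_{direction}_head{h}.tsv", mat,
                       delimiter="\t", fmt="%.6g")
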