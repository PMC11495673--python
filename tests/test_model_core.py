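import numpy as np
import pytest

from pairsite._autograd import Tensor
from pairsite.graph_features import ResidueGraph
from pairsite.model_core import (
    ComplexSample,
    ModelConfig,
    PairInteractionModel,
    forward,
    load_checkpoint,
    positional_encoding,
    save_checkpoint,
)


@pytest.fixture()
def model(tiny_config):
    return PairInteractionModel(tiny_config)


# -- positional encoding ----------------------------------------------------

def test_positional_encoding_at_origin():
    pe = positional_encoding(3, 6)
    # 1-based dimension index: odd i → cos → 1 at pos 0; even i → sin → 0
    assert np.allclose(pe[0, 0::2], 1.0)   # columns for i = 1, 3, 5
    assert np.allclose(pe[0, 1::2], 0.0)   # columns for i = 2, 4, 6
    assert (np.abs(pe) <= 1.0).all()


def test_positional_encoding_printed_convention_value():
    # pos=1, dimension i=2, d_model=4 → sin(1 / 10000^(2/4)) = sin(0.01)
    pe = positional_encoding(2, 4, convention="as_printed")
    assert pe[1, 1] == pytest.approx(np.sin(0.01), abs=1e-12)


def test_positional_encoding_standard_convention_differs():
    printed = positional_encoding(8, 6, "as_printed")
    standard = positional_encoding(8, 6, "standard")
    assert not np.allclose(printed, standard)
    with pytest.raises(ValueError):
        positional_encoding(0, 4)


def test_positional_disabled_passthrough(tiny_config):
    cfg = ModelConfig(**{**tiny_config.to_dict(), "use_positional": False})
    m = PairInteractionModel(cfg)
    h = Tensor(np.random.default_rng(0).standard_normal((4, cfg.d_model)))
    assert m._positional(h) is h


# -- local feature extractor ------------------------------------------------

def test_conv_extractor_shapes(model, small_dataset):
    sample = small_dataset.train[0]
    out = model.local_feature_extractor(sample.ligand_features)
    assert out.shape == (sample.ligand_features.n_residues, model.config.d_model)


def test_conv_extractor_single_residue(tiny_config, small_dataset):
    """Same-padding handles N=1 inputs."""
    from pairsite.node_features import NodeFeatureMatrix

    feats = NodeFeatureMatrix(
        matrix=small_dataset.train[0].ligand_features.matrix[:1].copy(),
        embed_dim=tiny_config.embed_dim,
    )
    model = PairInteractionModel(tiny_config)
    out = model.local_feature_extractor(feats)
    assert out.shape == (1, tiny_config.d_model)
    assert np.isfinite(out.data).all()


# -- graph attention --------------------------------------------------------

def test_gat_attention_normalizes(model, small_dataset):
    sample = small_dataset.train[0]
    collected = []
    model.encode(sample.ligand_graph, sample.ligand_features,
                 collect_attention=collected)
    assert collected
    for alpha, tgt in collected:
        sums = np.zeros(sample.ligand_graph.n_nodes)
        np.add.at(sums, tgt, alpha)
        present = np.unique(tgt)
        assert np.abs(sums[present] - 1.0).max() < 1e-6


def test_gat_isolated_node_passthrough(model):
    """A graph with no edges falls back to each node's own features."""
    g = ResidueGraph(n_nodes=1, edges=np.zeros((0, 2)), edge_features=np.zeros((0, 2)), k=1)
    h = Tensor(np.random.default_rng(0).standard_normal((1, model.config.d_model)))
    out, _, _ = model.gat_layers[0](h, g)
    assert out.shape == (1, model.config.d_model)
    assert np.isfinite(out.data).all()
    assert np.allclose(out.data, (h @ model.gat_layers[0].W).data)


def test_gat_matches_dense_node_only_oracle(tiny_config):
    """With edge features off, the layer equals plain graph attention."""
    cfg = ModelConfig(**{**tiny_config.to_dict(), "use_edge_features": False})
    model = PairInteractionModel(cfg)
    layer = model.gat_layers[0]
    rng = np.random.default_rng(8)
    n, d = 5, cfg.d_model
    edges = np.array([[1, 0], [2, 0], [0, 1], [3, 1], [4, 2], [0, 3], [2, 4], [1, 4]])
    g = ResidueGraph(n_nodes=n, edges=edges, edge_features=np.zeros((len(edges), 2)), k=2)
    h = rng.standard_normal((n, d))
    out, _, _ = layer(Tensor(h), g)

    # independent dense implementation
    W, a = layer.W.data, layer.a.data.ravel()
    wh = h @ W
    slope = cfg.leaky_slope
    expected = np.zeros_like(wh)
    for i in range(n):
        sources = edges[edges[:, 1] == i][:, 0]
        logits = np.array([
            np.concatenate([wh[i], wh[j]]) @ a for j in sources
        ])
        logits = np.where(logits > 0, logits, slope * logits)
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        expected[i] = (alpha[:, None] * wh[sources]).sum(axis=0)
    assert np.abs(out.data - expected).max() < 1e-10


# -- Siamese property -------------------------------------------------------

def test_siamese_shared_weights(model, small_dataset):
    sample = small_dataset.train[0]
    lig = (sample.ligand_graph, sample.ligand_features)
    rec = (sample.receptor_graph, sample.receptor_features)
    h_r, h_l = model.siamese_encode(rec, lig)
    h_r2, h_l2 = model.siamese_encode(lig, rec)  # swapped
    assert np.array_equal(h_r.data, h_l2.data)
    assert np.array_equal(h_l.data, h_r2.data)
    # same protein on both inputs → identical encodings
    same_r, same_l = model.siamese_encode(lig, lig)
    assert np.array_equal(same_r.data, same_l.data)


# -- cross-attention --------------------------------------------------------

def test_cross_attention_rows_normalize(model, small_dataset):
    result = model.predict(small_dataset.train[0])
    for mats in result.attention.values():
        assert len(mats) == model.config.n_heads
        for mat in mats:
            assert np.abs(mat.sum(axis=1) - 1.0).max() < 1e-6


def test_cross_attention_uniform_cases(model):
    d = model.config.d_model
    rng = np.random.default_rng(0)
    p_l = Tensor(rng.standard_normal((4, d)))
    # identical partner rows → constant logits → uniform attention
    p_r = Tensor(np.tile(rng.standard_normal(d), (6, 1)))
    _, _, attn = model.cross(p_l, p_r)
    for mat in attn["ligand_to_receptor"]:
        assert np.allclose(mat.data, 1.0 / 6.0)
    # partner of length 1 → every weight exactly 1
    p_single = Tensor(rng.standard_normal((1, d)))
    _, _, attn = model.cross(p_l, p_single)
    for mat in attn["ligand_to_receptor"]:
        assert np.allclose(mat.data, 1.0)


# -- full forward -----------------------------------------------------------

def test_forward_shapes_and_ranges(model, small_dataset):
    sample = small_dataset.train[0]
    result = forward(sample, model)
    n_l, n_r = sample.pair_labels.shape
    assert result.pair_probs.shape == (n_l, n_r)
    assert result.interface_probs_l.shape == (n_l,)
    assert result.interface_probs_r.shape == (n_r,)
    assert ((result.pair_probs > 0) & (result.pair_probs < 1)).all()


def test_forward_order_invariance(model, small_dataset):
    """Swapping receptor/ligand transposes pair scores, exchanges interfaces."""
    for sample in small_dataset.train[:3]:
        direct = model.predict(sample)
        swapped = model.predict(sample.swapped())
        assert np.abs(swapped.pair_probs.T - direct.pair_probs).max() < 1e-5
        assert np.abs(swapped.interface_probs_l - direct.interface_probs_r).max() < 1e-5
        assert np.abs(swapped.interface_probs_r - direct.interface_probs_l).max() < 1e-5


def test_forward_deterministic_in_eval_mode(model, small_dataset):
    sample = small_dataset.train[0]
    a, b = model.predict(sample), model.predict(sample)
    assert np.array_equal(a.pair_probs, b.pair_probs)
    assert np.array_equal(a.interface_probs_l, b.interface_probs_l)


def test_interface_head_is_rowwise(model, small_dataset):
    """Duplicated residue features give identical interface probabilities."""
    m = Tensor(np.tile(np.random.default_rng(1).standard_normal(model.config.d_model), (3, 1)))
    probs = model.iface_ffn(m).sigmoid().data
    assert np.allclose(probs, probs[0])


def test_single_gradient_step_decreases_loss(tiny_config, small_dataset):
    from pairsite._autograd import Adam
    from pairsite.train_eval import _complex_loss, downsample_negatives

    model = PairInteractionModel(tiny_config)
    sample = small_dataset.train[0]
    idx = downsample_negatives(sample.pair_labels, 10, rng_seed=0)
    opt = Adam(model.params(), lr=1e-3)
    loss0 = _complex_loss(model, sample, idx, tiny_config, None)
    opt.zero_grad()
    loss0.backward()
    opt.step()
    loss1 = _complex_loss(model, sample, idx, tiny_config, None)
    assert loss1.data < loss0.data


def test_ablation_switches(small_dataset, tiny_config):
    base = tiny_config.to_dict()
    sample = small_dataset.train[0]
    for switch in ("use_edge_features", "use_positional", "use_phychem"):
        cfg = ModelConfig(**{**base, switch: False})
        result = PairInteractionModel(cfg).predict(sample)
        assert np.isfinite(result.pair_probs).all()


def test_checkpoint_round_trip(model, small_dataset, tmp_path):
    sample = small_dataset.train[0]
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, small_dataset.node_stats, small_dataset.edge_stats,
                    history={"epoch_loss": [1.0]})
    loaded, node_stats, edge_stats, history = load_checkpoint(path)
    assert history == {"epoch_loss": [1.0]}
    assert np.array_equal(node_stats.mean, small_dataset.node_stats.mean)
    assert np.array_equal(
        loaded.predict(sample).pair_probs, model.predict(sample).pair_probs
    )


def test_sample_label_consistency_enforced(small_dataset):
    s = small_dataset.train[0]
    with pytest.raises(ValueError):
        ComplexSample(
            complex_id="bad",
            ligand_graph=s.ligand_graph,
            ligand_features=s.ligand_features,
            receptor_graph=s.receptor_graph,
            receptor_features=s.receptor_features,
            pair_labels=s.pair_labels,
            interface_l=1 - np.asarray(s.interface_l),
        )
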