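# Methods

This note documents the modeling and implementation choices behind
`pairsite`: what the pipeline computes, the defaults and why, what the
synthetic data generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Problem setting and assumptions

Given two protein structures (called receptor and ligand by convention
only — all outputs are invariant to the naming), the package addresses two
tasks:

* **pairwise interaction prediction** — for every (ligand residue,
  receptor residue) pair, the probability that the two residues interact
  in the complex; and
* **interface-region prediction** — for every residue, the probability
  that it interacts with at least one partner residue.

Two residues are defined to interact when any pair of their non-hydrogen
atoms lies within 6.0 Å (inclusive). Hydrogens are excluded throughout
the geometric featurization because they are usually absent from X-ray
structures; this makes behavior consistent whether or not a file happens
to include them.

The model assumes single- or multi-chain proteins whose residues can be
ordered deterministically (chains concatenated in file order). Positional
encodings run over that concatenated index; a per-chain restart is not
implemented because interface prediction depends mostly on local context
and the concatenated index keeps the pipeline simple (a chain break shows
up as a discontinuity in the k-NN graph, which the graph-attention layers
can absorb).

## Featurization

**Residue graphs.** Each protein is a directed k-NN graph where node `i`
receives edges from its `min(k, N−1)` nearest residues under the mean
heavy-atom-pair distance. The same metric supplies the distance edge
feature, so the neighborhood definition and the edge feature are mutually
consistent. Equidistant candidates are broken toward the lower residue
index, making graph construction deterministic.

**Edge features (2 per edge).** Mean inter-residue atom distance `D` (Å)
and relative plane orientation `θ` (radians). `θ` is
`arccos(|n_i · n_j|)` between the unit normals of the planes through each
residue's N, Cα and carbonyl C atoms. The absolute value is deliberate:
a plane normal is only defined up to sign, so the angle lives in
`[0, π/2]` and is symmetric in its arguments.

*Degenerate backbones.* A residue missing any of N/Cα/C, or whose three
backbone atoms are collinear (cross-product norm below 1e-8), has no plane.
Such residues are flagged on the graph (`degenerate_nodes`) and their
edges receive the mean orientation of the non-degenerate edges in the same
graph — which is ≈ 0 after standardization — rather than invented
geometry. Distances are unaffected.

**Node features (embedding + 16).** The embedding provider contract only
requires determinism (same sequence → bitwise-identical matrix) and a fixed
dimensionality. Two providers ship: a loader for matrices precomputed
offline by an external protein language model (`.npz` keyed by structure
id, with stored sequences for lookup), and the hash-based surrogate used in
tests. The 16 physicochemical channels, in fixed column order, are:

| # | channel | source scale |
|---|---------|--------------|
| 1 | hydrophilicity | Hopp–Woods 1981 |
| 2 | flexibility | Vihinen 1994 |
| 3 | accessibility | Janin 1979 |
| 4 | turn propensity | Chou–Fasman 1978 |
| 5 | exposed surface | Emini 1985 |
| 6 | antigenic propensity | Welling 1985 |
| 7 | net charge index of side chains | NCISC |
| 8 | polarizability | Charton–Charton 1982 |
| 9–10 | hydrophobicity (two scales) | Fauchère–Pliška 1983; Kyte–Doolittle 1982 |
| 11–12 | polarity (two scales) | Grantham 1974; Zimmerman 1968 |
| 13 | SASA (Å²) | Shrake–Rupley, probe 1.4 Å, element VdW radii |
| 14 | relative SASA | SASA / per-residue-type reference max (Tien 2013, theoretical) |
| 15 | side-chain volume (Å³) | Zamyatnin 1972 residue volumes |
| 16 | residue depth (Å) | mean heavy-atom distance to the nearest solvent-exposed atom |

The 12 sequence-level scales are configuration data pinned in
`data/physicochem_scales.tsv`; they are standard published scales chosen by
this package (the problem definition names the properties but no specific
tables). Unknown residues (`X`) receive each scale's mean over the 20
standard amino acids, with a warning. "Solvent-exposed" for residue depth
means per-atom SASA > 0.1 Å²; an isolated residue therefore has depth 0.
Note the reference maxima are tripeptide-context values, so relative SASA
of a fully isolated residue can exceed 1 — it is an exposure score, not a
bounded fraction.

Both node and edge features are standardized per channel using statistics
fitted on the training split only; the statistics travel with model
checkpoints so prediction-time inputs are transformed identically.
Zero-variance channels get scale 1 with a warning.

## Network

All computation is float64 on a compact reverse-mode autodiff engine
(`_autograd.py`) written for this package; with a fixed seed every
initialization, training step and prediction is exactly reproducible, and
the engine's gradients are finite-difference-checked in the test suite.

* **Local feature extractor**: `n_conv_layers` same-padded 1-D
  convolutions (kernel 3) with ReLU, mapping `d_node → d_model`.
* **Edge-aggregated graph attention**: per edge `j→i`, logit
  `LeakyReLU(a · [W h_i ‖ W h_j ‖ W_e ξ_ji])` (slope 0.2), softmax over
  the in-neighborhood, aggregation `Σ_j α_ji (W h_j + W_e ξ_ji)`, stacked
  `n_gat_layers` times with residual connections. A node with no in-edges
  (only possible in single-residue graphs) passes through its own
  transformed features. With `use_edge_features = false` the `W_e` terms
  vanish and the layer reduces to plain node-only graph attention — the
  test suite checks this against an independent dense implementation.
* **Positional encoding**: the sinusoidal form with a 1-based dimension
  index and exponent `i/d_model` (even `i` → sin, odd `i` → cos) as the
  default, rather than the more common paired `2i/d_model` convention;
  `pe_convention: "standard"` switches to the latter. Both fill the full
  frequency spectrum; they differ only in how dimensions pair up.
* **Cross-attention**: `n_heads` heads with shared `W_Q, W_K, W_V`
  (`d_model → d_k`, `d_k = d_model / n_heads` by default) across the two
  proteins, `softmax(Q K'ᵀ/√d_k) V'`, heads concatenated and projected by
  `W_O`, then residual + layer normalization (ε = 1e-5). Attention
  matrices are retained in every prediction for export.
* **Heads**: both FFNs use two hidden layers (width `ffn_hidden`), ReLU
  then LeakyReLU, then a sigmoid. The published description names the
  activations but not the widths or depth; these are this package's
  defaults. The pairwise head scores `[M_r ‖ M_l]` and `[M_l ‖ M_r]` and
  averages the two sigmoids, which makes receptor/ligand order invariance
  a construction property rather than a learned one.

**Initialization** is Glorot-uniform from a seeded generator. **Dropout**
(default 0.1) applies after conv layers and inside FFN hidden layers during
training only, drawn from a per-(epoch, complex) seeded stream; evaluation
mode is deterministic.

## Training protocol

Loss is binary cross-entropy, jointly over the two heads with equal
weights by default (`pairwise_loss_weight`, `interface_loss_weight`).
Each epoch re-draws the negative pairs per complex — all positives plus
`min(10 × n_pos, n_neg)` uniformly sampled negatives — from a seed
schedule derived from the master seed; `resample_each_epoch: false` fixes
one draw. Optimization is Adam (lr 1e-3 default; the synthetic experiments
use 2e-3). Complexes without a single positive pair are skipped with a
warning; a non-finite loss aborts with diagnostics. When a validation set
is supplied, the checkpoint with the best validation median pairwise AUROC
is restored after the final epoch.

Validation and test sets are never downsampled. Probabilities inside the
BCE are squeezed into `[1e-12, 1 − 1e-12]` by an affine map so the log is
always finite.

## Metrics

AUROC follows the Mann–Whitney convention (ties worth ½); AUPRC is the
step-wise precision–recall area with no linear interpolation. Both are
computed per complex and summarized by the **median** across complexes,
which keeps very small or very large complexes from dominating. AUPRC is
additionally pooled over all pairs of all complexes
(`auprc_aggregate`) because per-complex-median and pooled AUPRC answer
different questions under extreme imbalance; the report labels both.
Complexes whose labels are single-class are excluded from the per-complex
lists and counted (`n_excluded`). Precision at a threshold with zero
predicted positives is reported as `None` (flagged undefined), never
silently 0. Precision@N ranks all pairs of a complex (boundary ties broken
by row-major index) for N ∈ {10, 20, …, 100}. The implementations are
checked against brute-force enumeration oracles to 1e-12 in the tests.

## Synthetic data generator

`synthetic_fixtures` generates the study conditions for every experiment
in this repository: two-chain complexes (default 12 ligand and 15 receptor
residues, varied ±3 per complex in datasets) whose residues carry
idealized N/Cα/C/O backbone atoms. A contiguous block of
`interface_size = 3` residues per side is planted as the interface:

* the planted blocks sit in two tight facing rows near the origin so that
  *every* planted cross pair has closest-atom distance ≤
  `contact_distance` (default 4.5 Å) even under the worst-case jitter
  bound (`2√3 ×` the uniform jitter half-width, default jitter 0.2 Å);
* all other cross-protein pairs are ≥ `separation` (default 20 Å) apart —
  the non-interface residues form ordinary helices far from the origin;
* the construction is verified numerically and a spec error is raised if
  the margins cannot be met (e.g. jitter too large, or an interface too
  big to fit inside the contact ball with ≥ 0.8 Å between planted Cαs).

The expected label matrix is therefore *analytic* — the outer product of
the planted masks — and the geometric labeler must reproduce it exactly,
which the tests check on every fixture.

Interface membership is made learnable through sequence composition:
planted residues draw from a charged/polar alphabet (H, K, R, D, E) and
tail residues from an apolar one, with a 10% flip probability as label
noise. The surrogate embedder's first channel scores that alphabet (±2.0
with small hash noise), so a trained model can recover the planted
interface from node features. This is a deliberately easy, test-only
signal: real interfaces are not linearly encoded in one channel.

**What passing the recovery experiment shows** — that the whole pipeline
(featurization → graph attention → cross-attention → heads → loss →
sampling → metrics) is wired correctly and can extract a planted signal
end to end. **What it does not show** — predictive performance on real
complexes: the synthetic backbones have no side chains, no conformational
change between bound and unbound forms, a compressed (non-physical)
interface geometry, and an interface signal far stronger and simpler than
biochemical reality.

## Problem sizes used

The repository's experiments are sized for a single CPU: the recovery
experiment uses 50 complexes (30 train / 10 validation / 10 test) of ~12–18
residues per chain, `d_model = 32`, 2 conv + 2 graph-attention layers, 2
heads, 30 epochs. These sizes are the package's chosen defaults for the
synthetic suite; nothing in the architecture limits it to them.

## Other design decisions

* **PDB parsing** uses the first MODEL of multi-model files and resolves
  alternate locations to the highest-occupancy conformer (ties → first
  encountered) — standard, deterministic conventions. HETATM records are
  kept only for a configurable table of modified amino acids (MSE, CSO,
  SEP, TPO, PTR, HYP by default).
* **Missing atoms in real structures** are not imputed: residues missing
  backbone atoms stay in the graph (distances still defined) and are
  flagged degenerate for the orientation feature, as described above.
* **Checkpoints** are a single `.npz` archive holding the config, all
  parameter tensors and the feature-standardization statistics, so a saved
  model reproduces its predictions bit-for-bit.
* The **k** default (10) and the rest of the config defaults are this
  package's choices for the synthetic suite; tune them per dataset.

## Known limitations

* No GPU or minibatching — complexes are processed one at a time in
  numpy; fine for hundreds of residues, not for proteome-scale screening.
* The SASA/residue-depth backend uses element-based VdW radii; atom-type
  radii (e.g. ProtOr) would be marginally more accurate on real data.
* mmCIF input, biological-assembly expansion and hydrogen placement are
  out of scope; convert to PDB first.
* Precomputed embeddings are looked up by exact sequence match; point
  mutations require regenerating the embedding matrix offline.
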