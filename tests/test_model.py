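"""Embedding model: encoder invariances, aggregator properties, and
equivalence with an independent straight-line forward implementation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldvec.model import (AggregatorConfig, EncoderConfig,
                           ResidueEmbeddingSequence, StructureEmbedding,
                           aggregate, baseline_mean_embed,
                           concat_residue_embeddings, cosine, embed_assembly,
                           embed_chain, encode_residues,
                           init_aggregator_weights, load_checkpoint,
                           load_residue_embeddings, parameter_count,
                           save_checkpoint, save_residue_embeddings,
                           similarity)
from foldvec.structures import AssemblyStructure, ChainStructure
from foldvec.synthetic import generate_assembly

SMALL = AggregatorConfig(d_in=8, d_model=32, n_encoder_layers=2, d_ff=48,
                         n_residual_blocks=2)


def random_chain(L, seed):
    rng = np.random.default_rng(seed)
    coords = np.cumsum(rng.normal(size=(L, 3)) * 1.5 + [3.8, 0, 0], axis=0)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    return ChainStructure("A", seq, coords)


# --------------------------------------------------------------------------
# independent straight-line re-implementation of the aggregator forward
# --------------------------------------------------------------------------

def reference_forward(X, cfg, w):
    """Plain NumPy forward pass, written independently of the autograd path."""
    def ln(x, g, b, eps=1e-5):
        mu = x.mean(-1, keepdims=True)
        var = ((x - mu) ** 2).mean(-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    def softmax(x):
        e = np.exp(x - x.max(-1, keepdims=True))
        return e / e.sum(-1, keepdims=True)

    h = X
    if "in.W" in w:
        h = h @ w["in.W"] + w["in.b"]
    L = h.shape[0]
    H = cfg.n_heads
    dh = cfg.d_model // H
    for l in range(cfg.n_encoder_layers):
        p = f"enc{l}."
        q = (h @ w[p + "Wq"] + w[p + "bq"]).reshape(L, H, dh)
        k = (h @ w[p + "Wk"] + w[p + "bk"]).reshape(L, H, dh)
        v = (h @ w[p + "Wv"] + w[p + "bv"]).reshape(L, H, dh)
        att_out = np.empty((L, H, dh))
        for head in range(H):
            scores = q[:, head] @ k[:, head].T / np.sqrt(dh)
            att_out[:, head] = softmax(scores) @ v[:, head]
        h = ln(h + att_out.reshape(L, cfg.d_model) @ w[p + "Wo"] + w[p + "bo"],
               w[p + "ln1.g"], w[p + "ln1.b"])
        f = np.maximum(h @ w[p + "ff.W1"] + w[p + "ff.b1"], 0) \
            @ w[p + "ff.W2"] + w[p + "ff.b2"]
        h = ln(h + f, w[p + "ln2.g"], w[p + "ln2.b"])
    vpool = h.sum(axis=0)
    for r in range(cfg.n_residual_blocks):
        p = f"res{r}."
        vpool = vpool + np.maximum(vpool @ w[p + "W1"] + w[p + "b1"], 0) \
            @ w[p + "W2"] + w[p + "b2"]
    return vpool


def test_forward_matches_independent_reference():
    """20 random (weights, input) draws agree with the reference within 1e-5."""
    for trial in range(20):
        rng = np.random.default_rng(trial)
        L = int(rng.integers(1, 25))
        weights = init_aggregator_weights(SMALL, seed=trial)
        # scatter the initial weights so the check is not near-identity
        for wt in weights.values():
            wt.data = wt.data + rng.normal(0, 0.05, wt.data.shape)
        X = rng.normal(size=(L, SMALL.d_in))
        got = aggregate(ResidueEmbeddingSequence(X), SMALL, weights).vector
        want = reference_forward(X, SMALL, {k: t.data for k, t in weights.items()})
        np.testing.assert_allclose(got, want, atol=1e-5)


# --------------------------------------------------------------------------
# residue encoder
# --------------------------------------------------------------------------

def test_encoder_rigid_motion_invariance():
    c = random_chain(40, 0)
    R = Rotation.random(random_state=1).as_matrix()
    moved = c.transformed(R, np.array([7.0, -3.0, 2.0]))
    e1 = encode_residues(c).embeddings
    e2 = encode_residues(moved).embeddings
    np.testing.assert_allclose(e1, e2, atol=1e-5)


def test_encoder_sensitive_to_residue_order():
    c = random_chain(5, 2)
    rev = ChainStructure("A", c.sequence[::-1], c.ca_coords[::-1].copy())
    e1 = encode_residues(c).embeddings
    e2 = encode_residues(rev).embeddings[::-1]
    assert np.abs(e1 - e2).max() > 1e-6


def test_encoder_single_residue_chain():
    c = ChainStructure("A", "M", np.array([[1.0, 2.0, 3.0]]))
    e = encode_residues(c)
    assert e.embeddings.shape == (1, EncoderConfig().d_in)
    assert np.isfinite(e.embeddings).all()


# --------------------------------------------------------------------------
# aggregator invariances
# --------------------------------------------------------------------------

def test_permutation_invariance_over_random_inputs():
    weights = init_aggregator_weights(SMALL, seed=3)
    rng = np.random.default_rng(9)
    worst = 0.0
    for _ in range(50):
        X = rng.normal(size=(int(rng.integers(2, 40)), SMALL.d_in))
        perm = rng.permutation(X.shape[0])
        a = aggregate(ResidueEmbeddingSequence(X), SMALL, weights).vector
        b = aggregate(ResidueEmbeddingSequence(X[perm]), SMALL, weights).vector
        worst = max(worst, np.abs(a - b).max())
    assert worst <= 1e-4


def test_duplicated_rows_change_output():
    """Sum pooling is not mean pooling: doubling every row moves the output."""
    weights = init_aggregator_weights(SMALL, seed=4)
    X = np.random.default_rng(5).normal(size=(10, SMALL.d_in))
    a = aggregate(ResidueEmbeddingSequence(X), SMALL, weights).vector
    b = aggregate(ResidueEmbeddingSequence(np.repeat(X, 2, axis=0)),
                  SMALL, weights).vector
    assert np.abs(a - b).max() > 1e-6


def test_single_row_matches_reference():
    weights = init_aggregator_weights(SMALL, seed=6)
    X = np.random.default_rng(7).normal(size=(1, SMALL.d_in))
    got = aggregate(ResidueEmbeddingSequence(X), SMALL, weights).vector
    want = reference_forward(X, SMALL, {k: t.data for k, t in weights.items()})
    np.testing.assert_allclose(got, want, atol=1e-8)


def test_dimension_mismatch_rejected():
    weights = init_aggregator_weights(SMALL, seed=8)
    X = np.random.default_rng(8).normal(size=(5, SMALL.d_in + 1))
    with pytest.raises(ValueError):
        aggregate(ResidueEmbeddingSequence(X), SMALL, weights)


# --------------------------------------------------------------------------
# chain and assembly embeddings
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_model():
    enc = EncoderConfig()
    agg = AggregatorConfig.mini_preset()
    return enc, agg, init_aggregator_weights(agg, seed=0)


def test_identical_chains_have_similarity_one(mini_model):
    enc, agg, w = mini_model
    c = random_chain(30, 10)
    e1 = embed_chain(c, enc, agg, w)
    e2 = embed_chain(c, enc, agg, w)
    assert similarity(e1, e2) == pytest.approx(1.0)


def test_rigid_moved_chain_same_embedding(mini_model):
    enc, agg, w = mini_model
    c = random_chain(30, 11)
    R = Rotation.random(random_state=12).as_matrix()
    e1 = embed_chain(c, enc, agg, w)
    e2 = embed_chain(c.transformed(R, np.array([1.0, 2.0, 3.0])), enc, agg, w)
    assert cosine(e1, e2) >= 1 - 1e-6


def test_assembly_chain_order_invariance(mini_model):
    """All orderings of a 4-chain assembly give the same embedding."""
    from itertools import permutations

    enc, agg, w = mini_model
    base = random_chain(20, 13)
    chains = [ChainStructure(cid, base.sequence,
                             base.ca_coords + np.array([40.0 * i, 0, 0]))
              for i, cid in enumerate("ABCD")]
    ref = None
    for perm in permutations(range(4)):
        asm = AssemblyStructure("p", [chains[i] for i in perm])
        e = embed_assembly(asm, enc, agg, w)
        if ref is None:
            ref = e.vector
        else:
            assert np.abs(e.vector - ref).max() <= 1e-4


def test_assembly_spatial_arrangement_degeneracy(mini_model):
    """Identical subunits in different quaternary arrangements embed
    identically — the documented blind spot of chain-wise encoding."""
    enc, agg, w = mini_model
    chain = random_chain(25, 14)
    a = generate_assembly(chain, 3, "cyclic", radius=60)
    b = generate_assembly(chain, 3, "cyclic", radius=130)
    ea = embed_assembly(a, enc, agg, w)
    eb = embed_assembly(b, enc, agg, w)
    np.testing.assert_allclose(ea.vector, eb.vector, atol=1e-6)


def test_single_chain_assembly_equals_chain(mini_model):
    enc, agg, w = mini_model
    c = random_chain(15, 15)
    asm = AssemblyStructure("solo", [c])
    np.testing.assert_allclose(embed_assembly(asm, enc, agg, w).vector,
                               embed_chain(c, enc, agg, w).vector, atol=1e-10)


# --------------------------------------------------------------------------
# similarity and the baseline
# --------------------------------------------------------------------------

def test_similarity_clamping_rules():
    a = StructureEmbedding(np.array([1.0, 0.0]))
    b = StructureEmbedding(np.array([0.0, 1.0]))
    anti = StructureEmbedding(np.array([-1.0, 0.0]))
    assert similarity(a, a) == pytest.approx(1.0)
    assert similarity(a, b) == pytest.approx(0.0)
    assert cosine(a, anti) == pytest.approx(-1.0)
    assert similarity(a, anti) == 0.0


def test_zero_norm_embedding_rejected():
    with pytest.raises(ValueError):
        StructureEmbedding(np.zeros(4))


def test_baseline_mean_embed_properties():
    v = np.array([2.0, -1.0, 0.5, 3.0])
    const = ResidueEmbeddingSequence(np.tile(v, (6, 1)))
    np.testing.assert_allclose(baseline_mean_embed(const).vector, v)
    rng = np.random.default_rng(16)
    X = rng.normal(size=(9, 4))
    a = baseline_mean_embed(ResidueEmbeddingSequence(X)).vector
    b = baseline_mean_embed(
        ResidueEmbeddingSequence(X[rng.permutation(9)])).vector
    np.testing.assert_allclose(a, b, atol=1e-12)


# --------------------------------------------------------------------------
# presets, checkpoints, interchange
# --------------------------------------------------------------------------

def test_reference_preset_parameter_count():
    """~170M trainable parameters, computed analytically."""
    n = parameter_count(AggregatorConfig.paper_preset())
    assert abs(n - 170e6) / 170e6 <= 0.10


def test_checkpoint_roundtrip(tmp_path, mini_model):
    enc, agg, w = mini_model
    path = str(tmp_path / "ckpt.npz")
    save_checkpoint(path, w, agg, enc, extra={"note": "test"})
    w2, agg2, enc2, meta = load_checkpoint(path)
    assert agg2 == agg and enc2 == enc
    for k in w:
        np.testing.assert_array_equal(w[k].data, w2[k].data)
    assert meta["extra"]["note"] == "test"


def test_residue_embedding_interchange(tmp_path):
    seq = ResidueEmbeddingSequence(np.random.default_rng(17).normal(size=(7, 12)))
    path = str(tmp_path / "res.h5")
    save_residue_embeddings(path, seq, chain_id="X")
    back = load_residue_embeddings(path)
    np.testing.assert_array_equal(back.embeddings, seq.embeddings)


def test_concat_residue_embeddings_tracks_boundaries():
    a = ResidueEmbeddingSequence(np.ones((3, 4)))
    b = ResidueEmbeddingSequence(np.zeros((5, 4)))
    cat = concat_residue_embeddings([a, b])
    assert cat.chain_boundaries == [3, 5]
    assert cat.embeddings.shape == (8, 4)
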