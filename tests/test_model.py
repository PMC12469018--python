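import numpy as np
import pytest

from neurolatent.model import (
    HierarchicalAttentionNet,
    ModelConfig,
    extract_weight_views,
    load_checkpoint,
    save_checkpoint,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _oracle_forward(model, batch):
    """Independent plain-NumPy re-implementation of the dimensional flow."""
    cfg = model.cfg
    P = {k: p.data for k, p in model.params.items()}
    b_sz, t_total, _ = batch.shape
    k = t_total // cfg.window_len
    flat = batch[:, : k * cfg.window_len].reshape(b_sz * k, cfg.window_len, cfg.C)

    def lstm(x, w_ih, w_hh, b, hidden):
        n, t, _ = x.shape
        h = np.zeros((n, hidden))
        c = np.zeros((n, hidden))
        out = np.empty((n, t, hidden))
        for step in range(t):
            g = x[:, step] @ w_ih + h @ w_hh + b
            i = _sigmoid(g[:, :hidden])
            f = _sigmoid(g[:, hidden:2 * hidden])
            cand = np.tanh(g[:, 2 * hidden:3 * hidden])
            o = _sigmoid(g[:, 3 * hidden:])
            c = f * c + i * cand
            h = o * np.tanh(c)
            out[:, step] = h
        return out

    def attend(h, which):
        n, t, d = h.shape
        scores = (np.tanh(h.reshape(n * t, d) @ P[f"{which}.W"] + P[f"{which}.b"])
                  @ P[f"{which}.v"]).reshape(n, t)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        alpha = e / e.sum(axis=1, keepdims=True)
        return (alpha[:, :, None] * h).sum(axis=1), alpha

    h_enc = lstm(flat, P["enc.W_ih"], P["enc.W_hh"], P["enc.b"], cfg.D_enc)
    win_emb, alpha_win = attend(h_enc, "attn_win")
    h_main = lstm(win_emb.reshape(b_sz, k, cfg.D_enc),
                  P["main.W_ih"], P["main.W_hh"], P["main.b"], cfg.D_main)
    latent, alpha_glob = attend(h_main, "attn_glob")
    logits = latent @ P["dec.W"] + P["dec.b"]
    return latent, logits, alpha_win.reshape(b_sz, k, cfg.window_len), alpha_glob


def test_forward_matches_independent_numpy_oracle(tiny_model, rng):
    x = rng.standard_normal((4, 11, tiny_model.cfg.C))  # 2 windows + 3-step tail
    out = tiny_model.forward(x)
    latent, logits, aw, ag = _oracle_forward(tiny_model, x)
    np.testing.assert_allclose(out.latent, latent, atol=1e-12)
    np.testing.assert_allclose(out.logits, logits, atol=1e-12)
    for i, rec in enumerate(out.attention):
        np.testing.assert_allclose(rec.alpha_win, aw[i], atol=1e-12)
        np.testing.assert_allclose(rec.alpha_global, ag[i], atol=1e-12)


def test_reference_dimensional_flow():
    """Defaults reproduce the documented flow: 32x140x53 -> K=7 windows,
    224 total windows, 200-d latent, 2 logits."""
    model = HierarchicalAttentionNet(ModelConfig(), seed=0)
    x = np.random.default_rng(0).standard_normal((32, 140, 53))
    out = model.forward(x)
    assert out.latent.shape == (32, 200)
    assert out.logits.shape == (32, 2)
    rec = out.attention[0]
    assert rec.alpha_win.shape == (7, 20)
    assert rec.alpha_global.shape == (7,)
    assert 32 * rec.alpha_win.shape[0] == 224


def test_single_window_global_attention_is_exactly_one(tiny_model, rng):
    x = rng.standard_normal((1, tiny_model.cfg.window_len, tiny_model.cfg.C))
    out = tiny_model.forward(x)
    np.testing.assert_array_equal(out.attention[0].alpha_global, [1.0])


def test_attention_rows_are_probability_vectors(tiny_model, rng):
    out = tiny_model.forward(rng.standard_normal((5, 16, tiny_model.cfg.C)))
    for rec in out.attention:
        assert np.all(rec.alpha_win >= 0) and np.all(rec.alpha_global >= 0)
        np.testing.assert_allclose(rec.alpha_win.sum(axis=1), 1.0, atol=1e-9)
        assert rec.alpha_global.sum() == pytest.approx(1.0, abs=1e-9)


def test_batch_permutation_equivariance(tiny_model, rng):
    x = rng.standard_normal((6, 12, tiny_model.cfg.C))
    perm = rng.permutation(6)
    a = tiny_model.forward(x)
    b = tiny_model.forward(x[perm])
    np.testing.assert_allclose(b.latent, a.latent[perm], atol=1e-12)
    np.testing.assert_allclose(b.logits, a.logits[perm], atol=1e-12)


def test_short_series_and_nan_input_error(tiny_model, rng):
    with pytest.raises(ValueError, match="shorter than one window"):
        tiny_model.forward(rng.standard_normal((2, 3, tiny_model.cfg.C)))
    bad = rng.standard_normal((2, 8, tiny_model.cfg.C))
    bad[0, 0, 0] = np.nan
    with pytest.raises(FloatingPointError, match="input"):
        tiny_model.forward(bad)


def test_weight_view_shapes_and_gate_reduction(tiny_model):
    cfg = tiny_model.cfg
    w_enc, w_main = extract_weight_views(tiny_model, reduction="mean")
    assert w_enc.shape == (cfg.D_enc, cfg.C)
    assert w_main.shape == (cfg.D_main, cfg.D_enc)

    # brute-force slicing oracle for the gate-mean reduction
    raw = tiny_model.params["enc.W_ih"].data  # (C, 4*D_enc)
    blocks = [raw[:, i * cfg.D_enc:(i + 1) * cfg.D_enc] for i in range(4)]
    manual = np.mean(blocks, axis=0).T
    np.testing.assert_allclose(w_enc, manual, atol=1e-15)

    # cell-gate view picks exactly the candidate-gate block
    w_enc_cell, _ = extract_weight_views(tiny_model, reduction="cell-gate")
    np.testing.assert_array_equal(w_enc_cell, blocks[2].T)

    for p in tiny_model.params.values():
        p.data[:] = 0.0
    z_enc, z_main = extract_weight_views(tiny_model, reduction="mean")
    assert not z_enc.any() and not z_main.any()

    with pytest.raises(ValueError, match="unknown reduction"):
        extract_weight_views(tiny_model, reduction="bogus")


def test_default_weight_view_shapes_match_reference():
    model = HierarchicalAttentionNet(ModelConfig(), seed=1)
    w_enc, w_main = extract_weight_views(model)
    assert w_enc.shape == (256, 53)
    assert w_main.shape == (200, 256)


def test_checkpoint_roundtrip(tmp_path, tiny_model, rng):
    x = rng.standard_normal((2, 8, tiny_model.cfg.C))
    before = tiny_model.forward(x)
    path = tmp_path / "model.ckpt"
    save_checkpoint(tiny_model, path)
    restored = load_checkpoint(path)
    after = restored.forward(x)
    np.testing.assert_array_equal(after.latent, before.latent)
    np.testing.assert_array_equal(after.logits, before.logits)
    with pytest.raises(ValueError, match="does not match"):
        load_checkpoint(path, cfg=ModelConfig(C=99))
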