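"""Hierarchical recurrent network with dual attention.

The architecture processes a subject's ICA time courses in five stages,
following the dimensional flow (defaults in parentheses):

1. windowing: (B, T_total, C) -> (B, K, T, C), T = 20, K = floor(T_total/T);
2. per-window unidirectional LSTM encoder (input 53 -> hidden 256), run on the
   flattened (B*K, T, C) batch;
3. window-level additive attention pooling over the T time steps ->
   (B, K, 256);
4. main unidirectional LSTM over the K window embeddings (hidden 200) with
   global additive attention pooling over windows -> the subject latent
   z in R^200;
5. linear decoder z -> 2 logits (original/reversed during pretraining,
   patient/control downstream).

Both attention stages produce probability vectors (softmax over their scope),
which are returned per subject for the attribution stage.

The attention scorer is additive: a learned two-layer map of each hidden
state to a scalar, softmax-normalized within its scope.  Whether the original
architecture used additive or multiplicative scoring is not determinable from
its description; additive is the family default and yields the required
probability vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from ._autodiff import Parameter, Tensor, stack

__all__ = [
    "ModelConfig",
    "AttentionRecord",
    "ForwardOutput",
    "HierarchicalAttentionNet",
    "extract_weight_views",
    "save_checkpoint",
    "load_checkpoint",
]

_GATE_BLOCKS = {"input-gate": 0, "forget-gate": 1, "cell-gate": 2, "output-gate": 3}


@dataclass
class ModelConfig:
    """Architecture sizes; the defaults reproduce the reference dimensional flow."""

    C: int = 53          # input components
    D_enc: int = 256     # encoder LSTM hidden size
    D_main: int = 200    # main LSTM hidden size (latent dimensionality)
    window_len: int = 20
    n_out: int = 2
    D_attn: int = 64     # attention scorer hidden size (not architecture-critical)

    def __post_init__(self):
        for name in ("C", "D_enc", "D_main", "window_len", "n_out", "D_attn"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class AttentionRecord:
    """Per-subject attention weights (probability vectors) and raw scores."""

    alpha_win: np.ndarray      # (K, T), each row sums to 1
    alpha_global: np.ndarray   # (K,), sums to 1
    score_win: np.ndarray      # (K, T) pre-softmax scores
    score_global: np.ndarray   # (K,)


@dataclass
class ForwardOutput:
    """Batch forward-pass results with per-subject views."""

    latent: np.ndarray               # (B, D_main)
    logits: np.ndarray               # (B, n_out)
    attention: list[AttentionRecord]
    latent_t: Tensor | None = None   # graph handles, used during training
    logits_t: Tensor | None = None


def _check_finite(arr: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"non-finite values produced at stage: {stage}")


def _lstm_steps(steps, W_ih: Parameter, W_hh: Parameter, b: Parameter,
                hidden: int, n: int) -> list[Tensor]:
    """Run an LSTM over a list of (n, d_in) inputs; returns hidden state per step."""
    h = Tensor(np.zeros((n, hidden)))
    c = Tensor(np.zeros((n, hidden)))
    out: list[Tensor] = []
    for x_t in steps:
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        gates = x_t @ W_ih + h @ W_hh + b
        i = gates[:, 0 * hidden:1 * hidden].sigmoid()
        f = gates[:, 1 * hidden:2 * hidden].sigmoid()
        g = gates[:, 2 * hidden:3 * hidden].tanh()
        o = gates[:, 3 * hidden:4 * hidden].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        out.append(h)
    return out


def _softmax_rows(scores: Tensor) -> Tensor:
    m = Tensor(scores.data.max(axis=1, keepdims=True))  # constant shift, exact
    e = (scores - m).exp()
    return e / e.sum(axis=1, keepdims=True)


class HierarchicalAttentionNet:
    """Encoder LSTM + window attention + main LSTM + global attention + decoder."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)

        def uniform(shape, fan_in, name):
            bound = 1.0 / np.sqrt(fan_in)
            return Parameter(rng.uniform(-bound, bound, size=shape), name=name)

        c, de, dm, da, no = cfg.C, cfg.D_enc, cfg.D_main, cfg.D_attn, cfg.n_out
        self.params: dict[str, Parameter] = {
            "enc.W_ih": uniform((c, 4 * de), c, "enc.W_ih"),
            "enc.W_hh": uniform((de, 4 * de), de, "enc.W_hh"),
            "enc.b": uniform((4 * de,), de, "enc.b"),
            "attn_win.W": uniform((de, da), de, "attn_win.W"),
            "attn_win.b": uniform((da,), de, "attn_win.b"),
            "attn_win.v": uniform((da, 1), da, "attn_win.v"),
            "main.W_ih": uniform((de, 4 * dm), de, "main.W_ih"),
            "main.W_hh": uniform((dm, 4 * dm), dm, "main.W_hh"),
            "main.b": uniform((4 * dm,), dm, "main.b"),
            "attn_glob.W": uniform((dm, da), dm, "attn_glob.W"),
            "attn_glob.b": uniform((da,), dm, "attn_glob.b"),
            "attn_glob.v": uniform((da, 1), da, "attn_glob.v"),
            "dec.W": uniform((dm, no), dm, "dec.W"),
            "dec.b": uniform((no,), dm, "dec.b"),
        }

    # -- weight bookkeeping --------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray], skip: tuple[str, ...] = ()) -> None:
        for k, p in self.params.items():
            if any(k.startswith(s) for s in skip):
                continue
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: checkpoint {state[k].shape} vs model {p.data.shape}"
                )
            p.data = np.array(state[k], dtype=np.float64)

    def reinit_decoder(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(self.cfg.D_main)
        self.params["dec.W"].data = rng.uniform(-bound, bound, self.params["dec.W"].data.shape)
        self.params["dec.b"].data = rng.uniform(-bound, bound, self.params["dec.b"].data.shape)

    # -- attention block -----------------------------------------------------
    def _attend(self, H: Tensor, n: int, t: int, d: int, which: str):
        """Additive attention over axis 1 of an (n, t, d) tensor."""
        P = self.params
        W, b, v = P[f"{which}.W"], P[f"{which}.b"], P[f"{which}.v"]
        hidden = (H.reshape(n * t, d) @ W + b).tanh()
        scores = (hidden @ v).reshape(n, t)
        alpha = _softmax_rows(scores)
        pooled = (alpha.reshape(n, t, 1) * H).sum(axis=1)
        return pooled, alpha, scores

    # -- forward -------------------------------------------------------------
    def forward(self, batch: np.ndarray) -> ForwardOutput:
        """Run the full dimensional flow on a (B, T_total, C) batch."""
        cfg = self.cfg
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 3 or batch.shape[2] != cfg.C:
            raise ValueError(f"expected (B, T_total, {cfg.C}) input, got {batch.shape}")
        b_sz, t_total, _ = batch.shape
        t_win = cfg.window_len
        if t_total < t_win:
            raise ValueError(f"series shorter than one window ({t_total} < {t_win})")
        _check_finite(batch, "input")
        k = t_total // t_win
        win = batch[:, : k * t_win].reshape(b_sz, k, t_win, cfg.C)
        flat = win.reshape(b_sz * k, t_win, cfg.C)  # (B*K, T, C)

        P = self.params
        enc_steps = _lstm_steps(
            [flat[:, t, :] for t in range(t_win)],
            P["enc.W_ih"], P["enc.W_hh"], P["enc.b"], cfg.D_enc, b_sz * k,
        )
        H_enc = stack(enc_steps, axis=1)  # (B*K, T, D_enc)
        _check_finite(H_enc.data, "encoder")

        win_emb, alpha_win, score_win = self._attend(H_enc, b_sz * k, t_win, cfg.D_enc, "attn_win")
        _check_finite(win_emb.data, "window attention")
        win_seq = win_emb.reshape(b_sz, k, cfg.D_enc)

        main_steps = _lstm_steps(
            [win_seq[:, j, :] for j in range(k)],
            P["main.W_ih"], P["main.W_hh"], P["main.b"], cfg.D_main, b_sz,
        )
        H_main = stack(main_steps, axis=1)  # (B, K, D_main)
        _check_finite(H_main.data, "main recurrence")

        latent, alpha_glob, score_glob = self._attend(H_main, b_sz, k, cfg.D_main, "attn_glob")
        _check_finite(latent.data, "global attention")

        logits = latent @ P["dec.W"] + P["dec.b"]
        _check_finite(logits.data, "decoder")

        aw = alpha_win.data.reshape(b_sz, k, t_win)
        sw = score_win.data.reshape(b_sz, k, t_win)
        records = [
            AttentionRecord(
                alpha_win=aw[i].copy(),
                alpha_global=alpha_glob.data[i].copy(),
                score_win=sw[i].copy(),
                score_global=score_glob.data[i].copy(),
            )
            for i in range(b_sz)
        ]
        return ForwardOutput(
            latent=latent.data.copy(),
            logits=logits.data.copy(),
            attention=records,
            latent_t=latent,
            logits_t=logits,
        )


def extract_weight_views(model: HierarchicalAttentionNet,
                         reduction: str = "cell-gate") -> tuple[np.ndarray, np.ndarray]:
    """Reduce the gated input-to-hidden weights to the single matrices the
    attribution algorithm expects: W_enc (D_enc x C) and W_main (D_main x D_enc).

    A gated recurrent cell has four input-weight blocks (input, forget, cell,
    output gates); the attribution pseudocode declares one matrix per layer.
    ``reduction`` picks the collapse: ``"cell-gate"`` (default — the candidate
    gate is the path through which input activity enters the cell state, so
    its weights carry the sign of a component's influence on the latent),
    ``"mean"`` (arithmetic mean over the four blocks), ``"input-gate"`` or
    ``"output-gate"``.
    """
    cfg = model.cfg

    def reduce(w: np.ndarray, d_in: int, d_h: int) -> np.ndarray:
        blocks = w.reshape(d_in, 4, d_h)  # gate blocks are contiguous on the last axis
        if reduction == "mean":
            red = blocks.mean(axis=1)
        elif reduction in _GATE_BLOCKS:
            red = blocks[:, _GATE_BLOCKS[reduction], :]
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
        return red.T  # (d_h, d_in)

    w_enc = reduce(model.params["enc.W_ih"].data, cfg.C, cfg.D_enc)
    w_main = reduce(model.params["main.W_ih"].data, cfg.D_enc, cfg.D_main)
    if w_enc.shape != (cfg.D_enc, cfg.C) or w_main.shape != (cfg.D_main, cfg.D_enc):
        raise ValueError("weight view shape mismatch with model config")
    return w_enc, w_main


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: HierarchicalAttentionNet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.cfg))
        f.attrs["seed"] = model.seed
        grp = f.create_group("weights")
        for k, p in model.params.items():
            grp.create_dataset(k, data=p.data)


def load_checkpoint(path, cfg: ModelConfig | None = None) -> HierarchicalAttentionNet:
    with h5py.File(path, "r") as f:
        stored = ModelConfig(**json.loads(f.attrs["config"]))
        if cfg is not None and cfg != stored:
            raise ValueError(f"checkpoint config {stored} does not match requested {cfg}")
        model = HierarchicalAttentionNet(stored, seed=int(f.attrs["seed"]))
        state = {k: f["weights"][k][...] for k in f["weights"]}
    model.load_state_dict(state)
    return model
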