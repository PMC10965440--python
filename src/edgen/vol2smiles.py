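"""Volume-to-SMILES translation with an encoder-decoder transformer.

The encoder ingests a voxelized molecule (plain electron density or an
ED+ESP decorated volume) through a "molecule embedding" that flattens the 3D
tensor into a 2D sequence of feature vectors, by one of two strategies:

* ``squeeze``  — a filters=1 3D convolution squeezes out the channel axis,
  then a filters=1 2D convolution squeezes one spatial axis, leaving an
  (n, n) map that is linearly projected to (n, d_model);
* ``strided`` — repeated 3D convolutions with strides (1, 2, 2) and d_model
  filters halve the two trailing spatial axes until they reach size 1 and
  are dropped, leaving (n, d_model) directly.

The decoder is a standard autoregressive token transformer with causal
masking and cross-attention to the encoder sequence.  With cross-attention
disabled the decoder runs as a pure GPT-style SMILES language model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .smiles_codec import (END, PAD, START, TokenSequence, Vocabulary,
                           canonicalize, detokenize, split_smiles, tokenize)
from .voxelize import DecoratedVolume, DensityGrid

__all__ = [
    "XformerModel",
    "XformerConfig",
    "expand_to_4d",
    "molecule_embedding",
    "train_translator",
    "translate",
    "sample_translate",
    "gpt_generate",
    "sequence_accuracy",
    "token_accuracy",
]

NEG_INF = -1e9


def expand_to_4d(volume) -> np.ndarray:
    """Add/arrange the trailing channel axis: (n,n,n) -> (n,n,n,1);
    a decorated volume becomes (n,n,n,2)."""
    if isinstance(volume, DecoratedVolume):
        return np.moveaxis(volume.array, 0, -1)
    if isinstance(volume, DensityGrid):
        return volume.values[..., None]
    a = np.asarray(volume)
    if a.ndim == 3:
        return a[..., None]
    if a.ndim == 4:
        if a.shape[-1] > 2:
            raise ValueError(f"at most 2 channels supported, got {a.shape[-1]}")
        return a
    raise ValueError(f"expected a 3D or 4D volume, got shape {a.shape}")


class _SqueezeEmbedding(nn.Module):
    """filters=1 conv chain: (B,n,n,n,C) -> (B,n,n) -> project -> (B,n,d)."""

    def __init__(self, n: int, in_channels: int, d_model: int, rng):
        self.conv3 = nn.Conv3d(in_channels, 1, k=3, rng=rng)
        self.conv2 = nn.Conv2d(n, 1, k=3, rng=rng)  # third spatial axis as channels
        self.proj = nn.Linear(n, d_model, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv3(x)                      # (B, n, n, n, 1)
        h = h.reshape(h.shape[0], h.shape[1], h.shape[2], h.shape[3])
        h = self.conv2(h)                      # (B, n, n, 1)
        h = h.reshape(h.shape[0], h.shape[1], h.shape[2])
        return self.proj(h)                    # (B, n, d_model)


class _StridedEmbedding(nn.Module):
    """Strided (1,2,2) conv chain with d_model filters: (B,n,n,n,C) -> (B,n,d)."""

    def __init__(self, n: int, in_channels: int, d_model: int, rng):
        if n < 2 or n & (n - 1):
            raise ValueError(f"strided embedding needs a power-of-two grid, got {n}")
        self.convs = []
        cin = in_channels
        side = n
        while side > 1:
            self.convs.append(nn.Conv3d(cin, d_model, k=3, rng=rng, stride=(1, 2, 2)))
            cin = d_model
            side //= 2

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()                 # (B, n, s/2, s/2, d)
        # trailing two spatial axes are now 1: drop them
        return h.reshape(h.shape[0], h.shape[1], h.shape[4])


class _MultiHeadAttention(nn.Module):
    def __init__(self, d_model: int, n_heads: int, rng):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = nn.Linear(d_model, d_model, rng)
        self.wk = nn.Linear(d_model, d_model, rng)
        self.wv = nn.Linear(d_model, d_model, rng)
        self.wo = nn.Linear(d_model, d_model, rng)

    def __call__(self, q_in: nn.Tensor, kv_in: nn.Tensor,
                 mask: np.ndarray | None = None) -> nn.Tensor:
        B, Lq, d = q_in.shape
        Lk = kv_in.shape[1]
        def split(t, L):
            return t.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)
        q = split(self.wq(q_in), Lq)
        k = split(self.wk(kv_in), Lk)
        v = split(self.wv(kv_in), Lk)
        att = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.dh))
        if mask is not None:
            att = att + nn.Tensor(mask.astype(att.dtype))
        att = nn.softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, Lq, d)
        return self.wo(out)


class _FeedForward(nn.Module):
    def __init__(self, d_model: int, d_ff: int, rng):
        self.fc1 = nn.Linear(d_model, d_ff, rng)
        self.fc2 = nn.Linear(d_ff, d_model, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(x).relu())


class _EncoderBlock(nn.Module):
    def __init__(self, d_model, n_heads, d_ff, rng):
        self.ln1 = nn.LayerNorm(d_model)
        self.attn = _MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = nn.LayerNorm(d_model)
        self.ff = _FeedForward(d_model, d_ff, rng)

    def __call__(self, x):
        h = self.ln1(x)
        x = x + self.attn(h, h)
        x = x + self.ff(self.ln2(x))
        return x


class _DecoderBlock(nn.Module):
    def __init__(self, d_model, n_heads, d_ff, rng):
        self.ln1 = nn.LayerNorm(d_model)
        self.self_attn = _MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = nn.LayerNorm(d_model)
        self.cross_attn = _MultiHeadAttention(d_model, n_heads, rng)
        self.ln3 = nn.LayerNorm(d_model)
        self.ff = _FeedForward(d_model, d_ff, rng)

    def __call__(self, x, memory, causal_mask, use_cross: bool = True):
        h = self.ln1(x)
        x = x + self.self_attn(h, h, mask=causal_mask)
        if use_cross and memory is not None:
            x = x + self.cross_attn(self.ln2(x), memory)
        x = x + self.ff(self.ln3(x))
        return x


@dataclass
class XformerConfig:
    d_model: int = 64
    n_heads: int = 2
    n_blocks: int = 2
    d_ff: int = 128
    max_len: int = 32
    strategy: str = "strided"      # or "squeeze"
    epochs: int = 300
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0


class XformerModel(nn.Module):
    """Encoder-decoder transformer over (volume sequence, token sequence)."""

    def __init__(self, vocab: Vocabulary, n_voxels: int, in_channels: int,
                 config: XformerConfig):
        if config.strategy not in ("squeeze", "strided"):
            raise ValueError(f"unknown embedding strategy {config.strategy!r}")
        rng = np.random.default_rng(config.seed)
        self.vocab = vocab
        self.config = config
        self.n_voxels = n_voxels
        self.in_channels = in_channels
        self.meta: dict = {"epochs": 0, "loss_curve": [], "seed": config.seed}
        d, h, ff = config.d_model, config.n_heads, config.d_ff
        if config.strategy == "squeeze":
            self.mol_embed = _SqueezeEmbedding(n_voxels, in_channels, d, rng)
        else:
            self.mol_embed = _StridedEmbedding(n_voxels, in_channels, d, rng)
        self.enc_pos = nn.Parameter((rng.standard_normal((n_voxels, d)) * 0.02
                                     ).astype(np.float32))
        self.tok_embed = nn.Embedding(len(vocab), d, rng)
        self.dec_pos = nn.Parameter((rng.standard_normal((config.max_len, d)) * 0.02
                                     ).astype(np.float32))
        self.enc_blocks = [_EncoderBlock(d, h, ff, rng) for _ in range(config.n_blocks)]
        self.dec_blocks = [_DecoderBlock(d, h, ff, rng) for _ in range(config.n_blocks)]
        self.ln_out = nn.LayerNorm(d)
        self.out_proj = nn.Linear(d, len(vocab), rng)

    # -- forward pieces ------------------------------------------------------
    def encode_volumes(self, vols: np.ndarray) -> nn.Tensor:
        """vols: (B, n, n, n, C) float32 -> encoder memory (B, n, d_model)."""
        x = self.mol_embed(nn.Tensor(vols.astype(np.float32)))
        x = x + self.enc_pos
        for blk in self.enc_blocks:
            x = blk(x)
        return x

    def decode_logits(self, ids: np.ndarray, memory: nn.Tensor | None,
                      use_cross: bool = True) -> nn.Tensor:
        """ids: (B, L) int -> logits (B, L, V) with causal self-attention."""
        B, L = ids.shape
        x = self.tok_embed(ids) + self.dec_pos[:L]
        causal = np.triu(np.full((L, L), NEG_INF, dtype=np.float32), k=1)
        for blk in self.dec_blocks:
            x = blk(x, memory, causal, use_cross=use_cross)
        return self.out_proj(self.ln_out(x))

    def descriptor(self) -> dict:
        c = self.config
        return {"kind": "vol2smiles", "strategy": c.strategy, "d_model": c.d_model,
                "n_heads": c.n_heads, "n_blocks": c.n_blocks, "d_ff": c.d_ff,
                "max_len": c.max_len,
                "n_voxels": self.n_voxels, "in_channels": self.in_channels,
                "vocab": self.vocab.tokens}


def molecule_embedding(vol4d: np.ndarray, strategy: str, params=None,
                       d_model: int = 64, seed: int = 0) -> np.ndarray:
    """Standalone molecule embedding: a 4D volume to a 2D (L, d_model) sequence.

    ``params`` may carry a pre-built embedding module (to reuse trained
    weights); otherwise a freshly initialized one is used.
    """
    a = expand_to_4d(vol4d)
    n, c = a.shape[0], a.shape[-1]
    if params is None:
        rng = np.random.default_rng(seed)
        if strategy == "squeeze":
            params = _SqueezeEmbedding(n, c, d_model, rng)
        elif strategy == "strided":
            params = _StridedEmbedding(n, c, d_model, rng)
        else:
            raise ValueError(f"unknown embedding strategy {strategy!r}")
    out = params(nn.Tensor(a[None].astype(np.float32)))
    return out.data[0]


def load_xformer_model(path) -> XformerModel:
    """Rebuild an XformerModel from a checkpoint archive written by ``model.save``."""
    import json
    import zipfile

    with zipfile.ZipFile(path) as zf:
        d = json.loads(zf.read("architecture.json"))
    cfg = XformerConfig(d_model=d["d_model"], n_heads=d["n_heads"],
                        n_blocks=d["n_blocks"], d_ff=d.get("d_ff", 128),
                        max_len=d["max_len"], strategy=d["strategy"])
    model = XformerModel(Vocabulary(tokens=d["vocab"]), n_voxels=d["n_voxels"],
                         in_channels=d["in_channels"], config=cfg)
    model.load_weights(path)
    return model


# ---------------------------------------------------------------------------
# training


def _encode_corpus(smiles: list[str], vocab: Vocabulary, max_len: int) -> np.ndarray:
    ids = np.zeros((len(smiles), max_len), dtype=np.int64)  # PAD = 0
    for i, s in enumerate(smiles):
        seq = tokenize(s, vocab, max_len=max_len).indices
        ids[i, :len(seq)] = seq
    return ids


def train_translator(pairs, config: XformerConfig | None = None,
                     vocab: Vocabulary | None = None,
                     model: XformerModel | None = None) -> XformerModel:
    """Teacher-forced cross-entropy training on (volume, SMILES) pairs.

    SMILES are canonicalized before tokenization so accuracy metrics are
    well-defined string matches.
    """
    config = config or XformerConfig()
    if len(pairs) == 0:
        raise ValueError("empty training dataset")
    vols = np.stack([expand_to_4d(v) for v, _ in pairs]).astype(np.float32)
    smiles = []
    for _, s in pairs:
        canon = canonicalize(s)
        smiles.append(canon if canon is not None else s)
    if vocab is None:
        vocab = Vocabulary.from_corpus(smiles)
    else:
        for s in smiles:
            for t in split_smiles(s):
                if t not in vocab.index:
                    raise ValueError(f"corpus token {t!r} missing from vocabulary")
    ids = _encode_corpus(smiles, vocab, config.max_len)
    if model is None:
        model = XformerModel(vocab, n_voxels=vols.shape[1],
                             in_channels=vols.shape[-1], config=config)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr, clip=5.0)
    n_data = len(pairs)
    V = len(vocab)
    # trim the common padded length to the longest sequence (all-PAD cols train nothing)
    L_used = int(max((ids != 0).sum(axis=1).max(), 2))
    ids = ids[:, :L_used]
    for epoch in range(config.epochs):
        order = rng.permutation(n_data)
        losses = []
        for b0 in range(0, n_data, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            memory = model.encode_volumes(vols[idx])
            inp, tgt = ids[idx][:, :-1], ids[idx][:, 1:]
            logits = model.decode_logits(inp, memory)
            logp = nn.log_softmax(logits, axis=-1)
            onehot = np.eye(V, dtype=np.float32)[tgt]
            mask = (tgt != vocab.pad_id).astype(np.float32)
            nll = -(logp * nn.Tensor(onehot)).sum(axis=-1)
            loss = (nll * nn.Tensor(mask)).sum() * (1.0 / max(mask.sum(), 1.0))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.meta["loss_curve"].append(float(np.mean(losses)))
    model.meta["epochs"] += config.epochs
    return model


# ---------------------------------------------------------------------------
# decoding


def _prepare_volume(volume, model: XformerModel) -> np.ndarray:
    a = expand_to_4d(volume)
    n = model.n_voxels
    if a.shape != (n, n, n, model.in_channels):
        raise ValueError(f"volume shape {a.shape} does not match model "
                         f"({n},{n},{n},{model.in_channels})")
    return a[None]


def _decode_loop(model: XformerModel, memory: nn.Tensor | None,
                 pick, use_cross: bool = True) -> list[int]:
    v = model.vocab
    ids = [v.start_id]
    for _ in range(model.config.max_len - 1):
        logits = model.decode_logits(np.asarray([ids]), memory,
                                     use_cross=use_cross).data[0, -1]
        nxt = pick(logits)
        ids.append(int(nxt))
        if nxt == v.end_id:
            break
    return ids


def translate(volume, model: XformerModel) -> str:
    """Greedy argmax decoding from START until END or max_len (deterministic)."""
    memory = model.encode_volumes(_prepare_volume(volume, model))
    ids = _decode_loop(model, memory, pick=lambda lg: int(np.argmax(lg)))
    return detokenize(ids, model.vocab)


def sample_translate(volume, model: XformerModel, temperature: float = 1.0,
                     seed: int = 0) -> str:
    """Token-by-token sampling from softmax(logits / temperature)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    memory = model.encode_volumes(_prepare_volume(volume, model))
    def pick(lg):
        x = lg.astype(np.float64) / temperature
        x -= x.max()
        p = np.exp(x)
        p /= p.sum()
        return rng.choice(len(p), p=p)
    ids = _decode_loop(model, memory, pick=pick)
    return detokenize(ids, model.vocab)


def gpt_generate(model: XformerModel, seed: int = 0, temperature: float = 1.0) -> str:
    """Run the decoder alone (cross-attention disabled) as a SMILES language model."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    def pick(lg):
        x = lg.astype(np.float64) / temperature
        x -= x.max()
        p = np.exp(x)
        p /= p.sum()
        return rng.choice(len(p), p=p)
    ids = _decode_loop(model, None, pick=pick, use_cross=False)
    return detokenize(ids, model.vocab)


# ---------------------------------------------------------------------------
# accuracy metrics


def sequence_accuracy(preds: list[str], truths: list[str],
                      by_molecule: bool = False) -> float:
    """Exact canonical-string-match fraction.

    With ``by_molecule`` both sides are parsed and compared as canonical
    forms (molecule identity) instead of raw strings.
    """
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    if not preds:
        raise ValueError("empty lists")
    hits = 0
    for p, t in zip(preds, truths):
        if by_molecule:
            cp, ct = canonicalize(p), canonicalize(t)
            hits += int(cp is not None and cp == ct)
        else:
            hits += int(p == t)
    return hits / len(preds)


def token_accuracy(preds: list[str], truths: list[str]) -> float:
    """Micro-averaged positionwise token match on END-terminated sequences.

    Each string is split into tokens with END appended; positions up to the
    shorter sequence are compared, so a truncated or run-on prediction is
    penalized at the position where the END tokens disagree.
    """
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    if not preds:
        raise ValueError("empty lists")
    match = total = 0
    for p, t in zip(preds, truths):
        tp = (split_smiles(p, strict=False) if p else []) + [END]
        tt = (split_smiles(t, strict=False) if t else []) + [END]
        m = min(len(tp), len(tt))
        match += sum(a == b for a, b in zip(tp[:m], tt[:m]))
        total += m
    return match / total
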