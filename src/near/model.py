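"""1D residual convolutional embedding network.

Architecture: a learned token-embedding table of width ``d`` followed by
``n_blocks`` residual blocks, each computing

    ResidualBlock(x) = x + Conv2(sigma(Conv1(sigma(x))))

where Conv1 and Conv2 are 1D convolutions with identical hyper-parameters
(``d`` channels in and out, odd kernel, symmetric zero padding) and no weight
sharing anywhere. The final block's output is the embedding: one row per
residue, no output head, no normalization layer (search normalizes
explicitly; training uses raw dot products).

The network is small enough (default ~7.3M parameters) that forward and
backward passes are written directly in numpy. Convolutions are evaluated by
im2col + matmul; the backward pass mirrors it. Padded positions of a batched
input are forced to zero after the token lookup and after every convolution,
which makes a sequence's embedding bit-comparable whether it is embedded
alone or inside a padded batch (the zeros seen past a sequence end are the
same zeros symmetric padding would supply).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequences import ALPHABET_SIZE, ProteinSequence

_ACTIVATIONS = ("ELU", "ReLU", "GELU")


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the embedding network.

    embed_dim
        Width ``d`` of residue vectors and of every convolution (default 256).
    n_blocks
        Number of residual blocks (default 8).
    kernel_size
        Convolution kernel; odd so a length-preserving symmetric padding of
        (kernel_size - 1) / 2 exists (default 7).
    activation
        sigma in the block formula; ELU by default.
    alphabet_size
        Rows of the token table: 20 canonical amino acids + 1 unknown token.
    """

    embed_dim: int = 256
    n_blocks: int = 8
    kernel_size: int = 7
    activation: str = "ELU"
    alphabet_size: int = ALPHABET_SIZE

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be positive")

    @property
    def receptive_field_radius(self) -> int:
        """Max distance (in residues) an input edit can travel to an output row."""
        return self.n_blocks * 2 * ((self.kernel_size - 1) // 2)


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "ELU":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if name == "ReLU":
        return np.maximum(z, 0.0)
    # GELU (tanh approximation)
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * z * (1.0 + np.tanh(c * (z + 0.044715 * z**3)))


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "ELU":
        return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))
    if name == "ReLU":
        return (z > 0).astype(z.dtype)
    c = np.sqrt(2.0 / np.pi)
    t = np.tanh(c * (z + 0.044715 * z**3))
    return 0.5 * (1.0 + t) + 0.5 * z * (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * z**2)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, n, d) -> (B, n, k, d) sliding windows under symmetric zero padding."""
    p = (k - 1) // 2
    n = x.shape[1]
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    return np.stack([xp[:, i : i + n, :] for i in range(k)], axis=2)


def conv1d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Length-preserving 1D convolution.

    x: (B, n, d_in); weight: (d_out, d_in, k); bias: (d_out,).
    """
    d_out, d_in, k = weight.shape
    if x.shape[-1] != d_in:
        raise ValueError(
            f"conv weight expects {d_in} input channels, got {x.shape[-1]}"
        )
    cols = _im2col(x, k)  # (B, n, k, d_in)
    wm = weight.transpose(2, 1, 0).reshape(k * d_in, d_out)
    b_, n_ = x.shape[0], x.shape[1]
    y = cols.reshape(b_ * n_, k * d_in) @ wm
    return y.reshape(b_, n_, d_out) + bias


def _conv1d_backward(
    grad_y: np.ndarray, x: np.ndarray, weight: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d. Returns (grad_x, grad_weight, grad_bias)."""
    d_out, d_in, k = weight.shape
    p = (k - 1) // 2
    b_, n_ = x.shape[0], x.shape[1]
    cols = _im2col(x, k).reshape(b_ * n_, k * d_in)
    gy = grad_y.reshape(b_ * n_, d_out)
    wm = weight.transpose(2, 1, 0).reshape(k * d_in, d_out)
    grad_wm = cols.T @ gy  # (k*d_in, d_out)
    grad_weight = grad_wm.reshape(k, d_in, d_out).transpose(2, 1, 0)
    grad_bias = gy.sum(axis=0)
    gcols = (gy @ wm.T).reshape(b_, n_, k, d_in)
    grad_xp = np.zeros((b_, n_ + 2 * p, d_in), dtype=x.dtype)
    for i in range(k):
        grad_xp[:, i : i + n_, :] += gcols[:, :, i, :]
    return grad_xp[:, p : p + n_, :], grad_weight, grad_bias


def residual_block(
    x: np.ndarray, block_weights: dict[str, np.ndarray], activation: str = "ELU"
) -> np.ndarray:
    """Apply one residual block, x + Conv2(sigma(Conv1(sigma(x)))).

    ``x`` may be (n, d) or batched (B, n, d); shape is preserved. Both
    convolutions must carry identical hyper-parameters (d channels in/out,
    same kernel).
    """
    w1, b1 = block_weights["W1"], block_weights["b1"]
    w2, b2 = block_weights["W2"], block_weights["b2"]
    if w1.shape != w2.shape:
        raise ValueError("Conv1 and Conv2 must have identical shapes")
    d = x.shape[-1]
    if w1.shape[0] != d or w1.shape[1] != d:
        raise ValueError(
            f"block weights are {w1.shape[0]}x{w1.shape[1]} channels, input has {d}"
        )
    single = x.ndim == 2
    xb = x[None] if single else x
    h = conv1d(_act(activation, xb), w1, b1)
    out = xb + conv1d(_act(activation, h), w2, b2)
    return out[0] if single else out


class EmbeddingModel:
    """The residue embedding network: token table + residual trunk.

    Parameters live in ``self.params``: ``tok`` of shape
    (alphabet_size, d) and per block ``W1``/``b1``/``W2``/``b2``.
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        seed: int = 0,
        dtype: type = np.float32,
    ) -> None:
        self.config = config or ModelConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        d, k = self.config.embed_dim, self.config.kernel_size
        he = np.sqrt(2.0 / (d * k))
        self.params: dict[str, np.ndarray] = {
            "tok": (rng.standard_normal((self.config.alphabet_size, d)) / np.sqrt(d)).astype(dtype)
        }
        for b in range(self.config.n_blocks):
            self.params[f"b{b}.W1"] = (he * rng.standard_normal((d, d, k))).astype(dtype)
            self.params[f"b{b}.b1"] = np.zeros(d, dtype=dtype)
            self.params[f"b{b}.W2"] = (he * rng.standard_normal((d, d, k))).astype(dtype)
            self.params[f"b{b}.b2"] = np.zeros(d, dtype=dtype)

    # ---------------------------------------------------------------- forward

    def forward_tokens(
        self, tokens: np.ndarray, want_cache: bool = False
    ) -> np.ndarray | tuple[np.ndarray, dict]:
        """Embed a batch of token id rows.

        tokens: (B, n) int array; entries < 0 mark padding. Padded rows of the
        output are zero, and valid rows equal what the sequence would produce
        embedded alone (batch-independence contract).
        """
        if tokens.ndim != 2:
            raise ValueError("tokens must be (B, n)")
        act = self.config.activation
        valid = tokens >= 0
        mask = valid[..., None].astype(self.dtype)
        x = self.params["tok"][np.clip(tokens, 0, None)] * mask
        cache: dict = {"tokens": tokens, "mask": mask, "blocks": []}
        for b in range(self.config.n_blocks):
            w1, b1 = self.params[f"b{b}.W1"], self.params[f"b{b}.b1"]
            w2, b2 = self.params[f"b{b}.W2"], self.params[f"b{b}.b2"]
            z1 = _act(act, x)  # zero at padding since x is zero there
            y1 = conv1d(z1, w1, b1) * mask
            z2 = _act(act, y1)
            y2 = conv1d(z2, w2, b2) * mask
            if want_cache:
                cache["blocks"].append((x, z1, y1, z2))
            x = x + y2
        if want_cache:
            return x, cache
        return x

    def backward(self, grad_out: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Backprop ``grad_out`` (B, n, d) through the cached forward pass."""
        act = self.config.activation
        mask = cache["mask"]
        g = grad_out * mask
        grads = {name: np.zeros_like(p) for name, p in self.params.items()}
        for b in range(self.config.n_blocks - 1, -1, -1):
            x, z1, y1, z2 = cache["blocks"][b]
            w1, w2 = self.params[f"b{b}.W1"], self.params[f"b{b}.W2"]
            g_z2, gw2, gb2 = _conv1d_backward(g, z2, w2)
            grads[f"b{b}.W2"] += gw2
            grads[f"b{b}.b2"] += gb2
            g_y1 = g_z2 * _act_grad(act, y1) * mask
            g_z1, gw1, gb1 = _conv1d_backward(g_y1, z1, w1)
            grads[f"b{b}.W1"] += gw1
            grads[f"b{b}.b1"] += gb1
            g = g + g_z1 * _act_grad(act, x) * mask
        tokens = cache["tokens"]
        valid = tokens >= 0
        np.add.at(grads["tok"], tokens[valid], g[valid])
        return grads

    # ---------------------------------------------------------- sequence API

    def embed(self, seq: ProteinSequence) -> np.ndarray:
        """Embed one sequence -> (n, d) matrix, row i the vector of residue i.

        Deterministic given the weights; independent of any batching.
        """
        return self.forward_tokens(seq.tokens()[None])[0]

    def embed_batch(self, seqs: Sequence[ProteinSequence]) -> list[np.ndarray]:
        """Embed sequences together (padded batch); returns per-sequence matrices."""
        if not seqs:
            return []
        n_max = max(len(s) for s in seqs)
        tokens = np.full((len(seqs), n_max), -1, dtype=np.int64)
        for i, s in enumerate(seqs):
            tokens[i, : len(s)] = s.tokens()
        out = self.forward_tokens(tokens)
        return [out[i, : len(s)] for i, s in enumerate(seqs)]

    def embed_many(self, seqs: Iterable[ProteinSequence], batch_size: int = 32
                   ) -> dict[str, np.ndarray]:
        """Embed a stream of sequences -> {seq_id: (n, d) matrix}."""
        out: dict[str, np.ndarray] = {}
        chunk: list[ProteinSequence] = []
        for s in seqs:
            if s.id in out or any(c.id == s.id for c in chunk):
                raise ValueError(f"duplicate sequence id {s.id!r}")
            chunk.append(s)
            if len(chunk) == batch_size:
                for c, m in zip(chunk, self.embed_batch(chunk)):
                    out[c.id] = m
                chunk = []
        for c, m in zip(chunk, self.embed_batch(chunk)):
            out[c.id] = m
        return out

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Write config + weights to a single .npz container."""
        payload = {f"param/{k}": v for k, v in self.params.items()}
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["config_json"]).decode()))
            model = cls(cfg, seed=0)
            for key in z.files:
                if key.startswith("param/"):
                    name = key[len("param/"):]
                    if name not in model.params:
                        raise ValueError(f"unexpected parameter {name!r} in checkpoint")
                    model.params[name] = z[key]
        model.dtype = model.params["tok"].dtype.type
        return model


def count_parameters(model: EmbeddingModel) -> int:
    """Number of learnable scalars (token table + every conv weight and bias)."""
    return int(sum(p.size for p in model.params.values()))


def trunk_parameter_count(config: ModelConfig) -> int:
    """Closed form for the residual trunk alone: n_blocks * 2 * (d*d*k + d)."""
    d, k = config.embed_dim, config.kernel_size
    return config.n_blocks * 2 * (d * d * k + d)
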