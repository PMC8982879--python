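"""Graph encoder: MLP -> BiLSTM -> residual graph convolutions -> max-pool.

The encoder maps one structure graph to a fixed-length unit-norm
descriptor.  A small MLP lifts the raw node features, a bidirectional
LSTM injects the residue order (graph convolution alone is permutation
invariant and cannot see the chain), stacked residual graph-convolution
blocks aggregate spatial neighbourhoods through the inverse-distance
adjacency, and a global max pool over residues followed by L2
normalisation yields the descriptor.  The final node matrix doubles as
residue-level embeddings for the alignment stage.

Graph convolution is X' = sigma(A X W): the adjacency itself acts as the
aggregation weight (no Laplacian normalisation — the adjacency is already
bounded with a self-loop by construction).  A residual block chains two
convolutions with a skip connection, X'' = sigma(A X' W' + X Ws), where
Ws is the identity when dimensions already match.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, stack
from .featurization import StructureGraph

__all__ = [
    "EncoderConfig",
    "Descriptor",
    "ResidueEmbeddings",
    "GraphEncoder",
    "graph_conv",
    "residual_block",
    "sequential_context",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    ``input_dim`` is the raw node feature width (2^M).  ``descriptor_dim``
    (L) is the width of the final graph-convolution block, hence of both
    the residue embeddings and the pooled descriptor; it must stay fixed
    across a trained encoder pair.  ``distance_scale`` pre-scales the
    distance feature columns (raw values are tens of Angstrom) so all
    inputs are O(1) without batch statistics.
    """

    input_dim: int = 32
    mlp_dims: tuple[int, ...] = (64, 128)
    lstm_hidden: int = 64
    n_res_blocks: int = 3
    gc_dim: int = 256
    descriptor_dim: int = 512
    dropout_rate: float = 0.1
    activation: str = "leaky_relu"
    leaky_slope: float = 0.01
    distance_scale: float = 0.1

    def __post_init__(self) -> None:
        dims = (self.input_dim, *self.mlp_dims, self.lstm_hidden,
                self.gc_dim, self.descriptor_dim)
        if any(d <= 0 for d in dims) or self.n_res_blocks < 1:
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation not in ("leaky_relu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @classmethod
    def small(cls, descriptor_dim: int = 64) -> "EncoderConfig":
        """Reduced CPU-scale configuration (desk-scale experiments)."""
        return cls(
            mlp_dims=(32,),
            lstm_hidden=16,
            n_res_blocks=1,
            gc_dim=64,
            descriptor_dim=descriptor_dim,
            dropout_rate=0.0,
        )


@dataclass
class Descriptor:
    """Fixed-length unit-norm embedding of one structure."""

    structure_id: str
    vector: np.ndarray  # (L,), unit Euclidean norm
    n_residues: int


@dataclass
class ResidueEmbeddings:
    """Per-residue embeddings (rows unit-norm), for residue alignment."""

    structure_id: str
    matrix: np.ndarray  # (N_r, L)


def _act(x: Tensor, activation: str, slope: float) -> Tensor:
    if activation == "identity":
        return x
    return x.relu() if activation == "relu" else x.leaky_relu(slope)


def graph_conv(X, A, W, activation: str = "leaky_relu",
               slope: float = 0.01) -> Tensor:
    """One graph convolution, sigma(A X W).

    Equivalent to the per-node form x_j' = sigma(sum_k a_jk x_k W).
    ``activation`` may also be ``"identity"``.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    A = A if isinstance(A, Tensor) else Tensor(A)
    W = W if isinstance(W, Tensor) else Tensor(W)
    out = A @ X @ W
    if activation == "identity":
        return out
    return _act(out, activation, slope)


def residual_block(
    X,
    A,
    W1,
    W2,
    Ws=None,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    train: bool = False,
    activation: str = "leaky_relu",
    slope: float = 0.01,
) -> Tensor:
    """Two graph convolutions with a skip connection.

    The first convolution uses ReLU followed by (optional) dropout; the
    block output is sigma(A X' W2 + X Ws) with ``Ws = None`` meaning the
    identity skip (dimensions must then already match).
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    A = A if isinstance(A, Tensor) else Tensor(A)
    h = graph_conv(X, A, W1, activation="relu")
    if train and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
        h = h * Tensor(mask)
    skip = X if Ws is None else X @ (Ws if isinstance(Ws, Tensor) else Tensor(Ws))
    out = (A @ h) @ (W2 if isinstance(W2, Tensor) else Tensor(W2)) + skip
    return _act(out, activation, slope)


def _lstm_pass(X: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
               reverse: bool) -> Tensor:
    """Single-direction LSTM over the residue axis of X (N, d) -> (N, H)."""
    n = X.shape[0]
    hidden = Wh.shape[0]
    xw = X @ Wx  # precompute input contributions for all steps
    h = Tensor(np.zeros(hidden))
    c = Tensor(np.zeros(hidden))
    outs: list[Tensor] = [None] * n  # type: ignore[list-item]
    order = range(n - 1, -1, -1) if reverse else range(n)
    for t in order:
        z = xw[t] + h @ Wh + b
        i = z[0:hidden].sigmoid()
        f = z[hidden:2 * hidden].sigmoid()
        g = z[2 * hidden:3 * hidden].tanh()
        o = z[3 * hidden:4 * hidden].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs[t] = h
    return stack(outs, axis=0)


def sequential_context(X, params: dict, prefix: str = "lstm") -> Tensor:
    """BiLSTM over the residue sequence; output (N_r, 2*lstm_hidden).

    Forward and reverse hidden states are concatenated per position, so
    the output is sensitive to residue order (which graph convolution,
    being permutation invariant, cannot recover on its own).
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    if X.shape[0] == 0:
        raise ValueError("empty input sequence")
    fwd = _lstm_pass(X, params[f"{prefix}_fwd_Wx"], params[f"{prefix}_fwd_Wh"],
                     params[f"{prefix}_fwd_b"], reverse=False)
    bwd = _lstm_pass(X, params[f"{prefix}_bwd_Wx"], params[f"{prefix}_bwd_Wh"],
                     params[f"{prefix}_bwd_b"], reverse=True)
    return concat([fwd, bwd], axis=1)


def _init_params(config: EncoderConfig, rng: np.random.Generator) -> dict:
    """He-style initialisation; LSTM forget-gate bias starts at 1."""
    params: dict[str, Tensor] = {}

    def weight(name: str, fan_in: int, fan_out: int) -> None:
        params[name] = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
            requires_grad=True,
        )

    dim = config.input_dim
    for i, out in enumerate(config.mlp_dims):
        weight(f"mlp{i}_W", dim, out)
        params[f"mlp{i}_b"] = Tensor(np.zeros(out), requires_grad=True)
        dim = out

    hid = config.lstm_hidden
    for direction in ("fwd", "bwd"):
        weight(f"lstm_{direction}_Wx", dim, 4 * hid)
        weight(f"lstm_{direction}_Wh", hid, 4 * hid)
        b = np.zeros(4 * hid)
        b[hid:2 * hid] = 1.0
        params[f"lstm_{direction}_b"] = Tensor(b, requires_grad=True)

    dim = 2 * hid
    block_dims = [config.gc_dim] * (config.n_res_blocks - 1) + [config.descriptor_dim]
    for i, out in enumerate(block_dims):
        weight(f"res{i}_W1", dim, out)
        weight(f"res{i}_W2", out, out)
        if dim != out:
            weight(f"res{i}_Ws", dim, out)
        dim = out
    return params


class GraphEncoder:
    """The trainable encoder: owns a config and a parameter set."""

    def __init__(self, config: EncoderConfig, params: dict | None = None,
                 seed: int = 0):
        self.config = config
        if params is None:
            params = _init_params(config, np.random.default_rng(seed))
        self.params = params

    # ------------------------------------------------------------------
    def clone(self) -> "GraphEncoder":
        """Deep copy (used to spawn the momentum key encoder)."""
        params = {
            k: Tensor(v.data.copy(), requires_grad=v.requires_grad)
            for k, v in self.params.items()
        }
        return GraphEncoder(copy.deepcopy(self.config), params)

    def set_trainable(self, flag: bool) -> None:
        for p in self.params.values():
            p.requires_grad = flag
            p.grad = None

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ------------------------------------------------------------------
    def forward(self, g: StructureGraph, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Run the network; returns (node matrix (N_r, L), descriptor (L,)).

        The descriptor is the column-wise max over residues, L2-normalised.
        The node matrix is returned un-normalised (rows are normalised
        only where consumed as residue-level descriptors).
        """
        if g.n_residues == 0:
            raise ValueError("cannot encode an empty structure")
        cfg = self.config
        scale = np.full(cfg.input_dim, cfg.distance_scale)
        scale[-1] = 1.0  # angle column is already in [-1, 1]
        H: Tensor = Tensor(g.node_features * scale)
        A = Tensor(g.adjacency)
        for i in range(len(cfg.mlp_dims)):
            H = _act(H @ self.params[f"mlp{i}_W"] + self.params[f"mlp{i}_b"],
                     cfg.activation, cfg.leaky_slope)
        H = sequential_context(H, self.params)
        for i in range(cfg.n_res_blocks):
            H = residual_block(
                H, A,
                self.params[f"res{i}_W1"], self.params[f"res{i}_W2"],
                self.params.get(f"res{i}_Ws"),
                dropout_rate=cfg.dropout_rate, rng=rng, train=train,
                activation=cfg.activation, slope=cfg.leaky_slope,
            )
        descriptor = H.max(axis=0).l2_normalize()
        return H, descriptor

    def encode(self, g: StructureGraph) -> tuple[ResidueEmbeddings, Descriptor]:
        """Eval-mode encoding to plain numpy outputs."""
        nodes, desc = self.forward(g, train=False)
        mat = nodes.data
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        mat = mat / np.maximum(norms, 1e-12)
        return (
            ResidueEmbeddings(g.structure_id, mat),
            Descriptor(g.structure_id, desc.data.copy(), g.n_residues),
        )

    def encode_batch(
        self, graphs: list[StructureGraph]
    ) -> list[tuple[ResidueEmbeddings, Descriptor]]:
        """Encode a mini-batch; identical to per-structure encoding."""
        return [self.encode(g) for g in graphs]


def save_checkpoint(path: str | Path, query_encoder: GraphEncoder,
                    key_encoder: GraphEncoder | None = None,
                    step: int = 0) -> None:
    """Persist config + parameter sets as a single .npz archive."""
    payload: dict[str, np.ndarray] = {
        "__config__": np.array(json.dumps(asdict(query_encoder.config))),
        "__step__": np.array(step),
    }
    for k, v in query_encoder.params.items():
        payload[f"q::{k}"] = v.data
    if key_encoder is not None:
        for k, v in key_encoder.params.items():
            payload[f"k::{k}"] = v.data
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[GraphEncoder, GraphEncoder | None, int]:
    """Restore encoders saved by :func:`save_checkpoint` (bit-compatible)."""
    with np.load(path, allow_pickle=False) as npz:
        raw = json.loads(str(npz["__config__"]))
        raw["mlp_dims"] = tuple(raw["mlp_dims"])
        config = EncoderConfig(**raw)
        step = int(npz["__step__"])
        q_params, k_params = {}, {}
        for key in npz.files:
            if key.startswith("q::"):
                q_params[key[3:]] = Tensor(npz[key], requires_grad=True)
            elif key.startswith("k::"):
                k_params[key[3:]] = Tensor(npz[key], requires_grad=False)
    query = GraphEncoder(config, q_params)
    key = GraphEncoder(config, k_params) if k_params else None
    return query, key, step
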