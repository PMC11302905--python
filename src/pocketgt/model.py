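"""The edge-biased graph transformer pocket classifier.

Architecture
------------
Node inputs are the 21-way amino-acid one-hot mapped through a learned
embedding ``E_aa`` (21 x d); with SASA enabled the d-dimensional SASA RBF
block is concatenated and the 2d vector projected back to width d.  Each of
the L layers runs multi-head attention restricted to graph edges: for an
edge (i, j) the logit of head h is the scaled elementwise TRIPLE product

    (1 / sqrt(d_h)) * sum_k  q_ik * k_jk * b_ijk

where b_ij is a learned projection of the distance RBF edge feature.  Logits
are clamped to [-5, 5] before the per-neighborhood softmax (clamping the
softmax *input* is the only placement that can aid numerical stability).
Heads are concatenated, output-projected, and combined with dropout,
residual connections, layer normalization and a ReLU feed-forward block.
Edge features are not updated across layers.  Sum pooling over nodes feeds a
d -> d -> 1 ReLU MLP and a sigmoid; training minimizes binary cross-entropy.

Because only pairwise distances and per-residue scalars enter, the score is
exactly invariant under rigid motions (E(3)) of the input coordinates, and
sum pooling makes it invariant under node relabeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, EmptyPocketError
from .graphs import FeatureConfig, N_AA_TOKENS, PocketGraph, edge_features, node_features

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` must be divisible by ``n_heads``; ``ffn_hidden`` defaults
    to twice the hidden width.  ``clamp_bound`` bounds attention logits.
    """

    n_layers: int = 8
    hidden_dim: int = 128
    n_heads: int = 8
    ffn_hidden: int | None = None
    dropout: float = 0.1
    clamp_bound: float = 5.0
    use_sasa: bool = True
    sasa_range: tuple[float, float] = (0.0, 350.0)
    dist_range: tuple[float, float] = (3.0, 25.0)

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ConfigError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}"
            )
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.clamp_bound <= 0:
            raise ConfigError("clamp_bound must be positive")

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_heads

    @property
    def ffn_width(self) -> int:
        return 2 * self.hidden_dim if self.ffn_hidden is None else self.ffn_hidden

    @property
    def features(self) -> FeatureConfig:
        return FeatureConfig(
            hidden_dim=self.hidden_dim,
            sasa_range=self.sasa_range,
            dist_range=self.dist_range,
            use_sasa=self.use_sasa,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sasa_range"] = list(self.sasa_range)
        d["dist_range"] = list(self.dist_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["sasa_range"] = tuple(d["sasa_range"])
        d["dist_range"] = tuple(d["dist_range"])
        return cls(**d)


# -- parameters ----------------------------------------------------------------

def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_model(cfg: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """Reproducible fan-in-scaled uniform initialization.

    Weight matrices are stored as ``[in, out]`` (applied as ``x @ W + b``);
    normalization gains start at 1, offsets at 0, biases at 0.  The
    amino-acid embedding has no bias.
    """
    rng = np.random.default_rng(seed)
    d, f = cfg.hidden_dim, cfg.ffn_width
    params: dict[str, np.ndarray] = {}
    params["aa_embed"] = _uniform(rng, N_AA_TOKENS, (N_AA_TOKENS, d))
    if cfg.use_sasa:
        params["in_proj_W"] = _uniform(rng, 2 * d, (2 * d, d))
        params["in_proj_b"] = np.zeros(d)
    for l in range(cfg.n_layers):
        p = f"layer{l}."
        for name in ("q", "k", "v", "e", "o"):
            params[p + name + "_W"] = _uniform(rng, d, (d, d))
            params[p + name + "_b"] = np.zeros(d)
        params[p + "ffn1_W"] = _uniform(rng, d, (d, f))
        params[p + "ffn1_b"] = np.zeros(f)
        params[p + "ffn2_W"] = _uniform(rng, f, (f, d))
        params[p + "ffn2_b"] = np.zeros(d)
        params[p + "ln1_g"] = np.ones(d)
        params[p + "ln1_b"] = np.zeros(d)
        params[p + "ln2_g"] = np.ones(d)
        params[p + "ln2_b"] = np.zeros(d)
    params["mlp1_W"] = _uniform(rng, d, (d, d))
    params["mlp1_b"] = np.zeros(d)
    params["mlp2_W"] = _uniform(rng, d, (d, 1))
    params["mlp2_b"] = np.zeros(1)
    return params


def count_parameters(params: dict[str, np.ndarray]) -> int:
    """Total number of trainable scalars."""
    return int(sum(v.size for v in params.values()))


def wrap_parameters(params: dict[str, np.ndarray], requires_grad: bool = True) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in params.items()}


# -- core blocks ----------------------------------------------------------------

def attention_logits(q: np.ndarray, k: np.ndarray, b: np.ndarray, clamp_bound: float = 5.0) -> float:
    """Scalar edge logit: scaled triple product, clamped.

    ``(1/sqrt(d_h)) * sum_k q_k * k_k * b_k`` — the edge projection enters
    multiplicatively inside the sum, not as an additive bias.
    """
    q, k, b = (np.asarray(x, float) for x in (q, k, b))
    if not (q.shape == k.shape == b.shape) or q.ndim != 1:
        raise ValueError("q, k, b must be 1-D vectors of equal length")
    raw = float((q * k * b).sum() / np.sqrt(q.shape[0]))
    return float(np.clip(raw, -clamp_bound, clamp_bound))


def _layer_norm(x: Tensor, gain: Tensor, offset: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gain + offset


def _dropout(x: Tensor, rate: float, training: bool, rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def multi_head_attention(
    f: Tensor,
    edge_bias: Tensor,
    edges: np.ndarray,
    layer_params: dict[str, Tensor],
    cfg: ModelConfig,
    prefix: str,
) -> Tensor:
    """Edge-restricted multi-head attention; returns ``[N, d]`` (pre output-projection).

    ``edge_bias`` is the projected edge feature ``[E, d]``; attention for
    node i runs over the directed edges (i, j), softmax-normalized within
    each neighborhood.  Nodes without neighbors get a zero vector.
    """
    n, d = f.shape
    h_count, dh = cfg.n_heads, cfg.head_dim
    q = f @ layer_params[prefix + "q_W"] + layer_params[prefix + "q_b"]
    k = f @ layer_params[prefix + "k_W"] + layer_params[prefix + "k_b"]
    v = f @ layer_params[prefix + "v_W"] + layer_params[prefix + "v_b"]
    if edges.shape[0] == 0:
        return Tensor(np.zeros((n, d))) + q * 0.0  # keep tape connectivity
    centers, neighbors = edges[:, 0], edges[:, 1]
    q_e = ad.gather(q, centers).reshape((-1, h_count, dh))
    k_e = ad.gather(k, neighbors).reshape((-1, h_count, dh))
    v_e = ad.gather(v, neighbors).reshape((-1, h_count, dh))
    b_e = edge_bias.reshape((-1, h_count, dh))
    logits = (q_e * k_e * b_e).sum(axis=-1) * (1.0 / np.sqrt(dh))  # [E, H]
    logits = ad.clamp(logits, -cfg.clamp_bound, cfg.clamp_bound)
    w = ad.texp(logits)
    denom = ad.segment_sum(w, centers, n)  # [N, H]
    attn = w * ad.gather(denom, centers) ** -1.0  # [E, H]
    msg = attn.reshape((-1, h_count, 1)) * v_e  # [E, H, dh]
    out = ad.segment_sum(msg, centers, n)  # [N, H, dh]
    return out.reshape((n, d))


def gt_layer(
    f: Tensor,
    edge_bias_input: Tensor,
    edges: np.ndarray,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    layer: int,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """One graph-transformer layer (attention + FFN, residuals, layer norm)."""
    prefix = f"layer{layer}."
    edge_bias = (
        edge_bias_input @ params[prefix + "e_W"] + params[prefix + "e_b"]
        if edges.shape[0]
        else Tensor(np.zeros((0, cfg.hidden_dim)))
    )
    o = multi_head_attention(f, edge_bias, edges, params, cfg, prefix)
    o = _dropout(o, cfg.dropout, training, rng)
    attn_out = o @ params[prefix + "o_W"] + params[prefix + "o_b"]
    f_mid = _layer_norm(attn_out + f, params[prefix + "ln1_g"], params[prefix + "ln1_b"])
    hidden = ad.relu(f_mid @ params[prefix + "ffn1_W"] + params[prefix + "ffn1_b"])
    hidden = _dropout(hidden, cfg.dropout, training, rng)
    ffn_out = hidden @ params[prefix + "ffn2_W"] + params[prefix + "ffn2_b"]
    return _layer_norm(ffn_out + f_mid, params[prefix + "ln2_g"], params[prefix + "ln2_b"])


def _batch_arrays(graphs: list[PocketGraph], fcfg: FeatureConfig):
    """Disjoint-union batching: concatenated features with offset edge indices."""
    feats, efeats, edge_list, graph_ids = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        feats.append(node_features(g, fcfg))
        efeats.append(edge_features(g, fcfg))
        edge_list.append(g.edges + offset)
        graph_ids.append(np.full(g.n_nodes, gi))
        offset += g.n_nodes
    return (
        np.concatenate(feats),
        np.concatenate(efeats) if offset else np.empty((0, fcfg.hidden_dim)),
        np.concatenate(edge_list),
        np.concatenate(graph_ids),
    )


def forward(
    graphs: list[PocketGraph] | PocketGraph,
    params: dict,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Run the model; returns ``(scores, logits)`` as length-B tensors.

    ``graphs`` may be a single graph or a batch (processed as one disjoint
    union).  ``params`` may hold numpy arrays (inference) or
    :class:`Tensor` leaves (training).
    """
    if isinstance(graphs, PocketGraph):
        graphs = [graphs]
    if not graphs:
        raise EmptyPocketError("forward() needs at least one graph")
    if any(not isinstance(p, Tensor) for p in params.values()):
        params = {k: v if isinstance(v, Tensor) else Tensor(v) for k, v in params.items()}
    fcfg = cfg.features
    x, edge_rbf, edges, graph_ids = _batch_arrays(graphs, fcfg)
    onehot = Tensor(x[:, :N_AA_TOKENS])
    f = onehot @ params["aa_embed"]
    if cfg.use_sasa:
        f = ad.concat([f, Tensor(x[:, N_AA_TOKENS:])], axis=1)
        f = f @ params["in_proj_W"] + params["in_proj_b"]
    edge_rbf_t = Tensor(edge_rbf)
    for l in range(cfg.n_layers):
        f = gt_layer(f, edge_rbf_t, edges, params, cfg, l, training=training, rng=rng)
    h = ad.segment_sum(f, graph_ids, len(graphs))  # sum pooling, [B, d]
    hidden = ad.relu(h @ params["mlp1_W"] + params["mlp1_b"])
    logits = (hidden @ params["mlp2_W"] + params["mlp2_b"]).reshape((-1,))
    return ad.sigmoid(logits), logits


def predict_scores(params: dict[str, np.ndarray], graphs, cfg: ModelConfig) -> np.ndarray:
    """Inference-mode scores in (0, 1) as a plain array."""
    scores, _ = forward(graphs, params, cfg, training=False)
    return scores.data.copy()


def bce_loss(y: float, y_star: int) -> float:
    """Binary cross-entropy ``-y* log y - (1 - y*) log(1 - y)`` for a score in (0, 1).

    Computed from the logit via softplus so scores arbitrarily close to 0 or
    1 stay finite.
    """
    if not (0.0 < y < 1.0):
        raise ValueError("score must lie strictly in (0, 1)")
    z = np.log(y) - np.log1p(-y)  # logit
    return float(np.logaddexp(0.0, z) - y_star * z)


def bce_loss_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE over a batch, stabilized on the pre-sigmoid values."""
    labels_t = Tensor(np.asarray(labels, dtype=float))
    per_sample = ad.softplus(logits) - labels_t * logits
    return per_sample.mean()


# -- checkpoints -----------------------------------------------------------------

def save_checkpoint(path, members: list[dict[str, np.ndarray]] | dict, cfg: ModelConfig) -> Path:
    """Save one model or an ensemble (list of parameter dicts) plus its config."""
    if isinstance(members, dict):
        members = [members]
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = {
        f"member{i}/{name}": arr
        for i, params in enumerate(members)
        for name, arr in params.items()
    }
    header = json.dumps(
        {
            "format_version": _CHECKPOINT_VERSION,
            "n_members": len(members),
            "config": cfg.to_dict(),
        }
    )
    arrays["__meta__"] = np.array(header)
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path) -> tuple[list[dict[str, np.ndarray]], ModelConfig]:
    """Load a checkpoint; returns ``(member parameter dicts, config)``."""
    data = np.load(Path(path))
    meta = json.loads(str(data["__meta__"]))
    cfg = ModelConfig.from_dict(meta["config"])
    members = []
    for i in range(meta["n_members"]):
        prefix = f"member{i}/"
        members.append(
            {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
        )
    return members, cfg
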