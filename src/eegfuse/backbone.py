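"""Per-band graph backbone: hierarchical temporal CNN, self-adaptive
multi-graph adjacency, and spectral graph convolution over the channel graph.

Each frequency band gets an independent backbone instance. The temporal
stack applies three blocks of 1x5 convolution (filters 64 -> 128 -> 256) and
width-2 max pooling *along time only* — the kernel never mixes channels, so
channel permutations permute the output rows identically. Node embeddings
feed a modified Transformer-encoder attention whose head-averaged
pre-softmax score matrix A, combined with the self-correlation matrix S of
the embeddings, yields the learned adjacency

    E = softmax(A + S)   (row-wise),

sparsified by keeping the top-k entries per row (renormalized). Spectral
graph convolution with self-loops then mixes information across channels:

    H' = LeakyReLU(D_hat^{-1/2} E_hat D_hat^{-1/2} X Theta),  E_hat = E + I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1d, Linear, Module, Parameter, Tensor, maxpool1d

__all__ = [
    "BackboneConfig", "AdjacencyMatrix", "ConvStack", "SelfAdaptiveGraph",
    "BandBackbone", "top_k_sparsify", "self_adaptive_graph",
    "graph_convolution", "normalized_adjacency",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture knobs; defaults follow the reference configuration."""

    n_nodes: int = 62
    kernel_width: int = 5
    filter_sizes: tuple[int, ...] = (64, 128, 256)
    pool_width: int = 2
    graph_heads: int = 4
    top_k: int = 10
    leaky_slope: float = 0.01
    graph_dim: int = 32          # output width of the spectral graph convolution

    def __post_init__(self) -> None:
        if len(self.filter_sizes) != 3:
            raise ValueError("the temporal stack uses exactly 3 conv blocks")
        if list(self.filter_sizes) != sorted(set(self.filter_sizes)):
            raise ValueError("filter sizes must be strictly increasing")
        if not (1 <= self.top_k <= self.n_nodes):
            raise ValueError(f"top_k must lie in [1, {self.n_nodes}]")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")

    @property
    def min_frames(self) -> int:
        return self.pool_width ** len(self.filter_sizes)


@dataclass
class AdjacencyMatrix:
    """Learned channel adjacency after softmax and top-k sparsification.

    ``E`` rows are non-negative and sum to 1 (renormalized after masking);
    ``E_hat = E + I`` adds self-loops; ``D_hat`` is its degree vector.
    """

    E: np.ndarray
    E_hat: np.ndarray
    D_hat: np.ndarray


def top_k_sparsify(e: Tensor | np.ndarray, k: int) -> Tensor:
    """Keep the k largest entries of each row, renormalize rows to sum 1.

    Ties are broken stably by column index (equal scores keep the lowest
    indices). The mask is computed from values only; gradients flow through
    the kept entries and the renormalization.
    """
    t = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=float))
    n = t.shape[-1]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    if k == n:
        return t
    vals = t.data
    # stable tie-break: sort by (-value, column index)
    order = np.lexsort(
        (np.broadcast_to(np.arange(n), vals.shape), -vals), axis=-1
    )
    keep_idx = order[..., :k]
    mask = np.zeros_like(vals)
    np.put_along_axis(mask, keep_idx, 1.0, axis=-1)
    masked = t * Tensor(mask)
    row_sum = masked.sum(axis=-1, keepdims=True)
    return masked / (row_sum + 1e-12)


def normalized_adjacency(e: Tensor | np.ndarray) -> Tensor:
    """Symmetric degree normalization with self-loops: D^{-1/2}(E+I)D^{-1/2}."""
    t = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=float))
    n = t.shape[-1]
    e_hat = t + Tensor(np.eye(n, dtype=t.data.dtype))
    deg = e_hat.sum(axis=-1)
    inv_sqrt = deg ** -0.5
    left = inv_sqrt.reshape(*inv_sqrt.shape, 1)
    right = inv_sqrt.reshape(*inv_sqrt.shape[:-1], 1, inv_sqrt.shape[-1])
    return e_hat * left * right


def graph_convolution(x: Tensor | np.ndarray, adj: AdjacencyMatrix | Tensor | np.ndarray,
                      theta: Tensor | np.ndarray, slope: float = 0.01) -> Tensor:
    """Spectral graph convolution H' = LeakyReLU(D^{-1/2} E_hat D^{-1/2} X Theta).

    ``adj`` may be an :class:`AdjacencyMatrix` or the raw E matrix (self-loops
    are added here). Zero-degree nodes are impossible: the self-loop
    guarantees degree >= 1.
    """
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    th = theta if isinstance(theta, Tensor) else Tensor(np.asarray(theta, dtype=float))
    e = adj.E if isinstance(adj, AdjacencyMatrix) else adj
    norm = normalized_adjacency(e)
    return (norm @ xt @ th).leaky_relu(slope)


class ConvStack(Module):
    """Three-stage 1x5 conv + max-pool pyramid acting along time only.

    Input (B, nodes, T) with T >= pool_width^3; output (B, nodes, filters[-1])
    after global average pooling over the remaining frames.
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        sizes = (1,) + tuple(config.filter_sizes)
        self.convs = [
            Conv1d(sizes[i], sizes[i + 1], config.kernel_width, rng)
            for i in range(3)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        b, nodes, t = x.shape
        if t < cfg.min_frames:
            raise ValueError(
                f"need at least {cfg.min_frames} time frames for "
                f"{len(cfg.filter_sizes)} pooling stages, got {t}"
            )
        h = x.reshape(b * nodes, 1, t)
        for conv in self.convs:
            h = maxpool1d(conv(h).leaky_relu(cfg.leaky_slope), cfg.pool_width)
        h = h.mean(axis=-1)  # (B*nodes, filters[-1])
        return h.reshape(b, nodes, cfg.filter_sizes[-1])


class SelfAdaptiveGraph(Module):
    """Learned adjacency from encoder attention plus embedding self-correlation."""

    def __init__(self, embed_dim: int, config: BackboneConfig,
                 rng: np.random.Generator):
        if embed_dim % config.graph_heads != 0:
            raise ValueError("embed_dim must be divisible by graph_heads")
        self.config = config
        self.w_q = Linear(embed_dim, embed_dim, rng, bias=False)
        self.w_k = Linear(embed_dim, embed_dim, rng, bias=False)
        self.embed_dim = embed_dim

    def attention_scores(self, x: Tensor) -> Tensor:
        """Head-averaged pre-softmax score matrix A, shape (..., nodes, nodes)."""
        h = self.config.graph_heads
        d_head = self.embed_dim // h
        q, k = self.w_q(x), self.w_k(x)
        lead = x.shape[:-2]
        n = x.shape[-2]
        qh = q.reshape(*lead, n, h, d_head).swapaxes(-3, -2)  # (..., h, n, d)
        kh = k.reshape(*lead, n, h, d_head).swapaxes(-3, -2)
        scores = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_head))
        return scores.mean(axis=-3)

    @staticmethod
    def self_correlation(x: Tensor) -> Tensor:
        """Row-softmaxed cosine-similarity Gram matrix of the embeddings."""
        norm = (x * x).sum(axis=-1, keepdims=True) ** 0.5
        xn = x / (norm + 1e-12)
        return (xn @ xn.swapaxes(-1, -2)).softmax(axis=-1)

    def adjacency(self, embeddings: Tensor) -> Tensor:
        """Dense E = softmax(A + S) followed by top-k sparsification."""
        a = self.attention_scores(embeddings)
        s = self.self_correlation(embeddings)
        e = (a + s).softmax(axis=-1)
        return top_k_sparsify(e, self.config.top_k)


def self_adaptive_graph(embeddings: np.ndarray,
                        config: BackboneConfig | None = None,
                        module: SelfAdaptiveGraph | None = None,
                        seed: int = 0) -> AdjacencyMatrix:
    """Array-level adjacency construction for a (nodes, d) embedding matrix.

    Uses the supplied encoder module or a freshly seeded one, and returns the
    numpy :class:`AdjacencyMatrix` (E after top-k, E_hat = E + I, degrees).
    """
    x = np.asarray(embeddings, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("embeddings contain non-finite values")
    cfg = config or BackboneConfig(n_nodes=x.shape[0],
                                   top_k=min(10, x.shape[0]))
    mod = module or SelfAdaptiveGraph(x.shape[1], cfg, np.random.default_rng(seed))
    e = mod.adjacency(Tensor(x)).data
    e_hat = e + np.eye(e.shape[-1])
    return AdjacencyMatrix(E=e, E_hat=e_hat, D_hat=e_hat.sum(axis=-1))


class BandBackbone(Module):
    """One band's full path: conv stack -> learned graph -> graph conv -> 62-vector.

    The graph convolution output (nodes x graph_dim) is reduced to one scalar
    per node by a linear readout, producing the D = n_nodes band feature
    vector consumed by the band-attention fusion head.
    """

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        self.config = config
        self.conv_stack = ConvStack(config, rng)
        embed = config.filter_sizes[-1]
        self.graph = SelfAdaptiveGraph(embed, config, rng)
        self.theta = Parameter(
            (rng.standard_normal((embed, config.graph_dim))
             * np.sqrt(2.0 / embed)).astype(np.float32)
        )
        self.readout = Linear(config.graph_dim, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(B, nodes, T) band signal -> (B, nodes) band feature vector."""
        emb = self.conv_stack(x)                 # (B, nodes, embed)
        e = self.graph.adjacency(emb)            # (B, nodes, nodes)
        h = graph_convolution(emb, e, self.theta, self.config.leaky_slope)
        out = self.readout(h)                    # (B, nodes, 1)
        return out.reshape(x.shape[0], self.config.n_nodes)

    def export_adjacency(self, x: Tensor) -> np.ndarray:
        """Adjacency E realized on a batch (averaged over the batch)."""
        emb = self.conv_stack(x)
        return self.graph.adjacency(emb).data.mean(axis=0)
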