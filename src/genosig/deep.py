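"""Deep clustering of k-mer signatures with an information-theoretic objective.

A small multilayer perceptron maps each (standardized) k-mer frequency
vector to a hidden embedding, from which two heads branch off: a softmax
cluster head producing a posterior over ``n_clusters`` clusters, and a
linear projection head whose L2-normalized output feeds a contrastive loss.

Training sees (original, mimic) pairs.  The clustering objective is the
negative mutual information of the symmetrized joint distribution of the
two cluster assignments

    J = (1/n) sum_i p_orig[i] (x) p_mimic[i],     J <- (J + J^T)/2
    L_MI = -I(J) = -sum_ab J_ab (log J_ab - log J_a. - log J_.b)

which is minimized (at ``-log k``) when assignments are consistent across
the pair and clusters are balanced.  The contrastive term is the
normalized-temperature cross entropy (NT-Xent) over the 2n projections: for
each anchor its mimic partner is the positive and the other 2n-2 vectors
are negatives, with cosine similarity scaled by ``1/temperature``.

The implementation is plain NumPy with hand-written gradients and an Adam
optimizer; at the problem sizes this package targets (thousands of
sequences, a few thousand features) a BLAS-backed MLP trains in seconds to
minutes on one CPU core, and every run is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mimics import MimicPairs

__all__ = [
    "ModelConfig",
    "TrainParams",
    "ClusterAssignment",
    "LossTerms",
    "mi_clustering_loss",
    "contrastive_consistency_loss",
    "standardize_rows",
    "train_model",
    "write_loss_trace",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one ensemble member.

    ``input_dim`` is 4^k for k-mer features.  ``hidden_dims`` are the ReLU
    layer widths of the encoder; the embedding layer itself is linear.
    """

    input_dim: int
    n_clusters: int
    hidden_dims: tuple[int, ...] = (128,)
    embed_dim: int = 32
    proj_dim: int = 32
    n_heads: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError(f"n_clusters must be >= 2, got {self.n_clusters}")
        if self.embed_dim < 2:
            raise ValueError(f"embed_dim must be >= 2, got {self.embed_dim}")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")


@dataclass(frozen=True)
class TrainParams:
    """Optimization hyper-parameters (all exposed on the command line)."""

    epochs: int = 40
    batch_size: int = 512
    learning_rate: float = 1e-3
    lam: float = 1.0
    temperature: float = 0.5
    standardize: bool = True
    warmup_frac: float = 0.4
    kmeans_head_init: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not (0.0 <= self.warmup_frac <= 1.0):
            raise ValueError("warmup_frac must be in [0, 1]")


@dataclass(frozen=True)
class LossTerms:
    mi_loss: float
    contrastive_loss: float
    lam: float

    @property
    def total(self) -> float:
        return self.mi_loss + self.lam * self.contrastive_loss


@dataclass
class ClusterAssignment:
    """Output of one trained model: soft posteriors plus hidden embedding."""

    posterior: np.ndarray  # n x k, rows sum to 1
    embedding: np.ndarray  # n x embed_dim

    @property
    def hard_labels(self) -> np.ndarray:
        # argmax returns the first maximum, i.e. ties break to the lowest index
        return np.argmax(self.posterior, axis=1)

    @property
    def n_clusters(self) -> int:
        return self.posterior.shape[1]


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling of each row across features.

    Raw k-mer frequencies at k=6 are O(1e-3); per-vector standardization puts
    them on a scale the encoder can use without tiny gradients.  Constant
    rows map to zero vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd <= 0, 1.0, sd)
    return (x - mu) / sd


def _check_posteriors(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {p.shape}")
    if np.any(p < -1e-12):
        raise ValueError(f"{name} has negative entries")
    rowsum = p.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-6):
        worst = float(np.max(np.abs(rowsum - 1.0)))
        raise ValueError(f"{name} rows must sum to 1 (max deviation {worst:.2e})")
    return p


def _joint(p_orig: np.ndarray, p_mimic: np.ndarray) -> np.ndarray:
    n = p_orig.shape[0]
    j = p_orig.T @ p_mimic / n
    return (j + j.T) / 2.0


def mi_clustering_loss(p_orig: np.ndarray, p_mimic: np.ndarray) -> float:
    """Negative mutual information of the symmetrized assignment joint.

    Bounded below by ``-log k`` (diagonal balanced joint) and above by 0
    (independent assignments).  Symmetric in its arguments.
    """
    p_orig = _check_posteriors(p_orig, "p_orig")
    p_mimic = _check_posteriors(p_mimic, "p_mimic")
    if p_orig.shape != p_mimic.shape:
        raise ValueError(
            f"shape mismatch: {p_orig.shape} vs {p_mimic.shape}"
        )
    j = _joint(p_orig, p_mimic)
    a = j.sum(axis=1, keepdims=True)
    b = j.sum(axis=0, keepdims=True)
    # 0 log 0 = 0: only cells with mass contribute
    nz = j > 0
    logj = np.where(nz, np.log(np.where(nz, j, 1.0)), 0.0)
    with np.errstate(divide="ignore"):
        la = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), 0.0)
        lb = np.where(b > 0, np.log(np.where(b > 0, b, 1.0)), 0.0)
    return float(-np.sum(np.where(nz, j * (logj - la - lb), 0.0)))


def _mi_loss_and_posterior_grad(
    p_orig: np.ndarray, p_mimic: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus dL/dp_orig and dL/dp_mimic (no validation; training path)."""
    n = p_orig.shape[0]
    j = np.clip(_joint(p_orig, p_mimic), _EPS, None)
    log_j = np.log(j)
    log_a = np.log(j.sum(axis=1, keepdims=True))
    log_b = np.log(j.sum(axis=0, keepdims=True))
    loss = float(-np.sum(j * (log_j - log_a - log_b)))
    g = -log_j + log_a + log_b + 1.0  # symmetric because j is
    d_orig = p_mimic @ g / n
    d_mimic = p_orig @ g / n
    return loss, d_orig, d_mimic


def _normalize_rows(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm = np.where(norm <= 0, 1.0, norm)
    return v / norm, norm


def contrastive_consistency_loss(
    z_orig: np.ndarray, z_mimic: np.ndarray, temperature: float = 0.5
) -> float:
    """NT-Xent loss over paired embeddings (mean over the 2n anchors)."""
    loss, _ = _ntxent_loss_and_grad(
        np.asarray(z_orig, dtype=np.float64),
        np.asarray(z_mimic, dtype=np.float64),
        temperature,
    )
    return loss


def _ntxent_loss_and_grad(
    z_orig: np.ndarray, z_mimic: np.ndarray, temperature: float
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the *unnormalized* stacked embeddings.

    Returns (loss, d_stacked) with d_stacked of shape (2n, d); the first n
    rows correspond to originals.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if z_orig.shape != z_mimic.shape:
        raise ValueError(f"shape mismatch: {z_orig.shape} vs {z_mimic.shape}")
    n = z_orig.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 pairs (no negatives otherwise)")
    v = np.vstack([z_orig, z_mimic])
    u, norm = _normalize_rows(v)
    m = 2 * n
    s = (u @ u.T) / temperature
    np.fill_diagonal(s, -np.inf)
    smax = s.max(axis=1, keepdims=True)
    exp_s = np.exp(s - smax)
    denom = exp_s.sum(axis=1, keepdims=True)
    logp = s - smax - np.log(denom)
    pos = np.concatenate([np.arange(n, m), np.arange(0, n)])
    loss = float(-logp[np.arange(m), pos].mean())

    soft = exp_s / denom
    y = np.zeros_like(soft)
    y[np.arange(m), pos] = 1.0
    d_s = (soft - y) / m
    d_u = ((d_s + d_s.T) @ u) / temperature
    # back through row normalization u = v / ||v||
    d_v = (d_u - u * np.sum(u * d_u, axis=1, keepdims=True)) / norm
    return loss, d_v


# ---------------------------------------------------------------------------
# MLP parameters and training


class _MLP:
    """Encoder + cluster heads + projection head with explicit backprop.

    Several softmax cluster heads share the encoder; all are trained on the
    averaged clustering loss and the best one (lowest full-data MI loss) is
    kept at the end.  Extra heads cost almost nothing and give the optimizer
    independent chances to escape merged-cluster local optima.
    """

    def __init__(self, config: ModelConfig):
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_dims, config.embed_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))
        head_scale = np.sqrt(1.0 / config.embed_dim)
        self.n_heads = config.n_heads
        self.w_clusters = [
            (rng.standard_normal((config.embed_dim, config.n_clusters)) * head_scale).astype(
                np.float32
            )
            for _ in range(config.n_heads)
        ]
        self.b_clusters = [
            np.zeros(config.n_clusters, dtype=np.float32) for _ in range(config.n_heads)
        ]
        self.w_proj = (
            rng.standard_normal((config.embed_dim, config.proj_dim)) * head_scale
        ).astype(np.float32)
        self.b_proj = np.zeros(config.proj_dim, dtype=np.float32)

    def parameters(self) -> list[np.ndarray]:
        return [
            *self.weights,
            *self.biases,
            *self.w_clusters,
            *self.b_clusters,
            self.w_proj,
            self.b_proj,
        ]

    def forward(self, x: np.ndarray):
        """Returns (activations, embedding, per-head posteriors, projection)."""
        acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        z = acts[-1]
        posteriors = [
            _softmax(z @ w + b) for w, b in zip(self.w_clusters, self.b_clusters)
        ]
        proj = z @ self.w_proj + self.b_proj
        return acts, z, posteriors, proj

    def backward(
        self,
        acts: Sequence[np.ndarray],
        d_logits: Sequence[np.ndarray],
        d_proj: np.ndarray,
    ) -> list[np.ndarray]:
        """Gradients in the order of :meth:`parameters`."""
        z = acts[-1]
        d_proj = d_proj.astype(np.float32)
        g_wc: list[np.ndarray] = []
        g_bc: list[np.ndarray] = []
        d_h = d_proj @ self.w_proj.T
        for head, dl in enumerate(d_logits):
            dl = dl.astype(np.float32)
            g_wc.append(z.T @ dl)
            g_bc.append(dl.sum(axis=0))
            d_h = d_h + dl @ self.w_clusters[head].T
        g_w_proj = z.T @ d_proj
        g_b_proj = d_proj.sum(axis=0)
        g_weights: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        g_biases: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        for i in range(len(self.weights) - 1, -1, -1):
            a_in = acts[i]
            g_weights[i] = a_in.T @ d_h
            g_biases[i] = d_h.sum(axis=0)
            if i > 0:
                d_h = (d_h @ self.weights[i].T) * (acts[i] > 0)
        return [*g_weights, *g_biases, *g_wc, *g_bc, g_w_proj, g_b_proj]


def _softmax(logits: np.ndarray) -> np.ndarray:
    logits64 = logits.astype(np.float64)
    logits64 -= logits64.max(axis=1, keepdims=True)
    e = np.exp(logits64)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _init_heads_from_kmeans(model: _MLP, x_std: np.ndarray, config: ModelConfig) -> None:
    """Re-initialize every cluster head from a k-means run on the embedding.

    With centroids mu_c, setting W[:, c] = 2 s mu_c and b[c] = -s ||mu_c||^2
    makes the logits equal -s ||z - mu_c||^2 up to a per-row constant that
    softmax ignores.  The scale s is chosen so the typical distance gap maps
    to O(1) logit differences; each head uses a differently seeded k-means,
    which keeps the heads diverse.
    """
    from sklearn.cluster import KMeans

    _, z, _, _ = model.forward(x_std)
    z64 = z.astype(np.float64)
    for h in range(model.n_heads):
        km = KMeans(
            n_clusters=config.n_clusters,
            n_init=1,
            random_state=(config.seed + 7919 * h) % (2**31),
        ).fit(z64)
        mu = km.cluster_centers_
        mean_sq = km.inertia_ / max(z64.shape[0], 1)
        s = 1.0 / (mean_sq + 1e-12)
        model.w_clusters[h] = (2.0 * s * mu.T).astype(np.float32)
        model.b_clusters[h] = (-s * np.sum(mu * mu, axis=1)).astype(np.float32)


def _softmax_backward(p: np.ndarray, d_p: np.ndarray) -> np.ndarray:
    inner = np.sum(p * d_p, axis=1, keepdims=True)
    return p * (d_p - inner)


def train_model(
    features: np.ndarray,
    pairs: MimicPairs,
    config: ModelConfig,
    params: TrainParams = TrainParams(),
) -> tuple[ClusterAssignment, list[LossTerms]]:
    """Train one model and return its assignment plus the per-epoch loss trace.

    Each epoch shuffles the data, picks one mimic per original at random,
    and minimizes ``mi_loss + lambda * contrastive_loss`` per minibatch with
    Adam.  Fully reproducible from ``config.seed``.  With ``epochs=0`` the
    posterior of the freshly initialized network is returned.
    """
    x = np.asarray(features, dtype=np.float64)
    n = x.shape[0]
    if x.ndim != 2 or x.shape[1] != config.input_dim:
        raise ValueError(
            f"features shape {x.shape} does not match input_dim {config.input_dim}"
        )
    if config.n_clusters > n:
        raise ValueError(f"n_clusters={config.n_clusters} exceeds n={n} sequences")
    if pairs.profiles.shape[1] != config.input_dim:
        raise ValueError("mimic profile width does not match input_dim")
    if pairs.orig_index.min() < 0 or pairs.orig_index.max() >= n:
        raise ValueError("mimic pair indices out of range")

    if params.standardize:
        x_std = standardize_rows(x).astype(np.float32)
        m_std = standardize_rows(pairs.profiles).astype(np.float32)
    else:
        x_std = x.astype(np.float32)
        m_std = pairs.profiles.astype(np.float32)

    model = _MLP(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    opt = _Adam(model.parameters(), params.learning_rate)
    trace: list[LossTerms] = []
    n_mimics = pairs.n_mimics

    # Two-phase schedule: a contrastive-only warm-up shapes the embedding
    # before the cluster heads receive gradients; the heads are then
    # initialized from k-means centroids in embedding space (a softmax over
    # negative squared centroid distances is a linear head) and the joint
    # objective refines everything.  Starting the heads inside the data
    # geometry avoids the merged/arbitrary-partition local optima that
    # plague mutual-information objectives started from random partitions.
    warmup_epochs = int(round(params.warmup_frac * params.epochs))

    for epoch in range(params.epochs):
        if epoch == warmup_epochs and params.kmeans_head_init:
            _init_heads_from_kmeans(model, x_std, config)
            opt = _Adam(model.parameters(), params.learning_rate)
        train_heads = epoch >= warmup_epochs or not params.kmeans_head_init
        order = rng.permutation(n)
        pick = rng.integers(0, n_mimics, size=n)
        mi_sum = 0.0
        ctr_sum = 0.0
        n_batches = 0
        for start in range(0, n, params.batch_size):
            idx = order[start : start + params.batch_size]
            if idx.size < 2:
                continue  # contrastive term needs negatives
            xb = x_std[idx]
            mb = m_std[idx * n_mimics + pick[idx]]
            both = np.vstack([xb, mb])
            acts, z, posteriors, proj = model.forward(both)
            b = idx.size
            mi = 0.0
            d_logits = []
            for posterior in posteriors:
                p_o, p_m = posterior[:b], posterior[b:]
                mi_h, d_po, d_pm = _mi_loss_and_posterior_grad(p_o, p_m)
                mi += mi_h / len(posteriors)
                if train_heads:
                    d_logits.append(
                        _softmax_backward(posterior, np.vstack([d_po, d_pm]))
                        / len(posteriors)
                    )
                else:
                    d_logits.append(np.zeros_like(posterior))
            ctr, d_proj = _ntxent_loss_and_grad(
                proj[:b].astype(np.float64),
                proj[b:].astype(np.float64),
                params.temperature,
            )
            if not (np.isfinite(mi) and np.isfinite(ctr)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: mi={mi}, contrastive={ctr}"
                )
            grads = model.backward(acts, d_logits, params.lam * d_proj)
            opt.step(model.parameters(), grads)
            mi_sum += mi
            ctr_sum += ctr
            n_batches += 1
        if n_batches == 0:
            raise RuntimeError("no usable minibatch (need batches of size >= 2)")
        trace.append(
            LossTerms(mi_sum / n_batches, ctr_sum / n_batches, params.lam)
        )

    # final inference pass; keep the head with the lowest full-data MI loss
    _, z, posteriors, _ = model.forward(x_std)
    best_head = 0
    if len(posteriors) > 1:
        _, _, mimic_posteriors, _ = model.forward(m_std)
        head_losses = []
        for h, posterior in enumerate(posteriors):
            p_o = posterior[pairs.orig_index]
            mi_h, _, _ = _mi_loss_and_posterior_grad(p_o, mimic_posteriors[h])
            head_losses.append(mi_h)
        best_head = int(np.argmin(head_losses))
    return (
        ClusterAssignment(
            posterior=posteriors[best_head].astype(np.float64),
            embedding=z.astype(np.float64),
        ),
        trace,
    )


def write_loss_trace(
    traces: Sequence[Sequence[LossTerms]], path: str | Path
) -> None:
    """CSV export of per-member, per-epoch loss terms."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("member,epoch,mi_loss,contrastive_loss,total\n")
        for member, trace in enumerate(traces):
            for epoch, terms in enumerate(trace):
                fh.write(
                    f"{member},{epoch},{terms.mi_loss!r},"
                    f"{terms.contrastive_loss!r},{terms.total!r}\n"
                )
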