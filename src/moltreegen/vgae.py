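"""Variational graph auto-encoder over fixed-size molecular feature maps.

The encoder is a stack of edge-conditioned graph-convolution layers (one
weight matrix per bond type plus a self-loop term), mean-pooled to a
graph-level embedding that parameterizes a diagonal-Gaussian posterior
``N(mu, diag(exp(logvar)))`` in a 64-dimensional latent space. The decoder
maps a latent vector through a two-layer perceptron to

* a node feature map (``max_atoms x D_node`` scores, softmax over the
  element block gives per-slot atom-type probabilities), and
* a symmetric ``max_atoms x max_atoms`` edge-existence probability map
  (logits symmetrized as ``(L + L^T)/2``, squashed through a logistic,
  zero diagonal).

Training maximizes the evidence lower bound: elementwise binary
cross-entropy on the edge map plus categorical cross-entropy on the element
one-hots (padding slots masked), regularized by the closed-form KL
divergence between the posterior and the standard-normal prior. Defaults
follow the reference protocol: latent dimension 64, learning rate 0.001,
batch size 64, adaptive-moment gradient descent.

The fitted model is a scikit-learn style estimator (:class:`GraphVAE`);
:func:`train` and the other module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, Tensor, parameter
from .chem_graph import ConfigurationError, FeatureConfig, MolecularGraph, smiles_to_graph

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z|G) = N(mu, diag(exp(logvar)))."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.logvar = np.asarray(self.logvar, dtype=float)
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("posterior parameters must be finite")


@dataclass
class DecodedFeatureMap:
    """Decoder output: symmetric edge-existence probabilities + node scores."""

    edge_prob: np.ndarray   # (max_atoms, max_atoms), in [0,1], zero diagonal
    node_map: np.ndarray    # (max_atoms, D_node) raw scores

    def validate(self) -> None:
        p = self.edge_prob
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("edge_prob must be square")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("edge probabilities must lie in [0,1]")
        if not np.allclose(p, p.T):
            raise ValueError("edge_prob must be symmetric")
        if np.diag(p).any():
            raise ValueError("edge_prob diagonal must be zero")


def _glorot(rng, fan_in, fan_out):
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class GraphVAE(BaseEstimator):
    """Variational graph auto-encoder with a scikit-learn estimator interface.

    Parameters
    ----------
    latent_dim : int, default 64
        Dimension of the latent space.
    hidden_dim : int, default 128
        Width of graph-convolution and decoder hidden layers.
    n_conv_layers : int, default 3
        Number of edge-conditioned graph-convolution layers in the encoder.
    learning_rate : float, default 0.001
    batch_size : int, default 64
    epochs : int, default 50
    validation_fraction : float, default 0.1
        Fraction of the training set held out for per-epoch validation loss.
    feature_config : FeatureConfig or None
        Featurization vocabulary; the package default when None.
    seed : int, default 0
        Seed for weight initialization, shuffling, and the reparameterization
        noise. Two fits with equal seeds produce identical loss histories.

    Attributes
    ----------
    params_ : dict of str -> Tensor
        Trained weights.
    loss_history_ : list of dict
        Per-epoch ``{"epoch", "train_recon", "train_kl", "train_total",
        "val_total"}`` records.
    feature_config_ : FeatureConfig
    """

    def __init__(self, latent_dim=64, hidden_dim=128, n_conv_layers=3,
                 learning_rate=0.001, batch_size=64, epochs=50,
                 validation_fraction=0.1, feature_config=None, seed=0):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.n_conv_layers = n_conv_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.feature_config = feature_config
        self.seed = seed

    # ------------------------------------------------------------------
    def _init_params(self, config: FeatureConfig, rng) -> dict:
        dn = config.n_node_features
        k = config.n_edge_features
        h, z, m = self.hidden_dim, self.latent_dim, config.max_atoms
        p = {}
        d_in = dn
        for layer in range(self.n_conv_layers):
            p[f"enc{layer}.self"] = parameter(_glorot(rng, d_in, h))
            for b in range(k):
                p[f"enc{layer}.bond{b}"] = parameter(_glorot(rng, d_in, h))
            p[f"enc{layer}.bias"] = parameter(np.zeros(h))
            d_in = h
        for head in ("mu", "logvar"):
            p[f"{head}.W"] = parameter(_glorot(rng, h, z))
            p[f"{head}.b"] = parameter(np.zeros(z))
        p["dec1.W"] = parameter(_glorot(rng, z, h))
        p["dec1.b"] = parameter(np.zeros(h))
        p["dec_node.W"] = parameter(_glorot(rng, h, m * dn))
        p["dec_node.b"] = parameter(np.zeros(m * dn))
        p["dec_edge.W"] = parameter(_glorot(rng, h, m * m))
        p["dec_edge.b"] = parameter(np.zeros(m * m))
        return p

    # ---- differentiable forward pieces --------------------------------
    def _encode_t(self, graph: MolecularGraph, params) -> tuple:
        cfg = self.feature_config_
        n = graph.n_atoms
        h = Tensor(graph.node_features[:n])
        # row-normalized per-bond-type adjacency (constant w.r.t. parameters)
        adjs = []
        for b in range(cfg.n_edge_features):
            a = graph.edge_features[:n, :n, b]
            deg = np.maximum(a.sum(axis=1, keepdims=True), 1.0)
            adjs.append(Tensor(a / deg))
        for layer in range(self.n_conv_layers):
            out = h @ params[f"enc{layer}.self"]
            for b, a in enumerate(adjs):
                out = out + (a @ h) @ params[f"enc{layer}.bond{b}"]
            h = (out + params[f"enc{layer}.bias"]).relu()
        g = h.mean(axis=0)
        mu = g @ params["mu.W"] + params["mu.b"]
        logvar = g @ params["logvar.W"] + params["logvar.b"]
        return mu, logvar

    def _decode_t(self, z: Tensor, params) -> tuple:
        cfg = self.feature_config_
        m, dn = cfg.max_atoms, cfg.n_node_features
        h = (z @ params["dec1.W"] + params["dec1.b"]).relu()
        node = (h @ params["dec_node.W"] + params["dec_node.b"]).reshape(m, dn)
        edge = (h @ params["dec_edge.W"] + params["dec_edge.b"]).reshape(m, m)
        edge_sym = (edge + edge.transpose2d()) * 0.5
        return node, edge_sym  # edge as symmetric logits

    def _loss_t(self, graph: MolecularGraph, params, eps: np.ndarray):
        cfg = self.feature_config_
        m = cfg.max_atoms
        mu, logvar = self._encode_t(graph, params)
        z = mu + (logvar * 0.5).exp() * eps
        node_logits, edge_logits = self._decode_t(z, params)

        edge_target = graph.adjacency
        offdiag = 1.0 - np.eye(m)
        recon_edge = edge_logits.bce_with_logits(edge_target, weight=offdiag)

        n_el = len(cfg.allowed_elements)
        elem_target = graph.node_features[:, :n_el]
        row_mask = np.zeros(m)
        row_mask[:graph.n_atoms] = 1.0
        elem_logits = _slice_cols(node_logits, n_el)
        recon_node = elem_logits.softmax_cross_entropy(elem_target, row_mask=row_mask)

        kl = ((logvar.exp() + mu * mu - 1.0 - logvar) * 0.5).sum()
        recon = recon_edge + recon_node
        return recon, kl

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit on a list of SMILES strings or :class:`MolecularGraph` objects."""
        cfg = self.feature_config or FeatureConfig()
        self.feature_config_ = cfg
        graphs = [g if isinstance(g, MolecularGraph) else smiles_to_graph(g, cfg)
                  for g in X]
        if not graphs:
            raise ConfigurationError("training set is empty")
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(cfg, rng)
        opt = Adam(self.params_, lr=self.learning_rate)

        n_val = int(round(self.validation_fraction * len(graphs)))
        order = rng.permutation(len(graphs))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order, order[:0]
        train_graphs = [graphs[i] for i in train_idx]
        val_graphs = [graphs[i] for i in val_idx]

        self.loss_history_ = []
        for epoch in range(self.epochs):
            perm = rng.permutation(len(train_graphs))
            ep_recon = ep_kl = 0.0
            for start in range(0, len(perm), self.batch_size):
                batch = [train_graphs[i] for i in perm[start:start + self.batch_size]]
                opt.zero_grad()
                total = None
                for g in batch:
                    eps = rng.standard_normal(self.latent_dim)
                    recon, kl = self._loss_t(g, self.params_, eps)
                    loss = recon + kl
                    ep_recon += float(recon.data)
                    ep_kl += float(kl.data)
                    total = loss if total is None else total + loss
                (total * (1.0 / len(batch))).backward()
                opt.step()
            rec = {
                "epoch": epoch,
                "train_recon": ep_recon / max(len(train_graphs), 1),
                "train_kl": ep_kl / max(len(train_graphs), 1),
            }
            rec["train_total"] = rec["train_recon"] + rec["train_kl"]
            rec["val_total"] = (self._mean_loss(val_graphs)
                                if val_graphs else float("nan"))
            self.loss_history_.append(rec)
        return self

    def _mean_loss(self, graphs) -> float:
        """Mean total loss at the posterior mean (no reparameterization noise)."""
        zero = np.zeros(self.latent_dim)
        totals = [float((r + k).data) for r, k in
                  (self._loss_t(g, self.params_, zero) for g in graphs)]
        return float(np.mean(totals))

    # ---- inference ----------------------------------------------------
    def encode(self, graph) -> LatentPosterior:
        """Posterior for one molecule (SMILES or MolecularGraph)."""
        check_is_fitted(self, "params_")
        if not isinstance(graph, MolecularGraph):
            graph = smiles_to_graph(graph, self.feature_config_)
        graph.validate(self.feature_config_)
        mu, logvar = self._encode_t(graph, self.params_)
        return LatentPosterior(mu.data.copy(), logvar.data.copy())

    def decode(self, z: np.ndarray) -> DecodedFeatureMap:
        """Decode a latent vector into node/edge feature maps."""
        check_is_fitted(self, "params_")
        z = np.asarray(z, dtype=float)
        if z.shape != (self.latent_dim,):
            raise ConfigurationError(
                f"latent vector must have shape ({self.latent_dim},)")
        node, edge = self._decode_t(Tensor(z), self.params_)
        m = self.feature_config_.max_atoms
        prob = 0.5 * (np.tanh(0.5 * edge.data) + 1.0)
        prob = prob * (1.0 - np.eye(m))
        fm = DecodedFeatureMap(edge_prob=prob, node_map=node.data.copy())
        fm.validate()
        return fm

    def transform(self, X) -> np.ndarray:
        """Posterior means, one row per molecule."""
        return np.stack([self.encode(x).mu for x in X])

    def sample_prior(self, seed=None, n=None) -> np.ndarray:
        """Standard-normal latent draw(s); the generative entry point."""
        rng = np.random.default_rng(seed)
        if n is None:
            return rng.standard_normal(self.latent_dim)
        return rng.standard_normal((n, self.latent_dim))

    # ---- persistence ---------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "params_")
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "feature_config": self.feature_config_.to_dict(),
            "hyper": {k: v for k, v in self.get_params().items()
                      if k != "feature_config"},
        }
        arrays = {k.replace(".", "__"): p.data for k, p in self.params_.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GraphVAE":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ConfigurationError(
                    f"unsupported checkpoint format {meta['format_version']}")
            cfg = FeatureConfig.from_dict(meta["feature_config"])
            model = cls(feature_config=cfg, **meta["hyper"])
            model.feature_config_ = cfg
            model.params_ = {k.replace("__", "."): parameter(archive[k].copy())
                             for k in archive.files if k != "__meta__"}
            model.loss_history_ = []
        # verify shape consistency against the embedded config
        expect = model._init_params(cfg, np.random.default_rng(0))
        for k, p in expect.items():
            if k not in model.params_ or model.params_[k].shape != p.shape:
                raise ConfigurationError(f"checkpoint incompatible at {k!r}")
        return model


def _slice_cols(t: Tensor, n_cols: int) -> Tensor:
    """First n_cols columns of a 2-D tensor, differentiable."""
    sel = np.zeros((t.shape[1], n_cols))
    sel[np.arange(n_cols), np.arange(n_cols)] = 1.0
    return t @ sel


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def encode(graph, model: GraphVAE) -> LatentPosterior:
    return model.encode(graph)


def decode(z, model: GraphVAE) -> DecodedFeatureMap:
    return model.decode(z)


def sample_posterior(post: LatentPosterior, seed=None) -> np.ndarray:
    """Reparameterized draw z = mu + exp(logvar/2) * eps, eps ~ N(0, I)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(post.mu.shape)
    return post.mu + np.exp(post.logvar / 2.0) * eps


def sample_prior(model: GraphVAE, seed=None) -> np.ndarray:
    return model.sample_prior(seed=seed)


def elbo_loss(graph: MolecularGraph, decoded: DecodedFeatureMap,
              post: LatentPosterior, config: FeatureConfig | None = None):
    """(reconstruction, kl, total) for a graph / decoded-map / posterior triple.

    The KL term is the closed form ``0.5 * sum(exp(logvar) + mu^2 - 1 - logvar)``
    and is non-negative for every input; reconstruction is edge-map binary
    cross-entropy (off-diagonal) plus element cross-entropy on occupied slots.
    """
    kl = 0.5 * float(np.sum(np.exp(post.logvar) + post.mu ** 2 - 1.0 - post.logvar))

    m = graph.node_features.shape[0]
    target = graph.adjacency
    p = np.clip(decoded.edge_prob, 1e-12, 1 - 1e-12)
    offdiag = 1.0 - np.eye(m)
    recon_edge = float(-np.sum(
        offdiag * (target * np.log(p) + (1 - target) * np.log(1 - p))))

    n_el = len((config or FeatureConfig()).allowed_elements)
    elem_logits = decoded.node_map[:, :n_el]
    elem_target = graph.node_features[:, :n_el]
    xs = elem_logits - elem_logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(xs).sum(axis=1))
    row_loss = lse - (xs * elem_target).sum(axis=1)
    recon_node = float(row_loss[:graph.n_atoms].sum())

    recon = recon_edge + recon_node
    return recon, kl, recon + kl


def train(dataset, hyper: dict | None = None, seed: int = 0):
    """Train a :class:`GraphVAE`; returns ``(model, loss_history)``."""
    model = GraphVAE(seed=seed, **(hyper or {}))
    model.fit(dataset)
    return model, model.loss_history_
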