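"""The full driver-gene classifier: stacked encoder layers, multi-layer
attention readout, masked binary cross-entropy training.

The model stacks ``n_layers`` fused encoder layers (all-pairs diffusion
attention + graph convolution + residual LayerNorm, see
:mod:`ecdcdgi.encoder`) on top of a ReLU feature projection, then reads
out a per-gene score as an attention-weighted sum over *all* layer
embeddings, ``M = sum_t alpha_t Z^t W_Z^t`` — layer 0 included, so the
readout can fall back on unpropagated features when propagation
over-smooths.  Scores are raw logits; their sigmoid is the driver
probability used in the loss.

Training is full-graph gradient descent (Adam) of the binary
cross-entropy averaged over the labeled genes selected by the training
mask; unlabeled genes receive predictions but never contribute to the
loss.

The public surface is the scikit-learn-style estimator
:class:`ECDCDGIClassifier` (``get_params``/``set_params``, ``fit``,
``decision_function``, ``predict_proba``); the task is transductive node
classification, so the graph adjacency is passed to ``fit`` alongside the
feature matrix, and ``y`` uses NaN (or -1) for unlabeled genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from . import encoder
from .autodiff import Tensor
from .encoder import EnergyDiagnosticConfig, LayerState
from .graph import GeneGraph

__all__ = [
    "ModelConfig",
    "ECDCDGIClassifier",
    "forward",
    "bce_loss",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_PROB_EPS = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults follow the reference setting: hidden dimension 100, four
    encoder layers, layer-readout weights initialized at 0.5, learning
    rate 0.001, 100 Adam epochs.  ``beta`` balances the fused branch
    output against the residual (previous-layer) embedding; the four
    ``use_*`` flags switch off individual architecture components for
    ablation studies without any code duplication.
    """

    hidden_dim: int = 100
    n_layers: int = 4
    beta: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 100
    use_ecd_attention: bool = True
    use_gcn: bool = True
    use_residual: bool = True
    use_multilayer_attention: bool = True
    softmax_layer_weights: bool = False
    gcn_input: str = "value"
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not (self.use_ecd_attention or self.use_gcn):
            raise ValueError("at least one of the two encoder branches must be enabled")
        if self.gcn_input not in ("value", "embedding"):
            raise ValueError("gcn_input must be 'value' or 'embedding'")


# ---------------------------------------------------------------------------
# weights


def init_weights(n_features: int, cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform initialization of all trainable arrays, seed-driven.

    Layer-readout weights alpha start at 0.5 for every layer; LayerNorm
    gains at 1 and shifts at 0; biases at 0.
    """
    d = cfg.hidden_dim

    def glorot(fan_in: int, fan_out: int, shape=None) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))

    two_branches = cfg.use_ecd_attention and cfg.use_gcn
    W: dict[str, np.ndarray] = {
        "W_I": glorot(n_features, d),
        "b_I": np.zeros(d),
    }
    for t in range(cfg.n_layers):
        W[f"W_K{t}"] = glorot(d, d)
        W[f"W_Q{t}"] = glorot(d, d)
        W[f"W_V{t}"] = glorot(d, d)
        width = 2 * d if two_branches else d
        W[f"W_d{t}"] = glorot(width, d)
        W[f"ln_gain{t}"] = np.ones(d)
        W[f"ln_shift{t}"] = np.zeros(d)
    for t in range(cfg.n_layers + 1):
        W[f"alpha{t}"] = np.asarray(0.5)
        # zero-initialized readout: the model starts at probability 0.5 for
        # every gene (loss ln 2), which keeps the first optimization steps
        # small and the early loss trajectory stable
        W[f"W_Z{t}"] = np.zeros((d, 1))
    return W


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


# ---------------------------------------------------------------------------
# forward pass


def _forward_core(
    X,
    Ahat,
    W: dict,
    cfg: ModelConfig,
    record_states: bool = False,
    record_energy: bool = False,
    energy_cfg: EnergyDiagnosticConfig | None = None,
):
    """Run the full architecture; polymorphic over ndarray / Tensor weights."""
    Z = encoder.project_features(X, W["W_I"], W["b_I"])
    layer_embeddings = [Z]
    states: list[LayerState] = []
    if record_states:
        states.append(LayerState(Z=_data(Z).copy()))
    for t in range(cfg.n_layers):
        K, Q, V = encoder.compute_qkv(
            Z, W[f"W_K{t}"], W[f"W_Q{t}"], W[f"W_V{t}"]
        )
        branches = []
        R = P = H = None
        if cfg.use_ecd_attention:
            R = encoder.pairwise_similarity(Q, K)
            P = encoder.attention_propagate(R, V)
            branches.append(P)
        if cfg.use_gcn:
            src = V if cfg.gcn_input == "value" else Z
            H = ad.const_matmul(Ahat, src)
            branches.append(H)
        stacked = ad.concat(branches, axis=1) if len(branches) == 2 else branches[0]
        fused = stacked @ W[f"W_d{t}"]
        b = cfg.beta if cfg.use_residual else 1.0
        mixed = fused if b == 1.0 else b * fused + (1.0 - b) * Z
        Z_next = ad.layer_norm(mixed, W[f"ln_gain{t}"], W[f"ln_shift{t}"])
        if not np.isfinite(_data(Z_next)).all():
            raise FloatingPointError(f"non-finite activations in encoder layer {t}")
        energy = None
        if record_energy:
            energy = encoder.diffusion_energy(_data(Z_next), _data(Z), energy_cfg)
        if record_states:
            states.append(
                LayerState(
                    Z=_data(Z_next).copy(),
                    K=_data(K).copy(), Q=_data(Q).copy(), V=_data(V).copy(),
                    R=None if R is None else _data(R).copy(),
                    P=None if P is None else _data(P).copy(),
                    H=None if H is None else _data(H).copy(),
                    energy=energy,
                )
            )
        elif record_energy:
            states.append(LayerState(Z=np.empty(0), energy=energy))
        Z = Z_next
        layer_embeddings.append(Z)

    T = cfg.n_layers
    if cfg.use_multilayer_attention:
        alphas = [W[f"alpha{t}"] for t in range(T + 1)]
        if cfg.softmax_layer_weights:
            exps = [ad.exp(a) for a in alphas]
            total = exps[0]
            for e in exps[1:]:
                total = total + e
            alphas = [ad.div(e, total) for e in exps]
        M = alphas[0] * (layer_embeddings[0] @ W["W_Z0"])
        for t in range(1, T + 1):
            M = M + alphas[t] * (layer_embeddings[t] @ W[f"W_Z{t}"])
    else:
        M = layer_embeddings[T] @ W[f"W_Z{T}"]
    probs = ad.sigmoid(M)
    return M, probs, states


def forward(
    graph: GeneGraph,
    weights: dict[str, np.ndarray],
    config: ModelConfig,
    record_energy: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[LayerState]]:
    """Full forward pass on a graph with explicit (ndarray) weights.

    Returns per-gene logits ("scores"), their sigmoid probabilities, and
    the list of per-layer diagnostic states (layer 0 = projected
    features).
    """
    if graph.n_features != weights["W_I"].shape[0]:
        raise ValueError(
            f"graph has {graph.n_features} features, weights expect "
            f"{weights['W_I'].shape[0]}"
        )
    Ahat = encoder.normalized_adjacency(graph.A)
    M, probs, states = _forward_core(
        graph.X, Ahat, weights, config,
        record_states=True, record_energy=record_energy,
    )
    return _data(M).ravel(), _data(probs).ravel(), states


# ---------------------------------------------------------------------------
# loss


def bce_loss(probabilities, y, mask=None):
    """Mean binary cross-entropy over the labeled genes selected by ``mask``.

    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logs.
    Unlabeled genes (NaN label) are always excluded; ``mask`` restricts
    further (e.g. to a training fold).  Polymorphic: with a Tensor input
    the loss is differentiable.
    """
    y = np.asarray(y, dtype=float).ravel()
    labeled = ~np.isnan(y)
    if mask is not None:
        labeled = labeled & np.asarray(mask, dtype=bool).ravel()
    count = int(labeled.sum())
    if count == 0:
        raise ValueError("mask selects zero labeled nodes")
    pshape = probabilities.shape if isinstance(probabilities, Tensor) else np.shape(probabilities)
    yv = np.nan_to_num(y, nan=0.0).reshape(pshape)
    w = (labeled.astype(float) / count).reshape(pshape)
    p = ad.clip(probabilities, _PROB_EPS, 1.0 - _PROB_EPS)
    terms = yv * ad.log(p) + (1.0 - yv) * ad.log(1.0 - p)
    return -ad.tsum(w * terms)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam with bias correction (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator


class ECDCDGIClassifier(BaseEstimator, ClassifierMixin):
    """Energy-constrained diffusion attention classifier for driver genes.

    A transductive node classifier: ``fit(X, y, adjacency=A)`` trains on
    the labeled nodes of one gene-gene graph (``y`` entries in {0, 1},
    with NaN or -1 marking unlabeled genes) and scores *all* nodes of
    that graph.  See :class:`ModelConfig` for the meaning and defaults of
    every hyperparameter; the constructor mirrors its fields.

    Attributes set by :meth:`fit`
    -----------------------------
    weights_ : dict of ndarray
        All learned arrays (projection, per-layer transforms, fusion,
        LayerNorm affine, per-layer readout weights and alphas).
    history_ : list of float
        Per-epoch training loss, evaluated before each update.
    energy_history_ : list of list of float, optional
        Per-epoch, per-layer diffusion energy (when ``log_energy=True``).
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        hidden_dim: int = 100,
        n_layers: int = 4,
        beta: float = 0.5,
        learning_rate: float = 0.001,
        epochs: int = 100,
        use_ecd_attention: bool = True,
        use_gcn: bool = True,
        use_residual: bool = True,
        use_multilayer_attention: bool = True,
        softmax_layer_weights: bool = False,
        gcn_input: str = "value",
        random_state: int = 0,
        log_energy: bool = False,
    ):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.beta = beta
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.use_ecd_attention = use_ecd_attention
        self.use_gcn = use_gcn
        self.use_residual = use_residual
        self.use_multilayer_attention = use_multilayer_attention
        self.softmax_layer_weights = softmax_layer_weights
        self.gcn_input = gcn_input
        self.random_state = random_state
        self.log_energy = log_energy

    # -- config plumbing -------------------------------------------------

    def _config(self) -> ModelConfig:
        return ModelConfig(**{
            f.name: getattr(self, f.name) for f in fields(ModelConfig)
        })

    @classmethod
    def from_config(cls, cfg: ModelConfig, log_energy: bool = False) -> "ECDCDGIClassifier":
        return cls(**asdict(cfg), log_energy=log_energy)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y, adjacency=None, sample_mask=None):
        """Train on the labeled nodes of one graph.

        Parameters
        ----------
        X : ndarray (N, F)
            Per-gene features.
        y : array-like (N,)
            Labels in {0, 1}; NaN or -1 marks unlabeled genes.
        adjacency : sparse or dense (N, N)
            Symmetric binary adjacency of the gene-gene network.
        sample_mask : bool array (N,), optional
            Restrict the loss to a subset of the labeled genes (e.g. a
            cross-validation training fold).
        """
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        y = np.where(y == -1, np.nan, y)
        if adjacency is None:
            raise ValueError("adjacency is required: this is a graph node classifier")
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of genes")
        train_mask = ~np.isnan(y)
        if sample_mask is not None:
            train_mask &= np.asarray(sample_mask, dtype=bool).ravel()
        classes = np.unique(y[train_mask])
        if not np.isin([0.0, 1.0], classes).all():
            raise ValueError("training mask must contain both classes")

        Ahat = encoder.normalized_adjacency(adjacency)
        rng = np.random.default_rng(cfg.random_state)
        params = {
            k: Tensor(v, requires_grad=True)
            for k, v in init_weights(X.shape[1], cfg, rng).items()
        }
        opt = Adam(params, lr=cfg.learning_rate)
        history: list[float] = []
        energy_history: list[list[float]] = []
        for _ in range(cfg.epochs):
            opt.zero_grad()
            _, probs, states = _forward_core(
                X, Ahat, params, cfg,
                record_energy=self.log_energy,
            )
            loss = bce_loss(probs, y, train_mask)
            history.append(loss.item())
            if self.log_energy:
                energy_history.append([s.energy for s in states])
            loss.backward()
            opt.step()

        self.weights_ = {k: p.data.copy() for k, p in params.items()}
        self.history_ = history
        if self.log_energy:
            self.energy_history_ = energy_history
        self.classes_ = np.array([0.0, 1.0])
        self.n_features_in_ = X.shape[1]
        self._Ahat = Ahat
        self._X = X
        return self

    def fit_graph(self, graph: GeneGraph, train_mask=None) -> "ECDCDGIClassifier":
        """Convenience wrapper: fit on a :class:`~ecdcdgi.graph.GeneGraph`."""
        return self.fit(graph.X, graph.y, adjacency=graph.A, sample_mask=train_mask)

    # -- inference -------------------------------------------------------

    def _scores(self, X=None, adjacency=None) -> tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "weights_"):
            raise ValueError("estimator is not fitted")
        if X is None:
            if not hasattr(self, "_X"):
                raise ValueError("no training graph stored; pass X and adjacency")
            X, Ahat = self._X, self._Ahat
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
                )
            if adjacency is not None:
                Ahat = encoder.normalized_adjacency(adjacency)
            elif hasattr(self, "_Ahat"):
                Ahat = self._Ahat
            else:
                raise ValueError("adjacency required for prediction on a new graph")
        M, probs, _ = _forward_core(X, Ahat, self.weights_, self._config())
        return np.asarray(M).ravel(), np.asarray(probs).ravel()

    def decision_function(self, X=None, adjacency=None) -> np.ndarray:
        """Raw per-gene readout scores (logits)."""
        return self._scores(X, adjacency)[0]

    def predict_proba(self, X=None, adjacency=None) -> np.ndarray:
        """Class probabilities, column 1 = driver probability."""
        p = self._scores(X, adjacency)[1]
        return np.column_stack([1.0 - p, p])

    def predict(self, X=None, adjacency=None) -> np.ndarray:
        return (self._scores(X, adjacency)[1] >= 0.5).astype(float)


# ---------------------------------------------------------------------------
# functional wrappers


def train(graph: GeneGraph, train_mask=None, config: ModelConfig | None = None,
          log_energy: bool = False) -> ECDCDGIClassifier:
    """Train a classifier on a graph; thin wrapper over the estimator."""
    cfg = config or ModelConfig()
    est = ECDCDGIClassifier.from_config(cfg, log_energy=log_energy)
    return est.fit_graph(graph, train_mask=train_mask)


def predict(model: ECDCDGIClassifier, graph: GeneGraph | None = None):
    """Per-gene logits and probabilities for all N nodes of ``graph``."""
    if graph is None:
        return model._scores()
    return model._scores(graph.X, graph.A)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ECDCDGIClassifier, path) -> None:
    """Serialize a fitted model (weights + config) to an .npz archive."""
    cfg = model._config()
    meta = json.dumps(asdict(cfg))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.weights_)


def load_model(path) -> ECDCDGIClassifier:
    """Load a model saved by :func:`save_model` (inference-ready)."""
    with np.load(path) as arch:
        meta = json.loads(bytes(arch["__config__"]).decode())
        weights = {k: arch[k] for k in arch.files if k != "__config__"}
    cfg = ModelConfig(**meta)
    est = ECDCDGIClassifier.from_config(cfg)
    est.weights_ = weights
    est.classes_ = np.array([0.0, 1.0])
    est.n_features_in_ = weights["W_I"].shape[0]
    return est
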