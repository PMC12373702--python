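"""Predictor families for treatment-need classification.

Two model families mirror the two study analyses:

* :class:`FluidLogit` — an L2-penalized logistic regression on eight
  scan-derived fluid features (IRF/SRF volumes, SRF height at Weeks 8
  and 16, and the week-16 minus week-8 volume changes).  Follows the
  statsmodels convention: construct from data, call :meth:`FluidLogit.fit`,
  get a results object with coefficients, standard errors and a
  ``summary()`` table.
* :class:`VolumeNet` — a small twin-encoder 3-D convolutional network
  over the Week-8/Week-16 model-input volume pair, trainable from
  scratch or by transfer learning (pretrained encoder, re-initialized
  head, reduced learning rate).

``pretrain_source`` / ``fine_tune`` / ``train_from_scratch`` are thin
functional wrappers over :class:`VolumeNet` for the transfer-learning
protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _nn
from ._nn import NetConfig
from .biomarkers import FluidMetrics

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "featurize",
    "FluidLogit",
    "FluidLogitResults",
    "fit_logistic",
    "NetConfig",
    "VolumeNet",
    "VolumeNetResults",
    "pretrain_source",
    "fine_tune",
    "train_from_scratch",
]

FEATURE_NAMES = (
    "irf_nl_wk8", "irf_nl_wk16",
    "srf_nl_wk8", "srf_nl_wk16",
    "srf_h_wk8", "srf_h_wk16",
    "delta_irf_nl", "delta_srf_nl",
)


@dataclass(frozen=True)
class FeatureVector:
    """Raw fluid features of one patient's Week-8/Week-16 scan pair."""

    irf_nl_wk8: float
    irf_nl_wk16: float
    srf_nl_wk8: float
    srf_nl_wk16: float
    srf_h_wk8: float
    srf_h_wk16: float
    delta_irf_nl: float
    delta_srf_nl: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("features must be finite")
        if abs(self.delta_irf_nl - (self.irf_nl_wk16 - self.irf_nl_wk8)) > 1e-6:
            raise ValueError("delta_irf_nl inconsistent with endpoints")
        if abs(self.delta_srf_nl - (self.srf_nl_wk16 - self.srf_nl_wk8)) > 1e-6:
            raise ValueError("delta_srf_nl inconsistent with endpoints")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


def featurize(metrics_wk8: FluidMetrics, metrics_wk16: FluidMetrics) -> FeatureVector:
    """Deterministic feature mapping from the two visits' fluid metrics."""
    if metrics_wk8 is None or metrics_wk16 is None:
        raise ValueError("both the Week-8 and Week-16 visit metrics are required")
    return FeatureVector(
        irf_nl_wk8=metrics_wk8.irf_volume_nl,
        irf_nl_wk16=metrics_wk16.irf_volume_nl,
        srf_nl_wk8=metrics_wk8.srf_volume_nl,
        srf_nl_wk16=metrics_wk16.srf_volume_nl,
        srf_h_wk8=metrics_wk8.srf_max_height_um,
        srf_h_wk16=metrics_wk16.srf_max_height_um,
        delta_irf_nl=metrics_wk16.irf_volume_nl - metrics_wk8.irf_volume_nl,
        delta_srf_nl=metrics_wk16.srf_volume_nl - metrics_wk8.srf_volume_nl,
    )


def _signed_log1p(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.log1p(np.abs(x))


class FluidLogit:
    """Penalized logistic regression on fluid features.

    Parameters
    ----------
    X : (n, p) array of raw features (nL / um scale).
    y : (n,) binary labels.
    feature_names : optional names for reporting.
    log_transform : apply a signed log1p to the features before
        standardization (volumes are heavy-tailed).
    standardize : center/scale features with training-set moments.
    class_weight : None or "balanced" (inverse-frequency loss weights).
    """

    def __init__(self, X, y, feature_names: Optional[Sequence[str]] = None,
                 log_transform: bool = True, standardize: bool = True,
                 class_weight: Optional[str] = None, hidden_units: int = 0):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y).astype(int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, p) with matching labels")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need both classes to fit a classifier")
        self.feature_names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(self.X.shape[1])]
        self.log_transform = log_transform
        self.standardize = standardize
        self.class_weight = class_weight
        self.hidden_units = int(hidden_units)

    @classmethod
    def from_feature_vectors(cls, vectors: Sequence[FeatureVector], y, **kw) -> "FluidLogit":
        X = np.stack([v.as_array() for v in vectors])
        return cls(X, y, feature_names=FEATURE_NAMES, **kw)

    def _design(self, X):
        Z = np.asarray(X, dtype=np.float64)
        if self.log_transform:
            Z = _signed_log1p(Z)
        if self.standardize:
            Z = (Z - self._mean) / self._scale
        return Z[:, self._keep]

    def fit(self, l2_strength: float = 1.0) -> "FluidLogitResults":
        """Maximize the L2-penalized binomial log-likelihood."""
        if l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        Z = _signed_log1p(self.X) if self.log_transform else self.X.copy()
        self._mean = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=0)
        constant = sd < 1e-12
        if constant.any():
            names = [self.feature_names[i] for i in np.flatnonzero(constant)]
            warnings.warn(f"dropping constant feature(s): {names}", UserWarning, stacklevel=2)
        self._scale = np.where(constant, 1.0, sd)
        if not self.standardize:
            self._mean = np.zeros_like(self._mean)
            self._scale = np.ones_like(self._scale)
        self._keep = np.flatnonzero(~constant)
        if self._keep.size == 0:
            # uninformative design: intercept-only model (chance predictions)
            warnings.warn("all features constant; fitting an intercept-only model",
                          UserWarning, stacklevel=2)
            pbar = float(np.clip(self.y.mean(), 1e-9, 1 - 1e-9))
            eta0 = float(np.log(pbar / (1 - pbar)))
            se0 = 1.0 / np.sqrt(len(self.y) * pbar * (1 - pbar))
            return FluidLogitResults(
                model=self, params=np.array([eta0]), bse=np.array([se0]),
                cov_params=np.array([[se0**2]]), l2_strength=l2_strength,
                kept_names=["intercept"])
        Zk = self._design(self.X)
        if self.hidden_units > 0:
            return self._fit_hidden(Zk, l2_strength)
        clf = LogisticRegression(C=1.0 / l2_strength, solver="lbfgs", max_iter=5000,
                                 class_weight=self.class_weight, tol=1e-8)
        clf.fit(Zk, self.y)
        coef = clf.coef_[0]
        intercept = float(clf.intercept_[0])
        # observed-information standard errors of the penalized fit
        eta = Zk @ coef + intercept
        p = 1.0 / (1.0 + np.exp(-eta))
        Wd = p * (1 - p)
        Xd = np.column_stack([np.ones(len(Zk)), Zk])
        H = Xd.T @ (Xd * Wd[:, None])
        ridge = np.diag([0.0] + [l2_strength] * Zk.shape[1])
        cov = np.linalg.inv(H + ridge)
        bse = np.sqrt(np.diag(cov))
        return FluidLogitResults(
            model=self,
            params=np.concatenate([[intercept], coef]),
            bse=bse,
            cov_params=cov,
            l2_strength=l2_strength,
            kept_names=["intercept"] + [self.feature_names[i] for i in self._keep],
        )

    def _fit_hidden(self, Zk, l2_strength):
        """Optional one-hidden-layer variant (sigmoid output head)."""
        from sklearn.neural_network import MLPClassifier

        net = MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                            alpha=l2_strength, max_iter=2000, random_state=0)
        net.fit(Zk, self.y)
        res = FluidLogitResults(
            model=self, params=np.zeros(Zk.shape[1] + 1),
            bse=np.full(Zk.shape[1] + 1, np.nan),
            cov_params=np.full((Zk.shape[1] + 1,) * 2, np.nan),
            l2_strength=l2_strength,
            kept_names=["intercept"] + [self.feature_names[i] for i in self._keep],
        )
        res._net = net
        return res


@dataclass
class FluidLogitResults:
    """Fitted logistic model: coefficients, uncertainties, predictions."""

    model: FluidLogit
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    l2_strength: float
    kept_names: list

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[1:]

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    _net = None  # set by the optional hidden-layer variant

    def predict_proba(self, X) -> np.ndarray:
        Z = self.model._design(X)
        if self._net is not None:
            return self._net.predict_proba(Z)[:, 1]
        eta = Z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def transformed_design(self) -> np.ndarray:
        """Training design matrix after transform/standardization."""
        return self.model._design(self.model.X)

    def summary(self) -> str:
        lines = [
            "Penalized logistic regression (binomial log-likelihood, L2)",
            f"  n = {len(self.model.y)}, events = {int(self.model.y.sum())}, "
            f"lambda = {self.l2_strength:g}",
            f"  {'term':<14s} {'coef':>9s} {'se':>8s} {'z':>7s}",
        ]
        for name, b, s in zip(self.kept_names, self.params, self.bse):
            z = b / s if s > 0 else np.nan
            lines.append(f"  {name:<14s} {b:9.4f} {s:8.4f} {z:7.2f}")
        return "\n".join(lines)


def fit_logistic(features, labels, l2_strength: float = 1.0, **kw) -> FluidLogitResults:
    """Convenience wrapper: build a :class:`FluidLogit` and fit it.

    Requires at least as many observations as features; the class itself
    accepts n < p designs (the L2 penalty keeps them well-posed).
    """
    X = np.asarray(features)
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many samples as features")
    return FluidLogit(X, labels, **kw).fit(l2_strength=l2_strength)


class VolumeNet:
    """Twin-encoder 3-D convolutional classifier for scan pairs.

    Input arrays have shape (n, 2, 28, 52, 72): the Week-8 and Week-16
    preprocessed model-input volumes.  ``fit`` trains with Adam, weighted
    cross-entropy and early stopping; pass ``init_weights`` (and
    ``finetune=True`` for the reduced learning rate) to transfer-learn
    from a pretrained encoder with a freshly initialized head.
    """

    def __init__(self, config: Optional[NetConfig] = None):
        self.config = config or NetConfig()

    def fit(self, X, y, X_val=None, y_val=None, init_weights: Optional[Dict] = None,
            finetune: bool = False, epochs: Optional[int] = None,
            seed: Optional[int] = None) -> "VolumeNetResults":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 5 or X.shape[1] != 2 or X.shape[2:] != self.config.input_shape:
            raise ValueError(f"X must be (n, 2, {self.config.input_shape}) volume pairs")
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        if init_weights is not None:
            for key in self.config.encoder_keys:
                if init_weights[key].shape != _nn.init_weights(self.config, np.random.default_rng(0))[key].shape:
                    raise ValueError(f"pretrained weight {key} does not match the configuration")
            w0 = _nn.init_weights(self.config, rng, encoder=init_weights)
        else:
            w0 = _nn.init_weights(self.config, rng)
        if finetune and (epochs is None or epochs > 0) and self.config.head_warmup_epochs > 0:
            # head warm-up: frozen pretrained encoder, full learning rate
            w0, warm_hist = _nn.train(
                X, y, self.config, X_val, y_val, init=w0,
                lr=self.config.learning_rate, epochs=self.config.head_warmup_epochs,
                rng=rng, trainable=self.config.head_keys, early_stop=False)
        else:
            warm_hist = None
        lr = self.config.learning_rate * (self.config.finetune_lr_scale if finetune else 1.0)
        weights, history = _nn.train(X, y, self.config, X_val, y_val, init=w0,
                                     lr=lr, epochs=epochs, rng=rng)
        if warm_hist is not None:
            history = {k: warm_hist[k] + history[k] for k in history}
        if history["train_loss"] and not np.isfinite(history["train_loss"][-1]):
            raise FloatingPointError("training diverged to a non-finite loss")
        return VolumeNetResults(config=self.config, weights=weights, history=history,
                                finetuned=finetune)


@dataclass
class VolumeNetResults:
    """Trained network: weights snapshot, training curves, predictions."""

    config: NetConfig
    weights: Dict[str, np.ndarray]
    history: Dict[str, list]
    finetuned: bool = False

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return _nn.predict_proba(X, self.weights, self.config)

    def weights_hash(self) -> str:
        return _nn.weights_hash(self.weights)

    def summary(self) -> str:
        n_params = sum(v.size for v in self.weights.values())
        lines = [
            "Volumetric twin-encoder network",
            f"  channels {self.config.channels}, head {self.config.head_width}, "
            f"{n_params} parameters",
            f"  mode: {'transfer (fine-tuned)' if self.finetuned else 'from scratch'}",
            f"  epochs run: {len(self.history['train_loss'])}",
        ]
        if self.history["val_loss"]:
            lines.append(f"  best validation loss: {min(self.history['val_loss']):.4f}")
        return "\n".join(lines)


def pretrain_source(net_config: NetConfig, X_source, y_source, seed: int = 0,
                    val_fraction: float = 0.2) -> Dict[str, np.ndarray]:
    """Train the network on the source task; return the weight snapshot.

    Emulates the origin of the transferred model: an encoder trained on a
    related disease-activity task (here a surrogate cohort labelled by
    fluid persistence) whose features transfer to the target endpoints.
    """
    X = np.asarray(X_source, dtype=np.float32)
    y = np.asarray(y_source, dtype=np.float64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(val_fraction * len(X))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    res = VolumeNet(net_config).fit(X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], seed=seed)
    return res.weights


def fine_tune(weights: Dict[str, np.ndarray], net_config: NetConfig,
              X, y, X_val=None, y_val=None, seed: int = 0,
              epochs: Optional[int] = None) -> VolumeNetResults:
    """Transfer learning: pretrained encoder, fresh head, reduced LR."""
    return VolumeNet(net_config).fit(X, y, X_val, y_val, init_weights=weights,
                                     finetune=True, seed=seed, epochs=epochs)


def train_from_scratch(net_config: NetConfig, X, y, X_val=None, y_val=None,
                       seed: int = 0, epochs: Optional[int] = None) -> VolumeNetResults:
    """Random initialization baseline with the same optimization budget."""
    return VolumeNet(net_config).fit(X, y, X_val, y_val, seed=seed, epochs=epochs)
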