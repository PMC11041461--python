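"""Classifiers over the four uncertainty channels.

Two predictors are provided, both trained by minimizing cross-entropy with
minibatch Adam and early stopping on validation macro-F1:

:class:`EUPClassifier`
    standalone model: the four channels are projected to the hidden
    dimension ``h``, concatenated (``I_EUP = I_M ⊕ I_C ⊕ I_F ⊕ I_P``) and
    fed to a one-hidden-layer softmax head.

:class:`GatedFusionClassifier`
    wraps any baseline whose penultimate feature ``o`` is available: each
    channel is scaled by a gate ``g_X = sigmoid(Linear(o ⊕ I_X))`` and the
    gated sum ``I = Σ g_X ⊙ I_X`` is concatenated with ``o`` before the
    head, so the baseline adaptively selects how much of each uncertainty
    channel to use.

Both follow the model/results idiom: the model object holds the data and
architecture, ``fit`` returns a :class:`ClassifierResults` carrying the
fitted weights, training history, diagnostics and a ``summary()``.
Channels can be knocked out (``drop_channels``) by zeroing the projected
channel vector everywhere it is used — before the physical channel is
assembled and before fusion — which keeps parameter counts comparable
across ablations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .data_io import RunConfig
from .eup_features import FeatureBundle, PostFeatures
from .evaluation import accuracy_score, f1_score, macro_f1

CHANNELS = ("macro", "micro", "framing", "physical")


def concat_eup(bundle: FeatureBundle) -> np.ndarray:
    """Concatenate the four channel vectors in the fixed order
    (I_M, I_C, I_F, I_P)."""
    return np.concatenate([bundle.I_M, bundle.I_C, bundle.I_F, bundle.I_P], axis=-1)


def gate(o: np.ndarray, I_X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gating vector: elementwise logistic of an affine map of ``o ⊕ I_X``."""
    q = np.concatenate([o, I_X], axis=-1)
    if q.shape[-1] != W.shape[0]:
        raise ValueError(f"gate expects input dimension {W.shape[0]}, got {q.shape[-1]}")
    return _nn.sigmoid(q @ W + b)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0, 1])):
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("single-class training set")
    return y


def _mask_vector(drop_channels: Sequence[str]) -> dict[str, float]:
    unknown = set(drop_channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if set(drop_channels) == set(CHANNELS):
        raise ValueError("cannot drop all four channels")
    return {ch: 0.0 if ch in drop_channels else 1.0 for ch in CHANNELS}


class _BaseClassifier:
    """Shared data handling and training loop."""

    def __init__(
        self,
        features: PostFeatures,
        labels: np.ndarray,
        hidden_dim: int = 32,
        config: RunConfig | None = None,
    ) -> None:
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        if len(self.labels) != len(features):
            raise ValueError("labels and features disagree in length")
        self.hidden_dim = hidden_dim
        self.config = config or RunConfig(hidden_dim=hidden_dim)
        self.embed_dim = features.X_F.shape[1]
        if features.X_M.shape[1] != 2 * self.embed_dim:
            raise ValueError("X_M must have dimension 2d")

    # subclasses: _init_params, _forward(params, feats, mask, baseline) -> (probs, cache)
    # and _backward(params, cache, dlogits, mask) -> grads

    def fit(
        self,
        seed: int = 0,
        val_data: tuple | None = None,
        drop_channels: Sequence[str] = (),
        learning_rate: float | None = None,
        epochs: int | None = None,
        batch_size: int | None = None,
        patience: int | None = None,
    ) -> "ClassifierResults":
        """Train with minibatch Adam; early-stops on validation macro-F1.

        ``val_data`` is ``(features, labels)`` (plus baseline features as a
        third element for the fused model).  Without validation data the
        model trains for the full epoch budget.
        """
        y = _check_labels(self.labels)
        mask = _mask_vector(drop_channels)
        cfg = self.config
        lr = learning_rate if learning_rate is not None else cfg.learning_rate
        n_epochs = epochs if epochs is not None else cfg.epochs
        bs = batch_size if batch_size is not None else cfg.batch_size
        wait = patience if patience is not None else cfg.patience

        rng = np.random.default_rng(seed)
        params = self._init_params(rng)
        opt = _nn.Adam(params, lr=lr)
        n = len(y)
        history: list[dict] = []
        best_metric = -np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        stale = 0

        for epoch in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                probs, cache = self._forward(params, self._slice(idx), mask)
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                opt.step(self._backward(params, cache, dlogits, mask))
            train_probs, _ = self._forward(params, self._slice(None), mask)
            row = {"epoch": epoch, "train_loss": _nn.cross_entropy(train_probs, y)}
            if val_data is not None:
                val_probs = self._val_probs(params, val_data, mask)
                y_val = np.asarray(val_data[1], dtype=int)
                row["val_loss"] = _nn.cross_entropy(val_probs, y_val)
                row["val_macro_f1"] = macro_f1(val_probs.argmax(axis=1), y_val)
                metric = row["val_macro_f1"]
                if metric > best_metric + 1e-12:
                    best_metric = metric
                    best_params = {k: v.copy() for k, v in params.items()}
                    best_epoch = epoch
                    stale = 0
                else:
                    stale += 1
            history.append(row)
            if val_data is not None and stale > wait:
                break
        if val_data is None:
            best_params = params
            best_epoch = len(history) - 1
        return ClassifierResults(
            model=self,
            params=best_params,
            mask=mask,
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            best_val_macro_f1=None if val_data is None else best_metric,
            seed=seed,
        )

    # -- helpers -----------------------------------------------------------

    def _slice(self, idx):
        f = self.features
        if idx is None:
            return f, self._baseline_all()
        return f.subset(idx), self._baseline_subset(idx)

    def _baseline_all(self):
        return None

    def _baseline_subset(self, idx):
        return None

    def _val_probs(self, params, val_data, mask):
        feats = val_data[0]
        baseline = val_data[2] if len(val_data) > 2 else None
        probs, _ = self._forward(params, (feats, baseline), mask)
        return probs

    def _channels_forward(self, params, feats: PostFeatures, mask):
        h = self.hidden_dim
        IM = (feats.X_M @ params["pM_W"] + params["pM_b"]) * mask["macro"]
        IC = (feats.X_C @ params["pC_W"] + params["pC_b"]) * mask["micro"]
        IF = (feats.X_F @ params["pF_W"] + params["pF_b"]) * mask["framing"]
        Z = feats.f[:, None] * np.concatenate([IM, IC, IF], axis=1)
        IP = (Z @ params["pP_W"] + params["pP_b"]) * mask["physical"]
        return IM, IC, IF, IP, Z

    def _channels_backward(self, params, cache, dIM, dIC, dIF, dIP, mask):
        feats: PostFeatures = cache["feats"]
        h = self.hidden_dim
        grads = {}
        dIP = dIP * mask["physical"]
        grads["pP_W"] = cache["Z"].T @ dIP
        grads["pP_b"] = dIP.sum(axis=0)
        dZ = (dIP @ params["pP_W"].T) * feats.f[:, None]
        dIM = (dIM + dZ[:, :h]) * mask["macro"]
        dIC = (dIC + dZ[:, h : 2 * h]) * mask["micro"]
        dIF = (dIF + dZ[:, 2 * h :]) * mask["framing"]
        grads["pM_W"] = feats.X_M.T @ dIM
        grads["pM_b"] = dIM.sum(axis=0)
        grads["pC_W"] = feats.X_C.T @ dIC
        grads["pC_b"] = dIC.sum(axis=0)
        grads["pF_W"] = feats.X_F.T @ dIF
        grads["pF_b"] = dIF.sum(axis=0)
        return grads

    def _init_channel_params(self, rng) -> dict[str, np.ndarray]:
        d, h = self.embed_dim, self.hidden_dim
        params = {}
        for name, n_in in (("pM", 2 * d), ("pC", 2 * d), ("pF", d), ("pP", 3 * h)):
            lin = _nn.init_linear(rng, n_in, h)
            params[f"{name}_W"], params[f"{name}_b"] = lin["W"], lin["b"]
        return params


class EUPClassifier(_BaseClassifier):
    """Standalone environmental-uncertainty classifier (no baseline)."""

    name = "EUP"

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        h = self.hidden_dim
        params = self._init_channel_params(rng)
        for name, n_in, n_out in (("h1", 4 * h, h), ("out", h, 2)):
            lin = _nn.init_linear(rng, n_in, n_out)
            params[f"{name}_W"], params[f"{name}_b"] = lin["W"], lin["b"]
        return params

    def _forward(self, params, data, mask):
        feats, _ = data if isinstance(data, tuple) else (data, None)
        IM, IC, IF, IP, Z = self._channels_forward(params, feats, mask)
        U = np.concatenate([IM, IC, IF, IP], axis=1)
        H = np.tanh(U @ params["h1_W"] + params["h1_b"])
        probs = _nn.softmax(H @ params["out_W"] + params["out_b"])
        cache = {"feats": feats, "Z": Z, "U": U, "H": H}
        return probs, cache

    def _backward(self, params, cache, dlogits, mask):
        h = self.hidden_dim
        H, U = cache["H"], cache["U"]
        grads = {"out_W": H.T @ dlogits, "out_b": dlogits.sum(axis=0)}
        dH = (dlogits @ params["out_W"].T) * (1 - H * H)
        grads["h1_W"] = U.T @ dH
        grads["h1_b"] = dH.sum(axis=0)
        dU = dH @ params["h1_W"].T
        grads.update(
            self._channels_backward(
                params, cache,
                dU[:, :h], dU[:, h : 2 * h], dU[:, 2 * h : 3 * h], dU[:, 3 * h :],
                mask,
            )
        )
        return grads


class GatedFusionClassifier(_BaseClassifier):
    """Gated fusion of the four channels with a baseline feature ``o``."""

    name = "GatedFusion"

    def __init__(
        self,
        features: PostFeatures,
        labels: np.ndarray,
        baseline_features: np.ndarray,
        hidden_dim: int = 32,
        config: RunConfig | None = None,
    ) -> None:
        super().__init__(features, labels, hidden_dim=hidden_dim, config=config)
        self.baseline_features = np.asarray(baseline_features, dtype=float)
        if len(self.baseline_features) != len(features):
            raise ValueError("baseline features and post features disagree in length")
        self.baseline_dim = self.baseline_features.shape[1]
        expected = self.config.baseline_dim
        if config is not None and self.baseline_dim != expected:
            raise ValueError(
                f"baseline feature dimension {self.baseline_dim} != configured {expected}"
            )

    def _baseline_all(self):
        return self.baseline_features

    def _baseline_subset(self, idx):
        return self.baseline_features[idx]

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        h, d_o = self.hidden_dim, self.baseline_dim
        params = self._init_channel_params(rng)
        for ch in CHANNELS:
            lin = _nn.init_linear(rng, d_o + h, h)
            params[f"g_{ch}_W"], params[f"g_{ch}_b"] = lin["W"], lin["b"]
        for name, n_in, n_out in (("h1", d_o + h, h), ("out", h, 2)):
            lin = _nn.init_linear(rng, n_in, n_out)
            params[f"{name}_W"], params[f"{name}_b"] = lin["W"], lin["b"]
        return params

    def _forward(self, params, data, mask):
        feats, O = data
        if O is None:
            raise ValueError("fused mode requires baseline features")
        IM, IC, IF, IP, Z = self._channels_forward(params, feats, mask)
        channels = {"macro": IM, "micro": IC, "framing": IF, "physical": IP}
        gates = {}
        I = np.zeros_like(IM)
        for ch in CHANNELS:
            gates[ch] = gate(O, channels[ch], params[f"g_{ch}_W"], params[f"g_{ch}_b"])
            I = I + gates[ch] * channels[ch]
        R = np.concatenate([O, I], axis=1)
        H = np.tanh(R @ params["h1_W"] + params["h1_b"])
        probs = _nn.softmax(H @ params["out_W"] + params["out_b"])
        cache = {"feats": feats, "Z": Z, "O": O, "channels": channels,
                 "gates": gates, "R": R, "H": H}
        return probs, cache

    def _backward(self, params, cache, dlogits, mask):
        d_o = self.baseline_dim
        H, R = cache["H"], cache["R"]
        O = cache["O"]
        grads = {"out_W": H.T @ dlogits, "out_b": dlogits.sum(axis=0)}
        dH = (dlogits @ params["out_W"].T) * (1 - H * H)
        grads["h1_W"] = R.T @ dH
        grads["h1_b"] = dH.sum(axis=0)
        dI = (dH @ params["h1_W"].T)[:, d_o:]
        d_channel = {}
        for ch in CHANNELS:
            G = cache["gates"][ch]
            I_X = cache["channels"][ch]
            dG = dI * I_X
            dS = dG * G * (1 - G)
            Q = np.concatenate([O, I_X], axis=1)
            grads[f"g_{ch}_W"] = Q.T @ dS
            grads[f"g_{ch}_b"] = dS.sum(axis=0)
            d_channel[ch] = dI * G + (dS @ params[f"g_{ch}_W"].T)[:, d_o:]
        grads.update(
            self._channels_backward(
                params, cache,
                d_channel["macro"], d_channel["micro"], d_channel["framing"],
                d_channel["physical"], mask,
            )
        )
        return grads


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResults:
    """Fitted weights plus training diagnostics for either classifier."""

    model: _BaseClassifier
    params: dict[str, np.ndarray]
    mask: dict[str, float]
    history: pd.DataFrame
    best_epoch: int
    best_val_macro_f1: float | None
    seed: int

    # -- prediction --------------------------------------------------------

    def predict_proba(self, features: PostFeatures, baseline: np.ndarray | None = None) -> np.ndarray:
        probs, _ = self.model._forward(self.params, (features, baseline), self.mask)
        return probs

    def predict(self, features: PostFeatures, baseline: np.ndarray | None = None) -> np.ndarray:
        return self.predict_proba(features, baseline).argmax(axis=1)

    def transform(self, features: PostFeatures, baseline: np.ndarray | None = None) -> list[FeatureBundle]:
        """Projected channel representations of each post (diagnostics)."""
        IM, IC, IF, IP, _ = self.model._channels_forward(self.params, features, self.mask)
        return [
            FeatureBundle(IM[i], IC[i], IF[i], IP[i], float(features.f[i]))
            for i in range(len(features))
        ]

    def predict_from_bundle(self, bundle: FeatureBundle) -> np.ndarray:
        """Head probabilities for one already-projected channel bundle."""
        u = concat_eup(bundle)
        H = np.tanh(u @ self.params["h1_W"] + self.params["h1_b"])
        return _nn.softmax(H @ self.params["out_W"] + self.params["out_b"])

    def gates(self, o: np.ndarray, bundle: FeatureBundle) -> dict[str, np.ndarray]:
        """Per-channel gating vectors for one post (fused model only)."""
        channels = {"macro": bundle.I_M, "micro": bundle.I_C,
                    "framing": bundle.I_F, "physical": bundle.I_P}
        return {
            ch: gate(o, channels[ch], self.params[f"g_{ch}_W"], self.params[f"g_{ch}_b"])
            for ch in CHANNELS
        }

    def fuse(self, o: np.ndarray, bundle: FeatureBundle) -> np.ndarray:
        """Gated channel sum ``I = Σ g_X ⊙ I_X`` (fused model only)."""
        channels = {"macro": bundle.I_M, "micro": bundle.I_C,
                    "framing": bundle.I_F, "physical": bundle.I_P}
        gates = self.gates(o, bundle)
        out = np.zeros_like(bundle.I_M)
        for ch in CHANNELS:
            out = out + gates[ch] * channels[ch]
        return out

    # -- evaluation --------------------------------------------------------

    def evaluate(self, features: PostFeatures, labels: np.ndarray,
                 baseline: np.ndarray | None = None) -> dict[str, float]:
        from .evaluation import sp_auc

        y = np.asarray(labels, dtype=int)
        probs = self.predict_proba(features, baseline)
        pred = probs.argmax(axis=1)
        metrics = {
            "accuracy": accuracy_score(pred, y),
            "macro_f1": macro_f1(pred, y),
            "f1_class1": f1_score(pred, y, positive=1),
            "f1_class0": f1_score(pred, y, positive=0),
        }
        if len(np.unique(y)) == 2:
            metrics["sp_auc"] = sp_auc(probs[:, 1], y)
        return metrics

    # -- reporting ---------------------------------------------------------

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def summary(self) -> str:
        model = self.model
        dropped = [ch for ch, m in self.mask.items() if m == 0.0] or ["none"]
        lines = [
            f"{model.name} classifier results",
            "=" * 40,
            f"observations (train):   {len(model.labels)}",
            f"hidden dimension h:     {model.hidden_dim}",
            f"embedding dimension d:  {model.embed_dim}",
            f"parameters:             {self.n_params}",
            f"seed:                   {self.seed}",
            f"epochs run:             {len(self.history)}",
            f"best epoch:             {self.best_epoch}",
            f"channels dropped:       {', '.join(dropped)}",
        ]
        if self.best_val_macro_f1 is not None:
            lines.append(f"best val macro-F1:      {self.best_val_macro_f1:.4f}")
        if len(self.history):
            lines.append(f"final train loss:       {self.history['train_loss'].iloc[-1]:.4f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path, scorer_fingerprint: str | None = None,
             f_bounds: tuple[float, float] | None = None,
             baseline_params: dict | None = None) -> None:
        """Write a single-file JSON checkpoint: weights, architecture,
        run configuration, the training scorer's fingerprint and the
        physical-factor normalization bounds."""
        import json
        from pathlib import Path

        model = self.model
        payload = {
            "format_version": 1,
            "model": model.name,
            "hidden_dim": model.hidden_dim,
            "embed_dim": model.embed_dim,
            "baseline_dim": getattr(model, "baseline_dim", None),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "mask": self.mask,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "best_val_macro_f1": self.best_val_macro_f1,
            "config": json.loads(model.config.to_json()),
            "scorer_sha256": scorer_fingerprint,
            "f_bounds": list(f_bounds) if f_bounds is not None else None,
            "baseline_params": None if baseline_params is None
            else {k: v.tolist() for k, v in baseline_params.items()},
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    def plot_history(self, ax=None):
        """Training-loss / validation-metric curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train loss")
        if "val_loss" in self.history:
            ax.plot(self.history["epoch"], self.history["val_loss"], label="val loss")
        if "val_macro_f1" in self.history:
            ax2 = ax.twinx()
            ax2.plot(self.history["epoch"], self.history["val_macro_f1"],
                     color="tab:green", label="val macro-F1")
            ax2.set_ylabel("val macro-F1")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax.legend(loc="best")
        return ax


def load_checkpoint(path) -> tuple[ClassifierResults, dict]:
    """Restore a checkpoint written by :meth:`ClassifierResults.save`.

    Returns the results object (ready for prediction; the shell model
    carries no training data) and the raw payload, which includes the
    scorer fingerprint, physical-factor bounds and, for fused checkpoints,
    the baseline adapter's weights.
    """
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    cls = {"EUP": EUPClassifier, "GatedFusion": GatedFusionClassifier}[payload["model"]]
    model = cls.__new__(cls)
    model.hidden_dim = int(payload["hidden_dim"])
    model.embed_dim = int(payload["embed_dim"])
    model.config = RunConfig(**payload["config"])
    model.labels = np.empty(0, dtype=int)
    model.features = None
    if payload["baseline_dim"] is not None:
        model.baseline_dim = int(payload["baseline_dim"])
        model.baseline_features = np.empty((0, model.baseline_dim))
    results = ClassifierResults(
        model=model,
        params={k: np.asarray(v, dtype=float) for k, v in payload["params"].items()},
        mask={k: float(v) for k, v in payload["mask"].items()},
        history=pd.DataFrame(),
        best_epoch=int(payload["best_epoch"]),
        best_val_macro_f1=payload.get("best_val_macro_f1"),
        seed=int(payload["seed"]),
    )
    return results, payload
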