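"""The feed-forward deconvolution network.

A plain multilayer perceptron mapping a normalized marker-gene profile
(length G, entries in [0, 1], summing to 1) to a cell-type proportion
vector (length K).  The default hidden layout is three blocks of paired
layers of decreasing width — (512, 512), (256, 256), (128, 128) — followed
by a single hidden layer of 64.  Each paired layer is followed by batch
normalization and a rectified-linear activation; the link from the last
hidden layer to the output passes through a leaky rectifier with
negative-side slope 0.1, which lets training penalize negative outputs
without silencing their gradient.

The training loss (mean absolute error) is computed on the *pre-scaling*
output: the network learns to emit near-proportion vectors directly, which
avoids the degenerate near-zero-sum outputs that a scale-then-loss design
invites at large K.  At inference the output is divided by its sum S so the
reported vector sums to exactly 1; if S <= 0 (all outputs non-positive, which
training actively discourages) the model falls back to the uniform vector
with a warning.

Everything here is NumPy; forward, backward and parameter updates are exact
and bit-reproducible on CPU for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN_LAYOUT = (512, 512, 256, 256, 128, 128, 64)
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``batch_norm`` applies to every hidden layer except the final (unpaired)
    one.  ``final_activation_slope`` is the negative-side gradient of the
    leaky rectifier on the output.
    """

    input_dim: int
    output_dim: int
    hidden_layout: tuple[int, ...] = DEFAULT_HIDDEN_LAYOUT
    final_activation_slope: float = 0.1
    loss: str = "L1"
    batch_norm: bool = True

    def __post_init__(self) -> None:
        self.hidden_layout = tuple(int(h) for h in self.hidden_layout)
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.output_dim < 2:
            raise ValueError("output_dim must be >= 2 (a single type needs no model)")
        if any(h <= 0 for h in self.hidden_layout):
            raise ValueError("hidden layer sizes must be positive")
        if self.loss != "L1":
            raise ValueError("only the L1 (mean absolute error) loss is supported")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "output_dim": self.output_dim,
            "hidden_layout": list(self.hidden_layout),
            "final_activation_slope": self.final_activation_slope,
            "loss": self.loss,
            "batch_norm": self.batch_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["hidden_layout"] = tuple(d["hidden_layout"])
        return cls(**d)


@dataclass
class OutputVector:
    """Raw (pre-scaling) and sum-normalized network output for one batch."""

    raw: np.ndarray
    scaled: np.ndarray
    S: np.ndarray


def scale_output(raw: np.ndarray, warn: bool = True) -> OutputVector:
    """Divide each output vector by its sum so it sums to 1.

    Rows whose sum is not positive fall back to the uniform vector.
    Negative entries are left as-is here (they can arise from the leaky
    slope); reporting-side clamping lives in :mod:`spotdecon.evaluation`.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    S = raw.sum(axis=1)
    scaled = np.empty_like(raw)
    bad = S <= 0
    if np.any(bad):
        if warn:
            logger.warning(
                "%d output vector(s) had non-positive sum; falling back to uniform",
                int(bad.sum()),
            )
        scaled[bad] = 1.0 / raw.shape[1]
    good = ~bad
    scaled[good] = raw[good] / S[good, None]
    return OutputVector(raw=raw, scaled=scaled, S=S)


def l1_loss(raw: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute difference between pre-scaling output and truth."""
    raw = np.asarray(raw, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if raw.shape != truth.shape:
        raise ValueError(f"shape mismatch: {raw.shape} vs {truth.shape}")
    return float(np.mean(np.abs(raw - truth)))


class DeconvolutionModel:
    """NumPy multilayer perceptron with manual backprop.

    Parameters are held in a flat ``{name: array}`` dict so an optimizer can
    iterate them generically.  Linear layers use the fan-in uniform
    initialization ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``.
    """

    def __init__(
        self,
        config: NetworkConfig,
        seed: int = 0,
        gene_ids: list[str] | None = None,
        label_order: list[str] | None = None,
    ):
        self.config = config
        self.gene_ids = gene_ids
        self.label_order = label_order
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        dims = [config.input_dim, *config.hidden_layout, config.output_dim]
        n_hidden = len(config.hidden_layout)
        # batch norm on every hidden layer except the last (unpaired) one
        self._bn_layers = [
            config.batch_norm and i < n_hidden - 1 for i in range(n_hidden)
        ]
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            bound = 1.0 / np.sqrt(fan_in)
            self.params[f"W{i}"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
            self.params[f"b{i}"] = rng.uniform(-bound, bound, size=fan_out)
            if i < n_hidden and self._bn_layers[i]:
                self.params[f"gamma{i}"] = np.ones(fan_out)
                self.params[f"beta{i}"] = np.zeros(fan_out)
                self.running[f"mean{i}"] = np.zeros(fan_out)
                self.running[f"var{i}"] = np.ones(fan_out)
        self._n_layers = len(dims) - 1

    # ------------------------------------------------------------------ #
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"profile length {X.shape[1]} != model input_dim "
                f"{self.config.input_dim}"
            )
        return X

    def forward(self, X: np.ndarray, train: bool = False):
        """Run the network.

        Returns an :class:`OutputVector`; in training mode also returns the
        cache needed by :meth:`backward`.  Evaluation mode uses the frozen
        running batch-norm statistics and is deterministic.
        """
        X = self._check_input(X)
        A = X
        cache: list[dict] = []
        n_hidden = len(self.config.hidden_layout)
        for i in range(n_hidden):
            W, b = self.params[f"W{i}"], self.params[f"b{i}"]
            Z = A @ W + b
            layer: dict = {"A_prev": A, "Z": Z}
            if self._bn_layers[i]:
                if train:
                    mu = Z.mean(axis=0)
                    var = Z.var(axis=0)
                    self.running[f"mean{i}"] = (
                        (1 - _BN_MOMENTUM) * self.running[f"mean{i}"]
                        + _BN_MOMENTUM * mu
                    )
                    # unbiased variance for the running estimate, as torch does
                    m = Z.shape[0]
                    unbiased = var * m / max(m - 1, 1)
                    self.running[f"var{i}"] = (
                        (1 - _BN_MOMENTUM) * self.running[f"var{i}"]
                        + _BN_MOMENTUM * unbiased
                    )
                else:
                    mu = self.running[f"mean{i}"]
                    var = self.running[f"var{i}"]
                ivar = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (Z - mu) * ivar
                H = self.params[f"gamma{i}"] * xhat + self.params[f"beta{i}"]
                layer.update({"xhat": xhat, "ivar": ivar, "bn": True})
            else:
                H = Z
                layer["bn"] = False
            A = np.maximum(H, 0.0)
            layer["H"] = H
            cache.append(layer)
        i = n_hidden
        O = A @ self.params[f"W{i}"] + self.params[f"b{i}"]
        slope = self.config.final_activation_slope
        raw = np.where(O > 0, O, slope * O)
        # during training only the raw output feeds the loss; don't warn
        # about non-positive sums the optimizer is still being pushed away from
        out = scale_output(raw, warn=not train)
        if train:
            return out, {"layers": cache, "A_last": A, "O": O}
        return out

    def backward(self, cache: dict, raw: np.ndarray, truth: np.ndarray):
        """Gradients of the mean-absolute pre-scaling loss w.r.t. all params."""
        truth = np.asarray(truth, dtype=float)
        B, K = raw.shape
        grads: dict[str, np.ndarray] = {}
        slope = self.config.final_activation_slope
        draw = np.sign(raw - truth) / (B * K)
        O = cache["O"]
        dO = draw * np.where(O > 0, 1.0, slope)
        i = self._n_layers - 1
        A_last = cache["A_last"]
        grads[f"W{i}"] = A_last.T @ dO
        grads[f"b{i}"] = dO.sum(axis=0)
        dA = dO @ self.params[f"W{i}"].T
        for i in reversed(range(len(self.config.hidden_layout))):
            layer = cache["layers"][i]
            dH = dA * (layer["H"] > 0)
            if layer["bn"]:
                xhat, ivar = layer["xhat"], layer["ivar"]
                grads[f"gamma{i}"] = (dH * xhat).sum(axis=0)
                grads[f"beta{i}"] = dH.sum(axis=0)
                m = dH.shape[0]
                dxhat = dH * self.params[f"gamma{i}"]
                dZ = (
                    ivar
                    / m
                    * (
                        m * dxhat
                        - dxhat.sum(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0)
                    )
                )
            else:
                dZ = dH
            A_prev = layer["A_prev"]
            grads[f"W{i}"] = A_prev.T @ dZ
            grads[f"b{i}"] = dZ.sum(axis=0)
            if i > 0:
                dA = dZ @ self.params[f"W{i}"].T
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scaled (sum-to-1) predictions in evaluation mode."""
        return self.forward(X, train=False).scaled

    # ------------------------------------------------------------------ #
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.copy() for k, v in self.params.items()}
        state.update({f"running:{k}": v.copy() for k, v in self.running.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            kind, name = k.split(":", 1)
            target = self.params if kind == "param" else self.running
            if name not in target:
                raise KeyError(f"unexpected state entry {k}")
            target[name] = np.array(v, dtype=float)

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: weights + config + gene/label order."""
        meta = {
            "config": self.config.to_dict(),
            "gene_ids": self.gene_ids,
            "label_order": self.label_order,
        }
        np.savez(
            Path(path), _meta=np.array(json.dumps(meta)), **self.state_dict()
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeconvolutionModel":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            model = cls(
                NetworkConfig.from_dict(meta["config"]),
                gene_ids=meta["gene_ids"],
                label_order=meta["label_order"],
            )
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "_meta"}
            )
        return model


def build_network(
    config: NetworkConfig,
    seed: int = 0,
    gene_ids: list[str] | None = None,
    label_order: list[str] | None = None,
) -> DeconvolutionModel:
    """Construct and initialize a deconvolution network from ``seed``."""
    return DeconvolutionModel(
        config, seed=seed, gene_ids=gene_ids, label_order=label_order
    )
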