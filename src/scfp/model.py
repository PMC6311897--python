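"""The two-stage 1-D convolutional network and its geometry.

The first convolution spans the full 42-column width of the SMILES feature
matrix, so convolution slides only along the string.  Two conv+pool stages
are followed by global max pooling, whose output is the SMILES convolution
fingerprint (SCFP, 64-dimensional by default); a single hidden layer and a
sigmoid unit sit on top for classification.

Geometry helpers map second-stage output positions back to input rows: one
output unit sees a window of at most ``2*k1 + k2`` input rows (the motif-size
bound), where ``k1`` and ``k2`` are the two convolution window widths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .featurizer import N_FEATURES

SCFP_DEFAULT_DIM = 64

_POOL_TYPES = ("max", "average", "none")
_PAD_POLICIES = ("none", "half")
_ACTIVATIONS = ("relu", "leaky_relu", "prelu")


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters (the searchable space plus defaults).

    Window sizes live in [1, 51] and strides in {1, 3, 5} when validating a
    search space; the defaults fix k1 = k2 = 7 with stride 1 and a
    width-7 average pool between the stages, so one second-stage unit spans
    19 input rows, within the 2*k1 + k2 = 21 bound.
    """

    conv1_filters: int = 128
    conv1_window: int = 7
    conv1_stride: int = 1
    conv1_padding: str = "none"
    pool1_type: str = "average"
    pool1_window: int = 7
    pool1_stride: int = 1
    pool1_padding: str = "none"
    conv2_filters: int = SCFP_DEFAULT_DIM
    conv2_window: int = 7
    conv2_stride: int = 1
    conv2_padding: str = "none"
    pool2_type: str = "none"
    pool2_window: int = 1
    pool2_stride: int = 1
    pool2_padding: str = "none"
    hidden_units: int = 96
    activation: str = "leaky_relu"
    leaky_slope: float = 0.2
    batch_norm: bool = False
    dropout: float = 0.0
    mask_padding: bool = True
    n_features: int = N_FEATURES

    def __post_init__(self):
        self.validate()

    def validate(self, search_space: bool = False):
        bad = []
        for name in ("conv1_filters", "conv1_window", "conv1_stride", "pool1_window",
                     "pool1_stride", "conv2_filters", "conv2_window", "conv2_stride",
                     "pool2_window", "pool2_stride", "hidden_units", "n_features"):
            if getattr(self, name) < 1:
                bad.append(f"{name} must be >= 1")
        for name in ("pool1_type", "pool2_type"):
            if getattr(self, name) not in _POOL_TYPES:
                bad.append(f"{name} must be one of {_POOL_TYPES}")
        for name in ("conv1_padding", "pool1_padding", "conv2_padding", "pool2_padding"):
            if getattr(self, name) not in _PAD_POLICIES:
                bad.append(f"{name} must be one of {_PAD_POLICIES}")
        if self.activation not in _ACTIVATIONS:
            bad.append(f"activation must be one of {_ACTIVATIONS}")
        if not 0.0 <= self.dropout < 1.0:
            bad.append("dropout must be in [0, 1)")
        if search_space:
            for name in ("conv1_window", "pool1_window", "conv2_window", "pool2_window"):
                if not 1 <= getattr(self, name) <= 51:
                    bad.append(f"{name} outside search range [1, 51]")
            for name in ("conv1_stride", "pool1_stride", "conv2_stride", "pool2_stride"):
                if getattr(self, name) not in (1, 3, 5):
                    bad.append(f"{name} outside search set {{1, 3, 5}}")
        if bad:
            raise ConfigError("invalid model config: " + "; ".join(bad))

    # -- layer geometry ------------------------------------------------

    def _pad(self, window: int, policy: str) -> int:
        return window // 2 if policy == "half" else 0

    def layers(self) -> list[tuple[int, int, int]]:
        """(window, stride, pad) of each sequence-direction layer, in order."""
        out = [(self.conv1_window, self.conv1_stride, self._pad(self.conv1_window, self.conv1_padding))]
        if self.pool1_type != "none":
            out.append((self.pool1_window, self.pool1_stride, self._pad(self.pool1_window, self.pool1_padding)))
        out.append((self.conv2_window, self.conv2_stride, self._pad(self.conv2_window, self.conv2_padding)))
        if self.pool2_type != "none":
            out.append((self.pool2_window, self.pool2_stride, self._pad(self.pool2_window, self.pool2_padding)))
        return out

    def out_len(self, L: int) -> int:
        for w, s, p in self.layers():
            L = _nn.out_length(L, w, s, p)
        return L


def receptive_field_bound(config: ModelConfig) -> int:
    """Exact width (in input rows) of the receptive field of one unit of the
    final pre-global-pool layer."""
    span, jump = 1, 1
    for w, s, _ in config.layers():
        span += (w - 1) * jump
        jump *= s
    return span


def motif_size_bound(config: ModelConfig) -> int:
    """Closed-form maximum-motif-size bound 2*k1 + k2, in SMILES symbols."""
    return 2 * config.conv1_window + config.conv2_window


def traceback_span(config: ModelConfig, position: int, input_len: int | None = None) -> tuple[int, int]:
    """Input-row interval [start, end) seen by one final-layer output unit.

    With ``input_len`` given, the position is range-checked against the
    layer-stack output length and the interval is clipped layer by layer, so
    windows hanging over a padded edge do not inflate the span: the result
    is the exact extent of real input rows that influence the unit.  Without
    ``input_len`` the unclipped interval is returned (its width is always
    :func:`receptive_field_bound`).
    """
    if position < 0:
        raise IndexError(f"position {position} out of range")
    layers = config.layers()
    if input_len is None:
        start = position
        for w, s, p in reversed(layers):
            start = start * s - p
        return start, start + receptive_field_bound(config)

    lengths = [input_len]  # real (unpadded) length at each layer input
    for w, s, p in layers:
        lengths.append(_nn.out_length(lengths[-1], w, s, p))
    if position >= lengths[-1]:
        raise IndexError(f"position {position} out of range (output length {lengths[-1]})")
    a, b = position, position + 1
    for (w, s, p), L in zip(reversed(layers), reversed(lengths[:-1])):
        a = a * s - p
        b = (b - 1) * s - p + w
        a, b = max(a, 0), min(b, L)
    return a, b


# ---------------------------------------------------------------- network


@dataclass
class SCFP:
    """A learned fingerprint: per-filter global-max activations."""

    values: np.ndarray
    compound_id: str = ""

    def __len__(self):
        return len(self.values)


class SCFPNetwork:
    """Weights + forward/backward for the two-stage SMILES CNN.

    Build with :func:`build_model`; training lives in :mod:`scfp.training`.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.bn_running: dict[str, dict[str, np.ndarray]] = {
            name: {"mean": np.zeros(f), "var": np.ones(f)}
            for name, f in (("bn1", config.conv1_filters), ("bn2", config.conv2_filters))
        }
        self.trained = False

    # -- construction ---------------------------------------------------

    @classmethod
    def build(cls, config: ModelConfig, seed: int = 0, init_std: float = 0.01) -> "SCFPNetwork":
        """All weights drawn i.i.d. N(0, init_std^2); biases zero."""
        config.validate()
        rng = np.random.default_rng(seed)
        c = config
        params = {
            "W1": rng.normal(0.0, init_std, (c.conv1_window * c.n_features, c.conv1_filters)),
            "b1": np.zeros(c.conv1_filters),
            "W2": rng.normal(0.0, init_std, (c.conv2_window * c.conv1_filters, c.conv2_filters)),
            "b2": np.zeros(c.conv2_filters),
            "W3": rng.normal(0.0, init_std, (c.conv2_filters, c.hidden_units)),
            "b3": np.zeros(c.hidden_units),
            "W4": rng.normal(0.0, init_std, (c.hidden_units, 1)),
            "b4": np.zeros(1),
        }
        if c.activation == "prelu":
            params["a1"] = np.array(0.25)
            params["a2"] = np.array(0.25)
            params["a3"] = np.array(0.25)
        if c.batch_norm:
            for name, f in (("bn1", c.conv1_filters), ("bn2", c.conv2_filters)):
                params[f"{name}_gamma"] = np.ones(f)
                params[f"{name}_beta"] = np.zeros(f)
        return cls(config, params)

    # -- masking --------------------------------------------------------

    def valid_positions(self, input_len: int, valid_lens: np.ndarray) -> np.ndarray:
        """(N, Lout) mask: output position q is valid iff its (unclipped)
        receptive field overlaps the unpadded part of the input."""
        Lout = self.config.out_len(input_len)
        starts = np.empty(Lout, dtype=np.int64)
        ends = np.empty(Lout, dtype=np.int64)
        for q in range(Lout):
            s, e = traceback_span(self.config, q)
            starts[q], ends[q] = s, e
        mask = (starts[None, :] < np.asarray(valid_lens)[:, None]) & (ends[None, :] > 0)
        # degenerate safety: never mask everything
        mask[~mask.any(axis=1), 0] = True
        return mask

    # -- forward / backward --------------------------------------------

    def _slope(self, layer: int) -> float:
        if self.config.activation == "prelu":
            return float(self.params[f"a{layer}"])
        return self.config.leaky_slope if self.config.activation == "leaky_relu" else 0.0

    def forward(
        self,
        X: np.ndarray,
        valid_lens: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Run the network on a (N, L, 42) batch.

        Returns a dict with ``scfp`` (N, F2), ``logits`` (N, 1), ``probs``,
        ``conv2_map`` (the pre-global-pool activation map), ``pos_mask`` and
        the backward cache.
        """
        c = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[2] != c.n_features:
            raise ValueError(f"expected (batch, length, {c.n_features}) input, got {X.shape}")
        p = self.params
        cache: dict = {}

        H, cache["conv1"] = _nn.conv1d_forward(
            X, p["W1"], p["b1"], c.conv1_stride, c._pad(c.conv1_window, c.conv1_padding)
        )
        if c.batch_norm:
            H, cache["bn1"] = _nn.batchnorm_forward(
                H, p["bn1_gamma"], p["bn1_beta"], self.bn_running["bn1"], train
            )
        kind = c.activation
        H, cache["act1"] = _nn.activation_forward(H, kind, self._slope(1))
        if c.pool1_type == "average":
            H, cache["pool1"] = _nn.avgpool1d_forward(
                H, c.pool1_window, c.pool1_stride, c._pad(c.pool1_window, c.pool1_padding)
            )
        elif c.pool1_type == "max":
            H, cache["pool1"] = _nn.maxpool1d_forward(
                H, c.pool1_window, c.pool1_stride, c._pad(c.pool1_window, c.pool1_padding)
            )
        H, cache["conv2"] = _nn.conv1d_forward(
            H, p["W2"], p["b2"], c.conv2_stride, c._pad(c.conv2_window, c.conv2_padding)
        )
        if c.batch_norm:
            H, cache["bn2"] = _nn.batchnorm_forward(
                H, p["bn2_gamma"], p["bn2_beta"], self.bn_running["bn2"], train
            )
        H, cache["act2"] = _nn.activation_forward(H, kind, self._slope(2))
        if c.pool2_type == "average":
            H, cache["pool2"] = _nn.avgpool1d_forward(
                H, c.pool2_window, c.pool2_stride, c._pad(c.pool2_window, c.pool2_padding)
            )
        elif c.pool2_type == "max":
            H, cache["pool2"] = _nn.maxpool1d_forward(
                H, c.pool2_window, c.pool2_stride, c._pad(c.pool2_window, c.pool2_padding)
            )

        N, L2, _ = H.shape
        if c.mask_padding and valid_lens is not None:
            pos_mask = self.valid_positions(X.shape[1], valid_lens)
        else:
            pos_mask = np.ones((N, L2), dtype=bool)
        scfp, gmax_idx = _nn.global_maxpool_forward(H, pos_mask)
        cache["gmax"] = (gmax_idx, L2)

        Z, cache["dense3"] = _nn.dense_forward(scfp, p["W3"], p["b3"])
        Z, cache["act3"] = _nn.activation_forward(Z, kind, self._slope(3))
        Z, cache["drop"] = _nn.dropout_forward(Z, c.dropout, rng or np.random.default_rng(), train)
        logits, cache["dense4"] = _nn.dense_forward(Z, p["W4"], p["b4"])

        return {
            "scfp": scfp,
            "logits": logits,
            "probs": _nn.sigmoid(logits),
            "conv2_map": H,
            "pos_mask": pos_mask,
            "gmax_idx": gmax_idx,
            "cache": cache,
        }

    def backward(self, out: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        c = self.config
        cache = out["cache"]
        grads: dict[str, np.ndarray] = {}

        dZ, grads["W4"], grads["b4"] = _nn.dense_backward(dlogits, cache["dense4"])
        dZ = _nn.dropout_backward(dZ, cache["drop"])
        dZ, da3 = _nn.activation_backward(dZ, cache["act3"])
        dscfp, grads["W3"], grads["b3"] = _nn.dense_backward(dZ, cache["dense3"])

        gmax_idx, L2 = cache["gmax"]
        dH = _nn.global_maxpool_backward(dscfp, gmax_idx, L2)

        if "pool2" in cache:
            back = _nn.avgpool1d_backward if c.pool2_type == "average" else _nn.maxpool1d_backward
            dH = back(dH, cache["pool2"])
        dH, da2 = _nn.activation_backward(dH, cache["act2"])
        if c.batch_norm:
            dH, grads["bn2_gamma"], grads["bn2_beta"] = _nn.batchnorm_backward(dH, cache["bn2"])
        dH, grads["W2"], grads["b2"] = _nn.conv1d_backward(dH, cache["conv2"])
        if "pool1" in cache:
            back = _nn.avgpool1d_backward if c.pool1_type == "average" else _nn.maxpool1d_backward
            dH = back(dH, cache["pool1"])
        dH, da1 = _nn.activation_backward(dH, cache["act1"])
        if c.batch_norm:
            dH, grads["bn1_gamma"], grads["bn1_beta"] = _nn.batchnorm_backward(dH, cache["bn1"])
        _, grads["W1"], grads["b1"] = _nn.conv1d_backward(dH, cache["conv1"])

        if c.activation == "prelu":
            grads["a1"] = np.array(da1)
            grads["a2"] = np.array(da2)
            grads["a3"] = np.array(da3)
        return grads

    # -- persistence ----------------------------------------------------

    def save(self, path):
        """Single-file checkpoint: JSON config header + weights (npz)."""
        meta = {"config": asdict(self.config), "trained": self.trained}
        arrays = dict(self.params)
        for name, run in self.bn_running.items():
            arrays[f"_run_{name}_mean"] = run["mean"]
            arrays[f"_run_{name}_var"] = run["var"]
        with open(path, "wb") as fh:  # file handle keeps np.savez from appending ".npz"
            np.savez(fh, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SCFPNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            config = ModelConfig(**meta["config"])
            params = {k: data[k].copy() for k in data.files if not k.startswith("_")}
            net = cls(config, params)
            for name in net.bn_running:
                if f"_run_{name}_mean" in data.files:
                    net.bn_running[name]["mean"] = data[f"_run_{name}_mean"].copy()
                    net.bn_running[name]["var"] = data[f"_run_{name}_var"].copy()
        net.trained = meta["trained"]
        return net


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SCFPNetwork:
    """Initialize a network with N(0, 0.01) weights and zero biases."""
    return SCFPNetwork.build(config or ModelConfig(), seed=seed)


def compute_scfp(model: SCFPNetwork, compound, max_len: int | None = None) -> SCFP:
    """SCFP for a single compound (SMILES string or FeatureMatrix).

    A convenience wrapper over featurize + forward; usable on trained and
    untrained networks alike.
    """
    from .featurizer import FeatureMatrix, FeaturizerConfig, featurize

    if isinstance(compound, FeatureMatrix):
        fm = compound
    else:
        cfg = FeaturizerConfig(max_len=max_len) if max_len else FeaturizerConfig()
        fm = featurize(compound, cfg)
    out = model.forward(fm.values[None], valid_lens=np.array([fm.valid_len]))
    return SCFP(out["scfp"][0], compound_id=fm.compound_id)
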