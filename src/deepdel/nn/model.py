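"""The window classifier: time-distributed CNN encoder + BLSTM + head.

Each of the T windows in a sample is encoded independently by the same
convolutional encoder (1x2 average pool, then six conv -> ReLU -> SE ->
max-pool blocks, global average pool, linear projection to F=160).  The
sequence of T encodings runs through two bidirectional LSTM layers of 64
units per direction, then a two-layer fully connected head with dropout
and a sigmoid emits one deletion probability per window.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..config import ConfigError, ModelConfig, MATRIX_ORIENTATION
from ..features import RegionBatch
from . import layers as L


class WindowClassifier:
    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = config or ModelConfig()
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = self.config

        # --- encoder: check spatial dims survive the pooling pyramid
        h, w = cfg.n, cfg.m
        w //= 2  # initial 1x2 average pool
        enc = [("pool0", L.AvgPool2d(1, 2))]
        in_ch = 1
        for bi, block in enumerate(cfg.conv_blocks):
            enc.append((f"conv{bi}", L.Conv2d(in_ch, block.filters,
                                              block.kernel, rng, dtype)))
            enc.append((f"relu{bi}", L.ReLU()))
            enc.append((f"se{bi}", L.SEBlock(block.filters, cfg.se_reduction,
                                             rng, dtype)))
            enc.append((f"pool{bi + 1}", L.MaxPool2d(*block.pool)))
            h, w = h // block.pool[0], w // block.pool[1]
            if h < 1 or w < 1:
                raise ConfigError(
                    f"conv block {bi} pools the {cfg.n}x{cfg.m} input away; "
                    "reduce pooling or enlarge m/n")
            in_ch = block.filters
        enc.append(("gap", L.GlobalAvgPool()))
        enc.append(("proj", L.Dense(in_ch, cfg.F, rng, dtype)))
        self.encoder = enc

        # --- recurrent core
        self.blstm1 = L.BiLSTM(cfg.F, cfg.lstm_units, rng, dtype)
        self.blstm2 = L.BiLSTM(2 * cfg.lstm_units, cfg.lstm_units, rng, dtype)

        # --- classification head (dropout after each fully connected layer)
        d1, d2 = cfg.dense_sizes
        drop_rng = np.random.default_rng(seed + 1)
        self.head = [
            ("fc1", L.Dense(2 * cfg.lstm_units, d1, rng, dtype)),
            ("hrelu1", L.ReLU()),
            ("drop1", L.Dropout(cfg.dropout_rate, drop_rng)),
            ("fc2", L.Dense(d1, d2, rng, dtype)),
            ("hrelu2", L.ReLU()),
            ("drop2", L.Dropout(cfg.dropout_rate, drop_rng)),
            ("fc_out", L.Dense(d2, 1, rng, dtype)),
            ("out_sigmoid", L.Sigmoid()),
        ]

    # -- parameter access ---------------------------------------------------
    def _layers(self):
        for name, layer in self.encoder:
            yield name, layer
        yield "blstm1_fwd", self.blstm1.fwd
        yield "blstm1_bwd", self.blstm1.bwd
        yield "blstm2_fwd", self.blstm2.fwd
        yield "blstm2_bwd", self.blstm2.bwd
        for name, layer in self.head:
            yield name, layer

    def parameters(self):
        """Flat list of (qualified_name, layer, param_key)."""
        out = []
        for name, layer in self._layers():
            for key in layer.params:
                out.append((f"{name}.{key}", layer, key))
        return out

    def num_parameters(self) -> int:
        return sum(layer.params[k].size for _, layer, k in self.parameters())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {qn: layer.params[k].copy() for qn, layer, k in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for qn, layer, k in self.parameters():
            layer.params[k] = weights[qn].astype(self.dtype).copy()

    # -- forward / backward -------------------------------------------------
    def encode_window(self, matrix) -> np.ndarray:
        """Encode one feature matrix (n x m) into an F-vector."""
        rows = matrix.rows if hasattr(matrix, "rows") else np.asarray(matrix)
        x = rows.astype(self.dtype)[None, None]
        for _, layer in self.encoder:
            x = layer.forward(x, train=False)
        return x[0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, T, n, m) window matrices -> (B, T) probabilities."""
        B, T, n, m = x.shape
        if (n, m) != (self.config.n, self.config.m):
            raise ConfigError(
                f"input windows are {n}x{m}, model expects "
                f"{self.config.n}x{self.config.m}")
        h = x.reshape(B * T, 1, n, m).astype(self.dtype)
        for _, layer in self.encoder:
            h = layer.forward(h, train)
        h = h.reshape(B, T, self.config.F)
        h = self.blstm1.forward(h, train)
        h = self.blstm2.forward(h, train)
        h = h.reshape(B * T, -1)
        for _, layer in self.head:
            h = layer.forward(h, train)
        self._BT = (B, T)
        return h.reshape(B, T)

    def backward(self, dprobs: np.ndarray) -> None:
        B, T = self._BT
        dh = dprobs.reshape(B * T, 1).astype(self.dtype)
        for _, layer in reversed(self.head):
            dh = layer.backward(dh)
        dh = dh.reshape(B, T, -1)
        dh = self.blstm2.backward(dh)
        dh = self.blstm1.backward(dh)
        dh = dh.reshape(B * T, self.config.F)
        for _, layer in reversed(self.encoder):
            dh = layer.backward(dh)

    # -- inference convenience ----------------------------------------------
    def classify_batch(self, batch: RegionBatch) -> np.ndarray:
        """Probabilities for the T windows of one sample (inference mode)."""
        x = batch.matrices[None].astype(self.dtype)
        if x.shape[1] != batch.mask.shape[0]:
            raise ConfigError("batch matrices and mask lengths differ")
        return self.forward(x, train=False)[0]

    def predict_windows(self, batches) -> list:
        """Score every real (unmasked) window; returns [(SubRegion, prob)]."""
        out = []
        for batch in batches:
            probs = self.classify_batch(batch)
            for t, region in enumerate(batch.regions):
                if batch.mask[t]:
                    out.append((region, float(probs[t])))
        return out

    # -- persistence ----------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write weights to <prefix>.npz and config to <prefix>.json."""
        prefix = Path(prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), **self.get_weights())
        meta = {"model_config": self.config.to_dict(), "seed": self.seed,
                "orientation": MATRIX_ORIENTATION}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path, dtype=np.float32) -> "WindowClassifier":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(meta["model_config"]),
                    seed=meta.get("seed", 0), dtype=dtype)
        with np.load(prefix.with_suffix(".npz")) as z:
            model.set_weights({k: z[k] for k in z.files})
        return model

    def check_compatible(self, sidecar: dict) -> None:
        """Refuse to run against extraction output with mismatched m/n/T."""
        for key in ("m", "n"):
            if sidecar.get(key) != getattr(self.config, key):
                raise ConfigError(
                    f"extraction sidecar {key}={sidecar.get(key)} does not "
                    f"match model {key}={getattr(self.config, key)}")
        if sidecar.get("orientation") not in (None, MATRIX_ORIENTATION):
            raise ConfigError("matrix orientation mismatch")
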