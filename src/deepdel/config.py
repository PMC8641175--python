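"""Validated configuration containers for the whole pipeline.

Every tunable hyperparameter of feature extraction, the network, training
and the simulator lives here, in one place, so that extraction output and
model weights can be checked for compatibility (same ``m``, ``n``, ``T``)
before any expensive work starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


#: How feature matrices are oriented when fed to the network: rows are reads
#: (n of them), columns are window positions (m of them).  The convolutional
#: encoder pools and convolves along the position axis.  Extraction and the
#: network both import this constant so the orientation cannot drift.
MATRIX_ORIENTATION = "rows=reads,cols=positions"


@dataclass
class ConvBlockSpec:
    """One convolutional block: conv -> ReLU -> SE re-weighting -> max pool."""

    filters: int
    kernel: int = 3
    pool: tuple[int, int] = (1, 2)

    def validate(self) -> None:
        if self.filters < 1 or self.kernel < 1:
            raise ConfigError("conv block filters and kernel must be positive")
        if self.pool[0] < 1 or self.pool[1] < 1:
            raise ConfigError("pool sizes must be positive")


def _default_blocks() -> list[ConvBlockSpec]:
    return [
        ConvBlockSpec(8, 3, (2, 2)),
        ConvBlockSpec(16, 3, (2, 2)),
        ConvBlockSpec(16, 3, (1, 2)),
        ConvBlockSpec(32, 3, (2, 2)),
        ConvBlockSpec(32, 3, (1, 2)),
        ConvBlockSpec(64, 3, (1, 2)),
    ]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference design: 200-bp windows, 18 matrix rows,
    100 time steps, a 160-dimensional encoder output, two bidirectional
    LSTM layers of 64 units, two fully connected layers with dropout 0.4.
    """

    m: int = 200
    n: int = 18
    T: int = 100
    F: int = 160
    conv_blocks: list[ConvBlockSpec] = field(default_factory=_default_blocks)
    lstm_units: int = 64
    dense_sizes: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.4
    se_reduction: int = 4

    def __post_init__(self) -> None:
        for name in ("m", "n", "T", "F", "lstm_units", "se_reduction"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if len(self.conv_blocks) != 6:
            raise ConfigError("the encoder uses exactly 6 convolutional blocks")
        blocks = []
        for b in self.conv_blocks:
            if isinstance(b, dict):
                b = ConvBlockSpec(b["filters"], b.get("kernel", 3),
                                  tuple(b.get("pool", (1, 2))))
            b.pool = tuple(b.pool)
            b.validate()
            blocks.append(b)
        self.conv_blocks = blocks
        if len(self.dense_sizes) != 2 or any(s < 1 for s in self.dense_sizes):
            raise ConfigError("dense_sizes must be two positive widths")
        self.dense_sizes = tuple(self.dense_sizes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["orientation"] = MATRIX_ORIENTATION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d.pop("orientation", None)
        if "conv_blocks" in d:
            d["conv_blocks"] = [
                ConvBlockSpec(b["filters"], b.get("kernel", 3),
                              tuple(b.get("pool", (1, 2))))
                for b in d["conv_blocks"]
            ]
        if "dense_sizes" in d:
            d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)


@dataclass
class TrainingConfig:
    """Optimisation hyperparameters.

    ``loss_a`` is the offset of the squared-log loss; ``batch_size`` is
    counted in windows (a large batch keeps positive windows present at
    every step despite the ~99% negative class balance) and is rounded up
    to whole window-sequence samples internally.
    """

    loss_a: float = 0.001
    learning_rate: float = 0.001
    batch_size: int = 512
    patience: int = 10
    max_epochs: int = 100
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_a <= 0:
            raise ConfigError("loss_a must be > 0")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AlignmentFilter:
    """Which alignment records contribute rows to feature matrices.

    Unmapped, secondary and QC-fail records are always skipped.
    Supplementary alignments are kept by default because split reads carry
    deletion evidence.  Mapping-quality filtering is off (0) by default.
    """

    min_mapq: int = 0
    keep_supplementary: bool = True

    def accepts(self, aln) -> bool:
        if aln.is_unmapped or aln.is_secondary or aln.is_qcfail:
            return False
        if aln.is_supplementary and not self.keep_supplementary:
            return False
        return aln.mapping_quality >= self.min_mapq


@dataclass
class SimulationConfig:
    """Parameters of the synthetic long-read deletion benchmark.

    Defaults emulate the target data regime: deletions of 50 bp – 5 kb,
    reads of 1–20 kb, and enough genome per deletion that the vast
    majority (~97-98%) of 200-bp windows are negative, approaching the
    heavy class imbalance of real deletion call sets.
    """

    genome_length: int = 2_000_000
    n_deletions: int = 20
    deletion_size_range: tuple[int, int] = (50, 5000)
    coverage: float = 30.0
    read_length_range: tuple[int, int] = (1000, 20000)
    noise_deletion_rate: float = 5e-4
    noise_deletion_size_range: tuple[int, int] = (1, 30)
    mismatch_rate: float = 0.01
    heterozygous: bool = False
    window_size: int = 200
    contig: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.noise_deletion_rate, self.mismatch_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must be in [0, 1]")
        self.deletion_size_range = tuple(self.deletion_size_range)
        self.read_length_range = tuple(self.read_length_range)
        self.noise_deletion_size_range = tuple(self.noise_deletion_size_range)
        for lo, hi in (self.deletion_size_range, self.read_length_range,
                       self.noise_deletion_size_range):
            if lo < 1 or hi < lo:
                raise ConfigError("size ranges must satisfy 1 <= lo <= hi")
        if self.genome_length < 1 or self.n_deletions < 0:
            raise ConfigError("genome_length must be positive, n_deletions >= 0")
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")
        if self.window_size < 1:
            raise ConfigError("window_size must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
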