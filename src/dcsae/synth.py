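"""Synthetic EEG-style feature tables with planted class structure.

Emulates the layout of the UCI epileptic-seizure recognition table (rows are
1-second segments, 178 feature columns, 2-5 classes) so that feature
selection, classification and tuning can be exercised without any download.
Two waveform modes:

* ``iid-gaussian`` — pure noise everywhere, plus a mean shift of
  ``c * class_separation * noise_sd`` on the informative columns for class c
  (separation is an effect size in noise-SD units);
* ``sinusoid-segment`` — each row is one second of a sine at a
  class-specific frequency plus noise, sampled at ``n_features`` points,
  mimicking amplitude samples of a 178 Hz segment.

The generator is fully seeded and balanced by default; ``imbalance_ratio``
reproduces the roughly 1:4 seizure/non-seizure imbalance of the real binary
table for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable, write_feature_table

__all__ = ["SynthConfig", "generate", "write_uci_csv"]


@dataclass
class SynthConfig:
    n_per_class: int = 100
    n_classes: int = 2
    n_features: int = 178
    informative_indices: tuple[int, ...] = field(default_factory=tuple)
    class_separation: float = 2.0
    noise_sd: float = 1.0
    waveform_mode: str = "iid-gaussian"
    imbalance_ratio: float | None = None  # class-0 count multiplier, e.g. 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= 5:
            raise ValueError("n_classes must be in 2..5")
        if self.n_per_class < 1 or self.n_features < 1:
            raise ValueError("n_per_class and n_features must be positive")
        if self.class_separation <= 0 or self.noise_sd <= 0:
            raise ValueError("class_separation and noise_sd must be positive")
        if self.waveform_mode not in ("iid-gaussian", "sinusoid-segment"):
            raise ValueError(f"unknown waveform mode {self.waveform_mode!r}")
        self.informative_indices = tuple(int(i) for i in self.informative_indices)
        if any(not 0 <= i < self.n_features for i in self.informative_indices):
            raise ValueError("informative_indices out of range")
        if not self.informative_indices:
            # default: ~10% of columns, evenly spread
            k = max(1, self.n_features // 10)
            self.informative_indices = tuple(
                np.linspace(0, self.n_features - 1, k).astype(int).tolist()
            )


def generate(config: SynthConfig) -> tuple[FeatureTable, tuple[int, ...]]:
    """Generate a table plus the ground-truth informative indices."""
    rng = np.random.default_rng(config.rng_seed)
    counts = [config.n_per_class] * config.n_classes
    if config.imbalance_ratio is not None:
        counts[0] = max(1, int(round(config.n_per_class * config.imbalance_ratio)))
    labels = np.concatenate([np.full(c, k, dtype=int) for k, c in enumerate(counts)])
    n = labels.shape[0]
    values = rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    info = np.array(config.informative_indices, dtype=int)
    if config.waveform_mode == "iid-gaussian":
        shift = labels[:, None] * config.class_separation * config.noise_sd
        values[:, info] += shift
    else:
        # one-second segments: class c gets frequency (c+1)*2 Hz on the
        # informative columns, scaled by the separation effect size
        t = np.linspace(0.0, 1.0, config.n_features, endpoint=False)
        for c in range(config.n_classes):
            rows = labels == c
            wave = np.sin(2.0 * np.pi * 2.0 * (c + 1) * t)
            values[np.ix_(rows, info)] += (
                config.class_separation * config.noise_sd * wave[info]
            )
    # deterministic shuffle so classes are interleaved
    order = rng.permutation(n)
    table = FeatureTable(
        values[order],
        labels[order],
        [f"X{j + 1}" for j in range(config.n_features)],
        "binary" if config.n_classes == 2 else "multiclass",
    )
    return table, config.informative_indices


def write_uci_csv(table: FeatureTable, path) -> None:
    """CSV with header X1..Xd, y; round-trips through the reader losslessly."""
    write_feature_table(table, path)
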