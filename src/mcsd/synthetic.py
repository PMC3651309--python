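"""Synthetic multi-block expression data with planted class structure.

The generator emulates the shape of a multi-omics subtyping study: a handful
of disease subtypes measured on the same patients in several feature blocks
of very different dimensionality (a small miRNA-like block and a large
mRNA-like block). Every value is baseline Gaussian noise around 0.5; each
class owns a small disjoint set of planted features per block whose mean is
shifted upward by ``effect_size`` noise standard deviations for that class's
samples. A ``block_signal_map`` restricts which classes are separable in
which block, which is how block-complementarity experiments are built.

Defaults mirror a balanced four-subtype design with 15 training and 14
testing samples per class and block sizes 150 / 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabeledDataset
from .errors import ConfigError

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "split_balanced"]


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a generated dataset.

    effect_size is the planted mean shift in units of noise_sigma; noise
    "lognormal" swaps the Gaussian baseline for a right-skewed, mean-matched
    log-normal (model misspecification mode).
    """

    n_classes: int = 4
    block_sizes: tuple[int, ...] = (150, 2000)
    per_class_train: int = 15
    per_class_test: int = 14
    informative_per_class_per_block: int = 10
    effect_size: float = 4.0
    noise_sigma: float = 0.1
    block_signal_map: tuple[tuple[int, ...], ...] | None = None
    noise: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if not self.block_sizes or any(b <= 0 for b in self.block_sizes):
            raise ConfigError("block sizes must be positive")
        if self.per_class_train < 2 or self.per_class_test < 1:
            raise ConfigError("need >=2 training and >=1 testing samples per class")
        if self.informative_per_class_per_block < 0:
            raise ConfigError("informative feature count must be non-negative")
        if self.effect_size < 0:
            raise ConfigError("effect size must be non-negative")
        if self.noise_sigma <= 0:
            raise ConfigError("noise sigma must be positive")
        if self.noise not in ("gaussian", "lognormal"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        k = self.informative_per_class_per_block * self.n_classes
        if any(k > b for b in self.block_sizes):
            raise ConfigError(
                "planted features per block exceed the block size "
                f"({k} > {min(self.block_sizes)})"
            )
        if self.block_signal_map is not None:
            if len(self.block_signal_map) != len(self.block_sizes):
                raise ConfigError("block_signal_map must have one entry per block")
            for classes in self.block_signal_map:
                if any(not (0 <= c < self.n_classes) for c in classes):
                    raise ConfigError("block_signal_map class index out of range")


@dataclass
class SyntheticDataset:
    """Per-block train/test datasets plus the planted ground truth."""

    train_blocks: list[LabeledDataset]
    test_blocks: list[LabeledDataset]
    truth: dict  # block_name -> {class_index: [feature indices]}
    class_names: list[str]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset. Fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_classes
    per_total = config.per_class_train + config.per_class_test
    n_samples = n * per_total
    class_names = [f"class{k + 1}" for k in range(n)]

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    labels_arr = np.repeat(np.arange(n), per_total)
    train_mask = np.zeros(n_samples, dtype=bool)
    for k in range(n):
        start = k * per_total
        train_mask[start : start + config.per_class_train] = True

    signal_map = config.block_signal_map
    if signal_map is None:
        signal_map = tuple(tuple(range(n)) for _ in config.block_sizes)

    train_blocks: list[LabeledDataset] = []
    test_blocks: list[LabeledDataset] = []
    truth: dict = {}
    for b, size in enumerate(config.block_sizes):
        if config.noise == "gaussian":
            values = rng.normal(0.5, config.noise_sigma, (size, n_samples))
        else:
            # mean-matched right-skewed noise around 0.5
            ln = rng.lognormal(0.0, config.noise_sigma, (size, n_samples))
            values = 0.5 + (ln - np.exp(config.noise_sigma**2 / 2))

        k_inf = config.informative_per_class_per_block
        planted = rng.choice(size, n * k_inf, replace=False)
        block_truth = {}
        for k in range(n):
            feats = planted[k * k_inf : (k + 1) * k_inf]
            block_truth[k] = sorted(int(f) for f in feats)
            if k in signal_map[b]:
                cols = labels_arr == k
                values[np.ix_(feats, cols)] += config.effect_size * config.noise_sigma
        truth[f"block{b}"] = block_truth

        probe_ids = [f"b{b}_p{i:05d}" for i in range(size)]
        labels = {sid: int(k) for sid, k in zip(sample_ids, labels_arr)}
        full = ExpressionMatrix(probe_ids, sample_ids, values)
        tr_ids = [s for s, t in zip(sample_ids, train_mask) if t]
        te_ids = [s for s, t in zip(sample_ids, train_mask) if not t]
        ds = LabeledDataset(full, labels, class_names)
        train_blocks.append(ds.subset_samples(tr_ids))
        test_blocks.append(ds.subset_samples(te_ids))
    return SyntheticDataset(train_blocks, test_blocks, truth, class_names)


def split_balanced(
    data: LabeledDataset, per_class: int, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded class-balanced random split: ``per_class`` training samples per
    class, the remainder as test."""
    counts = data.class_counts()
    if np.any(counts <= per_class):
        raise ValueError(
            f"every class needs more than {per_class} samples; counts {counts.tolist()}"
        )
    rng = np.random.default_rng(seed)
    y = data.y
    sids = np.array(data.matrix.sample_ids)
    train_ids: list[str] = []
    for k in range(data.n_classes):
        members = sids[y == k]
        chosen = rng.choice(members, per_class, replace=False)
        train_ids.extend(chosen.tolist())
    train_set = set(train_ids)
    test_ids = [s for s in data.matrix.sample_ids if s not in train_set]
    # preserve original sample order within the training selection
    train_ids = [s for s in data.matrix.sample_ids if s in train_set]
    return data.subset_samples(train_ids), data.subset_samples(test_ids)
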