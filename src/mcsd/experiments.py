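"""Canned simulation experiments on synthetic multi-block data.

Two study designs:

* :func:`recovery_experiment` — a balanced four-subtype, two-block design
  (15 training / 14 testing samples per class, 10 planted features per class
  per block) used to measure how reliably the detector recovers the planted
  class structure at a given effect size.
* :func:`block_split_experiment` — the block-complementarity design: two
  classes are separable only in the small block and the other two only in
  the large block, so neither single data type can resolve all four classes
  while the cascaded input can.

Both repeat over independently seeded datasets and report per-seed test
accuracies together with the largest compress-matrix row l1 norm seen, for
auditing the selector-row feasibility bound. The homotopy ("lars") solver is
the default here purely for speed at simulation scale; it satisfies the same
constraint-residual tolerance as the exact LP solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classifier import accuracy, fit, predict
from .data_io import LabeledDataset, cascade
from .synthetic import SyntheticConfig, SyntheticDataset, generate

__all__ = [
    "ExperimentRun",
    "recovery_experiment",
    "block_split_experiment",
    "cascade_labeled",
]


@dataclass
class ExperimentRun:
    seed: int
    accuracy: float
    phi_l1_max: float


def cascade_labeled(
    blocks: list[LabeledDataset],
) -> LabeledDataset:
    """Cascade the matrices of per-block labeled datasets sharing samples."""
    matrix, _ = cascade([b.matrix for b in blocks])
    return LabeledDataset(matrix, dict(blocks[0].labels), list(blocks[0].class_names))


def _fit_eval(
    train: LabeledDataset, test: LabeledDataset, m: int, solver: str, seed: int
) -> ExperimentRun:
    model = fit(train, m, solver=solver, seed=seed)
    acc = accuracy(predict(model, test.matrix), test.y)
    return ExperimentRun(seed, acc, float(model.phi.row_l1_norms().max()))


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def recovery_experiment(
    n_seeds: int = 20,
    effect_size: float = 4.0,
    base_seed: int = 0,
    m: int = 40,
    solver: str = "lars",
    config: SyntheticConfig | None = None,
) -> list[ExperimentRun]:
    """Cascaded-input test accuracy over independently generated datasets.

    The default configuration is the generator default (four classes, blocks
    of 150 and 2000 features, 15/14 train/test per class, 10 planted features
    per class per block) at the requested effect size.
    """
    base = config if config is not None else SyntheticConfig()
    runs = []
    for seed in _seeds(base_seed, n_seeds):
        data = generate(replace(base, effect_size=effect_size, seed=seed))
        train = cascade_labeled(data.train_blocks)
        test = cascade_labeled(data.test_blocks)
        runs.append(_fit_eval(train, test, m, solver, seed))
    return runs


def block_split_experiment(
    n_seeds: int = 20,
    effect_size: float = 4.0,
    base_seed: int = 0,
    m: int = 40,
    solver: str = "lars",
) -> dict[str, list[ExperimentRun]]:
    """Cascaded vs single-block accuracy when class signal is split.

    Classes 1-2 carry planted signal only in block 0 and classes 3-4 only in
    block 1. Returns per-seed runs under keys ``combined``, ``block0`` and
    ``block1``.
    """
    base = SyntheticConfig(
        effect_size=effect_size, block_signal_map=((0, 1), (2, 3))
    )
    out: dict[str, list[ExperimentRun]] = {"combined": [], "block0": [], "block1": []}
    for seed in _seeds(base_seed, n_seeds):
        data = generate(replace(base, seed=seed))
        train_c = cascade_labeled(data.train_blocks)
        test_c = cascade_labeled(data.test_blocks)
        out["combined"].append(_fit_eval(train_c, test_c, m, solver, seed))
        for b in (0, 1):
            out[f"block{b}"].append(
                _fit_eval(data.train_blocks[b], data.test_blocks[b], m, solver, seed)
            )
    return out
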