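"""Hyperparameter sweep over image size x batch size x epochs.

Reproduces the grid-study protocol: every configuration trains on the
same train/validation items and is evaluated on the identical held-out
test partition, so rows are directly comparable. Each row carries the
full seven-metric report averaged over the test images, the final
train/validation losses, an overfit flag from the curve-based rule, and a
status column — a failed configuration is recorded and the sweep
continues. Selection defaults to the highest test Dice with ties broken
by higher Jaccard, then lower Hausdorff, then fewer parameters.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import evaluate, binarize
from .model import ModelConfig, build_model, count_parameters, predict
from .trainer import TrainConfig, SplitResult, prepare_pair, train, detect_overfit

__all__ = ["SweepConfig", "expand_grid", "run_sweep", "select_best",
           "config_name"]

PAPER_GRID_SIZES = ((256, 256), (512, 512), (1024, 1024), (464, 1356))
PAPER_GRID_BATCHES = (2, 4, 8, 16)
PAPER_GRID_EPOCHS = (50, 100, 150)

RESULT_COLUMNS = ["config_name", "accuracy", "precision", "recall", "jaccard",
                  "dice", "mae", "hausdorff", "final_train_loss",
                  "final_val_loss", "overfit_flag", "status", "wall_time_s",
                  "n_parameters", "test_items_hash"]


@dataclass(frozen=True)
class SweepConfig:
    image_sizes: tuple = PAPER_GRID_SIZES
    batch_sizes: tuple = PAPER_GRID_BATCHES
    epoch_counts: tuple = PAPER_GRID_EPOCHS
    explicit_configs: tuple | None = None
    split_seed: int = 0
    init_seed: int = 0
    base_filters: int = 16
    encoder_depth: int = 2
    validation_fraction: float = 0.2
    early_stop_patience: int = 10


def config_name(size: tuple, batch: int, epochs: int) -> str:
    h, w = size
    return f"PS_{h}x{w}_B{batch}_E{epochs}"


def expand_grid(sweep: SweepConfig) -> list[tuple]:
    """Cartesian product (size-major, then batch, then epochs) of the grid,
    or the explicit configuration list verbatim. Duplicates are an error."""
    if sweep.explicit_configs is not None:
        configs = [tuple(c) for c in sweep.explicit_configs]
    else:
        configs = [(tuple(s), int(b), int(e))
                   for s in sweep.image_sizes
                   for b in sweep.batch_sizes
                   for e in sweep.epoch_counts]
    if not configs:
        raise ValueError("sweep expands to an empty configuration list")
    seen, dupes = set(), []
    for c in configs:
        if c in seen:
            dupes.append(config_name(*c))
        seen.add(c)
    if dupes:
        raise ValueError(f"duplicate sweep configurations: {dupes}")
    return configs


def _items_hash(items) -> str:
    joined = "|".join(str(i) for i in items)
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


@dataclass
class SweepRow:
    config_name: str
    status: str = "ok"
    metrics: dict = field(default_factory=dict)
    final_train_loss: float = float("nan")
    final_val_loss: float = float("nan")
    overfit_flag: bool = False
    wall_time_s: float = float("nan")
    n_parameters: int = 0
    test_items_hash: str = ""

    def as_record(self) -> dict:
        rec = {"config_name": self.config_name}
        for k in ("accuracy", "precision", "recall", "jaccard", "dice",
                  "mae", "hausdorff"):
            rec[k] = self.metrics.get(k, float("nan"))
        rec.update(final_train_loss=self.final_train_loss,
                   final_val_loss=self.final_val_loss,
                   overfit_flag=self.overfit_flag, status=self.status,
                   wall_time_s=self.wall_time_s,
                   n_parameters=self.n_parameters,
                   test_items_hash=self.test_items_hash)
        return rec


def run_sweep(configs, dataset, split: SplitResult,
              sweep: SweepConfig = SweepConfig()) -> pd.DataFrame:
    """Train and evaluate every configuration against one shared split.

    ``dataset`` maps item identifiers to (image, mask) pairs at any
    source resolution; pairs are resized per configuration. Returns one
    row per configuration (failed rows keep status='failed').
    """
    test_hash = _items_hash(split.test_items)
    rows = []
    for size, batch, epochs in configs:
        name = config_name(size, batch, epochs)
        row = SweepRow(config_name=name, test_items_hash=test_hash)
        t0 = time.perf_counter()
        try:
            mc = ModelConfig(input_height=size[0], input_width=size[1],
                             encoder_depth=sweep.encoder_depth,
                             base_filters=sweep.base_filters)
            model = build_model(mc, seed=sweep.init_seed)
            tc = TrainConfig(image_size=size, batch_size=batch, epochs=epochs,
                             split_seed=sweep.split_seed,
                             init_seed=sweep.init_seed,
                             validation_fraction=sweep.validation_fraction,
                             early_stop_patience=sweep.early_stop_patience)
            history = train(model, dataset, split, tc)
            reports = []
            for item in split.test_items:
                img, msk = prepare_pair(*dataset[item], size)
                pred = binarize(predict(model, img), tc.binarize_threshold)
                reports.append(evaluate(pred, msk).to_dict())
            row.metrics = {k: float(np.mean([r[k] for r in reports]))
                           for k in reports[0]}
            row.final_train_loss = history.train_loss[-1]
            row.final_val_loss = history.val_loss[-1]
            try:
                row.overfit_flag = detect_overfit(history)[0]
            except ValueError:
                row.overfit_flag = False  # run shorter than the trend window
            row.n_parameters = count_parameters(model)
        except Exception as exc:  # record and continue: one bad cell
            row.status = f"failed: {type(exc).__name__}: {exc}"
        row.wall_time_s = time.perf_counter() - t0
        rows.append(row)
    return pd.DataFrame([r.as_record() for r in rows],
                        columns=RESULT_COLUMNS)


_CRITERIA = {
    "dice": [("dice", -1), ("jaccard", -1), ("hausdorff", 1),
             ("n_parameters", 1)],
    "val_loss": [("final_val_loss", 1), ("dice", -1)],
    "mae": [("mae", 1), ("dice", -1)],
}


def select_best(rows: pd.DataFrame, criterion: str = "dice"):
    """Pick the winning configuration.

    Default: maximum Dice, ties broken by higher Jaccard, then lower
    Hausdorff, then fewer parameters. Returns (config_name, comparison
    table sorted best-first).
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"choose from {sorted(_CRITERIA)}")
    ok = rows[rows["status"] == "ok"].copy()
    if ok.empty:
        raise ValueError("no successful sweep rows to select from")
    keys = _CRITERIA[criterion]
    for col, sign in keys:
        ok[f"_k_{col}"] = sign * ok[col].to_numpy(dtype=np.float64)
    sort_cols = [f"_k_{col}" for col, _ in keys]
    ok = ok.sort_values(sort_cols, kind="stable").drop(columns=sort_cols)
    winner = ok.iloc[0]["config_name"]
    return winner, ok.reset_index(drop=True)
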