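"""File formats and run configuration.

Everything on disk is plain CSV (UTF-8, comma-separated, "." decimal) or
YAML; CFSE generation tables are small, so no binary format is warranted.
Counts files carry the columns ``time_h, replicate_id, generation_class,
cell_count`` with the literal ``5+`` for the merged class; files denominated
in days may use ``time_d`` instead and are converted on ingestion.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (GENERATION_CLASSES, GenerationSchedule, MeanTrajectory,
                    ModelValidationError, _check, schedule_from_config)
from .synth import HOURS_PER_DAY, CFSEDataset, ExperimentDesign

__all__ = [
    "CountsParseError",
    "RunConfig",
    "read_counts",
    "write_counts",
    "load_config",
    "trajectory_frame",
    "write_csv_atomic",
]


class CountsParseError(ValueError):
    """A counts CSV violates the dataset contract (reported with line numbers)."""


def _offending_lines(mask: pd.Series) -> list[int]:
    # +2: one for the header, one for 1-based numbering
    return [int(i) + 2 for i in np.flatnonzero(mask.to_numpy())]


def read_counts(path) -> CFSEDataset:
    """Read a generation-count table into a :class:`~erlangcell.synth.CFSEDataset`.

    Accepts ``time_h`` (hours) or ``time_d`` (days, converted to hours).
    Malformed rows — unknown class labels, negative or non-integer counts —
    raise :class:`CountsParseError` naming the offending line numbers.
    """
    df = pd.read_csv(path, dtype={"generation_class": str})
    if "time_d" in df.columns and "time_h" not in df.columns:
        df["time_h"] = df.pop("time_d").astype(float) * HOURS_PER_DAY
    required = ["time_h", "replicate_id", "generation_class", "cell_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CountsParseError(f"{path}: missing columns {missing}")
    bad_class = ~df["generation_class"].isin(GENERATION_CLASSES)
    if bad_class.any():
        raise CountsParseError(
            f"{path}: unknown generation class on lines {_offending_lines(bad_class)} "
            f"(allowed: {list(GENERATION_CLASSES)})")
    counts = pd.to_numeric(df["cell_count"], errors="coerce")
    bad_count = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad_count.any():
        raise CountsParseError(
            f"{path}: invalid cell_count on lines {_offending_lines(bad_count)} "
            "(must be a nonnegative integer)")
    df["cell_count"] = counts.astype(int)
    try:
        return CFSEDataset(frame=df[required])
    except ModelValidationError as exc:
        raise CountsParseError(f"{path}: {exc}") from exc


def write_counts(dataset: CFSEDataset, path) -> None:
    """Write a dataset in the repository's counts dialect (atomic)."""
    write_csv_atomic(dataset.frame, path)


def write_csv_atomic(frame: pd.DataFrame, path) -> None:
    """Write a CSV via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            frame.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def trajectory_frame(traj: MeanTrajectory) -> pd.DataFrame:
    """Long-format export of a mean trajectory: time_h, generation, stage, mean_count."""
    rows = []
    for g, s in enumerate(traj.block_slices):
        block = traj.values[:, s]
        for j in range(block.shape[1]):
            for ti, t in enumerate(traj.times):
                rows.append((float(t), g, j + 1, float(block[ti, j])))
    return pd.DataFrame(rows, columns=["time_h", "generation", "stage", "mean_count"])


@dataclass(frozen=True)
class RunConfig:
    """Validated YAML run configuration.

    Blocks: ``model`` (see :func:`~erlangcell.model.schedule_from_config`),
    ``design`` (``days``, ``mice_per_day``), ``inference`` (``particles``,
    ``iterations``, ``seed``, ``variant``), ``io`` (paths).  Unknown keys
    anywhere are rejected before any computation.
    """

    schedule: GenerationSchedule
    design: ExperimentDesign
    inference: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        _check(isinstance(cfg, dict), "config must be a mapping")
        unknown = set(cfg) - {"model", "design", "inference", "io"}
        _check(not unknown, f"unknown config blocks: {sorted(unknown)}")
        _check("model" in cfg, "config must contain a 'model' block")
        schedule = schedule_from_config(cfg["model"])
        design_cfg = dict(cfg.get("design", {}))
        unknown = set(design_cfg) - {"days", "mice_per_day"}
        _check(not unknown, f"unknown design keys: {sorted(unknown)}")
        design = ExperimentDesign(
            days=tuple(design_cfg.get("days", ExperimentDesign.days)),
            mice_per_day=(tuple(design_cfg["mice_per_day"])
                          if isinstance(design_cfg.get("mice_per_day"), (list, tuple))
                          else design_cfg.get("mice_per_day", ExperimentDesign.mice_per_day)),
        )
        inf_cfg = dict(cfg.get("inference", {}))
        unknown = set(inf_cfg) - {"particles", "iterations", "seed", "variant"}
        _check(not unknown, f"unknown inference keys: {sorted(unknown)}")
        io_cfg = dict(cfg.get("io", {}))
        return cls(schedule=schedule, design=design, inference=inf_cfg, io=io_cfg)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return RunConfig.from_dict(cfg)
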