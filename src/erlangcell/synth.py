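"""Synthetic CFSE-style generation-count datasets.

Emulates the design of adoptive-transfer proliferation experiments: labelled
T cells are injected into lymphopenic mice, and at each of a handful of
nominal time points (days after transfer) a few mice are sacrificed and
their recovered cells classified into generation classes 0-4 plus a merged
"5+" class by CFSE dilution.  Each mouse is modelled as one independent
realisation of the MS-G branching process observed at its sacrifice time —
the noise is purely demographic (no measurement-error overlay), every mouse
receives the same initial cell number, and days are converted to hours on
generation.

The default truth parameters are chosen to resemble a rapidly proliferating
CD8 T-cell clonotype under lymphopenia: ``C0 = 4.5e4`` transferred cells,
a slower first division (3 stages at 0.05/h, mean 60 h to first division)
than subsequent ones (5 stages at 0.12/h, mean ~42 h), and a small linear
death slope ``alpha = 2e-4`` per division per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (GENERATION_CLASSES, MERGE_CUTOFF, GenerationSchedule,
                    ModelValidationError, _check, build_schedule)
from .simulate import DEFAULT_CELL_CAP, DEFAULT_G_CAP, _substream_seeds, simulate

__all__ = ["ExperimentDesign", "CFSEDataset", "default_truth", "generate_dataset", "summarize"]

HOURS_PER_DAY = 24.0
#: Standard-deviation floor (cells) applied when computing data summaries:
#: the inference distance divides by sigma, which must never be zero.
SIGMA_FLOOR = 1.0


def default_truth(G_max: int = 15) -> GenerationSchedule:
    """OT-I-like truth schedule used as the generator default."""
    return build_schedule(C0=4.5e4, N0=3, lambda0=0.05, N=5, lam=0.12,
                          alpha=2e-4, G_max=G_max)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design: sacrifice days and mice per time point.

    ``mice_per_day`` is either a fixed integer or an inclusive ``(lo, hi)``
    range from which the per-day replicate count is drawn (seeded) — the
    default ``(3, 7)`` mirrors typical transfer experiments.
    """

    days: tuple = (3, 4, 5, 6, 7, 10, 12, 18)
    mice_per_day: int | tuple = (3, 7)

    def __post_init__(self):
        _check(len(self.days) >= 1 and all(d > 0 for d in self.days),
               "design needs at least one positive sampling day")
        if isinstance(self.mice_per_day, int):
            _check(self.mice_per_day >= 1, "need >= 1 replicate per time point")
        else:
            lo, hi = self.mice_per_day
            _check(1 <= lo <= hi, f"invalid replicate range {self.mice_per_day}")

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(sorted(self.days), dtype=float) * HOURS_PER_DAY

    def replicate_counts(self, rng: np.random.Generator) -> dict[float, int]:
        """Mice per time point (hours), drawn from the configured range."""
        out = {}
        for t in self.times_h:
            if isinstance(self.mice_per_day, int):
                out[t] = self.mice_per_day
            else:
                lo, hi = self.mice_per_day
                out[t] = int(rng.integers(lo, hi + 1))
        return out


@dataclass
class CFSEDataset:
    """Replicate-level generation-class counts plus per-(class, time) summaries.

    ``frame`` columns: ``time_h``, ``replicate_id``, ``generation_class``
    (one of ``'0'..'4', '5+'``), ``cell_count``.  Every (time, replicate)
    pair carries all six classes, zeros included.
    """

    frame: pd.DataFrame
    truth: GenerationSchedule | None = field(default=None, repr=False)

    def __post_init__(self):
        df = self.frame
        required = ["time_h", "replicate_id", "generation_class", "cell_count"]
        missing = [c for c in required if c not in df.columns]
        _check(not missing, f"dataset is missing columns {missing}")
        _check(len(df) > 0, "dataset is empty")
        df = df.copy()
        df["generation_class"] = df["generation_class"].astype(str)
        bad = set(df["generation_class"]) - set(GENERATION_CLASSES)
        _check(not bad, f"unknown generation classes {sorted(bad)}; "
                        f"expected {list(GENERATION_CLASSES)}")
        _check((df["cell_count"] >= 0).all(), "cell counts must be >= 0")
        counts = df.groupby(["time_h", "replicate_id"])["generation_class"].nunique()
        _check((counts == len(GENERATION_CLASSES)).all(),
               "every (time, replicate) must carry all generation classes")
        self.frame = df.sort_values(["time_h", "replicate_id", "generation_class"],
                                    key=_class_sort_key).reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        """Observation times in hours, sorted."""
        return np.sort(self.frame["time_h"].unique())

    def summaries(self) -> pd.DataFrame:
        """Per-(class, time) mean, floored SD and replicate count."""
        return summarize(self)

    def class_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Summary means and SDs as ``(n_times, 6)`` arrays (class-ordered)."""
        s = self.summaries()
        times = self.times
        mean = np.empty((times.size, len(GENERATION_CLASSES)))
        sd = np.empty_like(mean)
        for ci, cls in enumerate(GENERATION_CLASSES):
            sub = s.loc[s["generation_class"] == cls].set_index("time_h")
            mean[:, ci] = sub.loc[times, "mean"].to_numpy()
            sd[:, ci] = sub.loc[times, "sd"].to_numpy()
        return mean, sd


def _class_sort_key(col):
    if col.name == "generation_class":
        order = {c: i for i, c in enumerate(GENERATION_CLASSES)}
        return col.map(order)
    return col


def summarize(dataset: CFSEDataset) -> pd.DataFrame:
    """Sample mean and floored sample SD of counts per (class, time).

    The SD uses ``ddof=1`` over replicates and is floored at
    :data:`SIGMA_FLOOR` (1 cell), which also covers the single-replicate and
    identical-replicate cases where the sample SD is undefined or zero.
    """
    df = dataset.frame
    g = df.groupby(["generation_class", "time_h"], sort=False)["cell_count"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0).clip(lower=SIGMA_FLOOR)
    return out


def generate_dataset(
    schedule: GenerationSchedule | None = None,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    G_cap: int = DEFAULT_G_CAP,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> CFSEDataset:
    """Simulate a full CFSE experiment under a known truth schedule.

    Each mouse is an independent Gillespie realisation of ``schedule``
    observed at its sacrifice time; generations >= 5 are merged into the
    "5+" class.  Identical ``(schedule, design, seed)`` reproduce the
    dataset byte for byte.
    """
    schedule = default_truth() if schedule is None else schedule
    design = ExperimentDesign() if design is None else design
    if schedule.G_max < MERGE_CUTOFF:
        raise ModelValidationError(
            f"truth schedule tracks only {schedule.G_max} generations; "
            f"the merged class needs >= {MERGE_CUTOFF}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    reps = design.replicate_counts(rng)
    n_total = sum(reps.values())
    mouse_seeds = iter(_substream_seeds(seed, n_total))
    rows = []
    for t, n_mice in reps.items():
        for m in range(1, n_mice + 1):
            res = simulate(schedule, [t], int(next(mouse_seeds)),
                           G_cap=G_cap, cell_cap=cell_cap)
            classes = res.merged_classes()[0]
            for cls, count in zip(GENERATION_CLASSES, classes):
                rows.append((t, m, cls, int(count)))
    frame = pd.DataFrame(rows, columns=["time_h", "replicate_id",
                                        "generation_class", "cell_count"])
    return CFSEDataset(frame=frame, truth=schedule)
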