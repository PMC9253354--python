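"""Parameter containers, validation and rate laws for the multi-stage models.

Two model families are represented here:

* The **MS model** (:class:`StageChain`): a cell must traverse ``N`` sequential
  exponential stages, with per-stage advance rate ``lambda^(j)``, before it
  divides; at any stage it may die with rate ``mu``.  When all advance rates
  are equal, the time to division is Erlang(lambda, N) distributed.

* The **MS-G model** (:class:`GenerationSchedule`): the MS model extended with
  generation tracking — the two daughters of a dividing generation-``g`` cell
  enter the first stage of generation ``g + 1``.  Stage counts and rates may
  depend on the generation; the death rate may follow the linear law
  ``mu_g = alpha * g`` (generation-0 cells never die under that law).

All rates are in inverse hours; times are in hours.  Experimental designs are
often quoted in days and are converted on ingestion (see :mod:`.synth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelValidationError",
    "StageChain",
    "GenerationSchedule",
    "MeanTrajectory",
    "death_rate_at",
    "build_schedule",
]

#: Generation classes reported by CFSE-style experiments: generations 0-4 plus
#: the merged "five or more divisions" class.
MERGED_CLASS = "5+"
GENERATION_CLASSES = ("0", "1", "2", "3", "4", MERGED_CLASS)
#: Smallest generation folded into the merged class.
MERGE_CUTOFF = 5


class ModelValidationError(ValueError):
    """Raised when model parameters violate their domain constraints."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ModelValidationError(msg)


def death_rate_at(alpha: float, g: int) -> float:
    """Per-cell death rate of generation ``g`` under the linear death law.

    The death rate is proportional to the number of divisions a cell has
    undergone, ``mu_g = alpha * g``, encoding that cells become more likely to
    die after several rounds of division.  In particular ``mu_0 = 0``.

    Parameters
    ----------
    alpha
        Death-rate slope per division, in inverse hours; ``alpha >= 0``.
    g
        Generation (number of completed divisions); non-negative integer.
    """
    _check(alpha >= 0, f"death-rate slope alpha must be >= 0, got {alpha}")
    _check(float(g) == int(g) and g >= 0, f"generation must be a non-negative integer, got {g}")
    return alpha * int(g)


@dataclass(frozen=True)
class StageChain:
    """MS-model parameters: an N-stage division chain with competing death.

    Attributes
    ----------
    N : int
        Number of stages a cell traverses before dividing (``N >= 1``).
    advance_rates : ndarray
        Per-stage advance rates ``lambda^(j) > 0`` (1/h), length ``N``.
    death_rate : float
        Per-cell death rate ``mu >= 0`` (1/h), identical across stages.
    initial_count : float
        Number of cells ``C0`` in stage 1 at ``t = 0``.
    """

    N: int
    advance_rates: np.ndarray
    death_rate: float
    initial_count: float = 1.0

    def __post_init__(self):
        _check(int(self.N) == self.N and self.N >= 1, f"N must be an integer >= 1, got {self.N}")
        rates = np.atleast_1d(np.asarray(self.advance_rates, dtype=float))
        if rates.size == 1 and self.N > 1:
            rates = np.full(self.N, rates[0])
        _check(rates.shape == (self.N,), f"expected {self.N} advance rates, got shape {rates.shape}")
        _check(np.all(rates > 0), "all advance rates must be > 0")
        _check(self.death_rate >= 0, f"death rate must be >= 0, got {self.death_rate}")
        _check(self.initial_count >= 0, f"initial count must be >= 0, got {self.initial_count}")
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "advance_rates", rates)
        rates.setflags(write=False)

    @classmethod
    def erlang(cls, N: int, lam: float, mu: float, C0: float = 1.0) -> "StageChain":
        """Chain with identical per-stage rate: Erlang(lam, N) division times."""
        return cls(N=N, advance_rates=np.full(int(N), float(lam)), death_rate=mu, initial_count=C0)

    @property
    def is_erlang(self) -> bool:
        """True iff all per-stage advance rates are equal."""
        return bool(np.all(self.advance_rates == self.advance_rates[0]))

    @property
    def rate(self) -> float:
        """The common advance rate lambda; only defined for Erlang chains."""
        if not self.is_erlang:
            raise ModelValidationError("chain has unequal per-stage rates; no single lambda")
        return float(self.advance_rates[0])


@dataclass(frozen=True)
class GenerationSchedule:
    """MS-G model parameters: per-generation stage counts and rates.

    ``stage_counts[g]``, ``birth_rates[g]`` and ``death_rates[g]`` give
    ``N_g``, ``lambda_g`` and ``mu_g`` for generations ``g = 0..G_max``.
    The convenience constructor :func:`build_schedule` produces the two-block
    parameterisation used for CFSE fitting (generation 0 distinct from the
    rest, linear death law).
    """

    stage_counts: np.ndarray
    birth_rates: np.ndarray
    death_rates: np.ndarray
    initial_count: float = 1.0
    #: Death-rate slope when the linear law was used to build the schedule;
    #: ``None`` when death rates were set directly (e.g. constant override).
    alpha: float | None = None

    def __post_init__(self):
        ns = np.atleast_1d(np.asarray(self.stage_counts, dtype=int))
        lams = np.atleast_1d(np.asarray(self.birth_rates, dtype=float))
        mus = np.atleast_1d(np.asarray(self.death_rates, dtype=float))
        _check(ns.ndim == 1 and ns.size >= 1, "stage_counts must be a non-empty vector")
        _check(lams.shape == ns.shape and mus.shape == ns.shape,
               "stage_counts, birth_rates and death_rates must have equal length")
        _check(np.all(ns >= 1), "all stage counts N_g must be >= 1")
        _check(np.all(lams > 0), "all birth rates lambda_g must be > 0")
        _check(np.all(mus >= 0), "all death rates mu_g must be >= 0")
        _check(self.initial_count >= 0, f"initial count must be >= 0, got {self.initial_count}")
        for name, arr in (("stage_counts", ns), ("birth_rates", lams), ("death_rates", mus)):
            object.__setattr__(self, name, arr)
            arr.setflags(write=False)

    @property
    def G_max(self) -> int:
        """Largest explicitly tracked generation."""
        return int(self.stage_counts.size - 1)

    @property
    def total_stages(self) -> int:
        """Dimension of the stacked mean-field system, ``sum_g N_g``."""
        return int(self.stage_counts.sum())

    @property
    def is_uniform(self) -> bool:
        """True iff (N_g, lambda_g, mu_g) are identical across generations."""
        return bool(
            np.all(self.stage_counts == self.stage_counts[0])
            and np.all(self.birth_rates == self.birth_rates[0])
            and np.all(self.death_rates == self.death_rates[0])
        )

    def extended(self, G_max: int) -> "GenerationSchedule":
        """Schedule tracked to a larger ``G_max``, extending the g >= 1 block.

        New generations inherit ``N_g`` and ``lambda_g`` from the last tracked
        generation; death rates continue the linear law when ``alpha`` is set,
        otherwise they repeat the last tracked value.
        """
        if G_max <= self.G_max:
            return self
        extra = G_max - self.G_max
        ns = np.concatenate([self.stage_counts, np.full(extra, self.stage_counts[-1])])
        lams = np.concatenate([self.birth_rates, np.full(extra, self.birth_rates[-1])])
        if self.alpha is not None:
            mus = np.concatenate([self.death_rates,
                                  [death_rate_at(self.alpha, g) for g in range(self.G_max + 1, G_max + 1)]])
        else:
            mus = np.concatenate([self.death_rates, np.full(extra, self.death_rates[-1])])
        return GenerationSchedule(ns, lams, mus, self.initial_count, self.alpha)

    def to_config(self) -> dict:
        """Serialise to the ``model`` YAML block (lossless round-trip)."""
        cfg: dict = {
            "C0": float(self.initial_count),
            "G_max": self.G_max,
            "N0": int(self.stage_counts[0]),
            "lambda0": float(self.birth_rates[0]),
        }
        if self.G_max >= 1:
            cfg["N"] = int(self.stage_counts[1])
            cfg["lambda"] = float(self.birth_rates[1])
        else:
            cfg["N"] = int(self.stage_counts[0])
            cfg["lambda"] = float(self.birth_rates[0])
        if self.alpha is not None:
            cfg["alpha"] = float(self.alpha)
        else:
            cfg["alpha"] = 0.0
            cfg["mu_constant"] = float(self.death_rates[0])
        # Irregular schedules fall outside the two-block config; refuse to
        # pretend otherwise.
        round_trip = schedule_from_config(cfg)
        if not (np.array_equal(round_trip.stage_counts, self.stage_counts)
                and np.array_equal(round_trip.birth_rates, self.birth_rates)
                and np.allclose(round_trip.death_rates, self.death_rates, rtol=0, atol=0)):
            raise ModelValidationError(
                "schedule is not expressible in the (N0, lambda0, N, lambda, alpha) config form")
        return cfg


def build_schedule(
    C0: float,
    N0: int,
    lambda0: float,
    N: int,
    lam: float,
    alpha: float,
    G_max: int,
    mu_constant: float | None = None,
    for_merged_classes: bool = True,
) -> GenerationSchedule:
    """Two-block MS-G schedule used throughout the CFSE case study.

    Generation 0 has ``N0`` stages and birth rate ``lambda0`` (cells must
    first activate before dividing, so its Erlang clock may differ);
    generations ``1..G_max`` share ``N`` stages and birth rate ``lam``.
    Death follows the linear law ``mu_g = alpha * g`` unless ``mu_constant``
    is given, in which case every generation dies at that constant rate (the
    regime in which the MS-G model collapses exactly onto the MS model).

    With ``for_merged_classes=True`` (the default) the schedule must track at
    least generation 5 so that the merged "5+" observation class is
    representable.
    """
    _check(int(G_max) == G_max and G_max >= 0, f"G_max must be a non-negative integer, got {G_max}")
    G_max = int(G_max)
    if for_merged_classes:
        _check(G_max >= MERGE_CUTOFF,
               f"G_max={G_max} cannot represent the merged '{MERGED_CLASS}' class; need >= {MERGE_CUTOFF}")
    ns = np.array([int(N0)] + [int(N)] * G_max)
    lams = np.array([float(lambda0)] + [float(lam)] * G_max)
    if mu_constant is not None:
        _check(mu_constant >= 0, f"mu_constant must be >= 0, got {mu_constant}")
        mus = np.full(G_max + 1, float(mu_constant))
        stored_alpha = None
    else:
        mus = np.array([death_rate_at(alpha, g) for g in range(G_max + 1)])
        stored_alpha = float(alpha)
    return GenerationSchedule(ns, lams, mus, float(C0), stored_alpha)


def schedule_from_config(model_cfg: dict) -> GenerationSchedule:
    """Build a schedule from the ``model`` block of a YAML config."""
    allowed = {"C0", "N0", "lambda0", "N", "lambda", "alpha", "G_max", "mu_constant"}
    unknown = set(model_cfg) - allowed
    _check(not unknown, f"unknown model config keys: {sorted(unknown)}")
    required = {"C0", "N0", "lambda0", "N", "lambda", "alpha", "G_max"}
    missing = required - set(model_cfg)
    _check(not missing, f"missing model config keys: {sorted(missing)}")
    return build_schedule(
        C0=model_cfg["C0"],
        N0=model_cfg["N0"],
        lambda0=model_cfg["lambda0"],
        N=model_cfg["N"],
        lam=model_cfg["lambda"],
        alpha=model_cfg["alpha"],
        G_max=model_cfg["G_max"],
        mu_constant=model_cfg.get("mu_constant"),
        for_merged_classes=False,
    )


@dataclass
class MeanTrajectory:
    """Expected compartment counts ``M^g_j(t)`` on a time grid.

    ``values`` has shape ``(len(times), total_stages)``, with compartments
    stacked generation-major: generation 0 stages 1..N_0 first, then
    generation 1, and so on (stage indices are 1-based, generations 0-based).
    ``provenance`` records which engine produced the values:
    ``"closed-form"``, ``"matrix-exponential"``, ``"simulation-ensemble"`` or
    ``"cyton"``.
    """

    times: np.ndarray
    values: np.ndarray
    schedule: GenerationSchedule
    provenance: str = "matrix-exponential"
    #: Tolerance for clipping solver round-off below zero.
    NEG_TOL: float = field(default=1e-9, repr=False)

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        v = np.asarray(self.values, dtype=float)
        _check(t.ndim == 1 and np.all(np.diff(t) > 0) if t.size > 1 else t.ndim == 1,
               "times must be a strictly increasing 1-D grid")
        _check(v.shape == (t.size, self.schedule.total_stages),
               f"values shape {v.shape} does not match (n_times, total_stages)="
               f"({t.size}, {self.schedule.total_stages})")
        scale = max(abs(v).max(initial=0.0), self.schedule.initial_count, 1.0)
        _check(v.min(initial=0.0) >= -self.NEG_TOL * scale,
               f"trajectory has negative components below tolerance: min={v.min():g}")
        self.times = t
        self.values = np.clip(v, 0.0, None)

    @property
    def block_slices(self) -> list[slice]:
        """Column slice of each generation within ``values``."""
        offsets = np.concatenate([[0], np.cumsum(self.schedule.stage_counts)])
        return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]

    def generation_totals(self) -> np.ndarray:
        """Per-generation means ``M^g(t)``, shape ``(n_times, G_max+1)``."""
        return np.stack([self.values[:, s].sum(axis=1) for s in self.block_slices], axis=1)

    def stage_totals(self) -> np.ndarray:
        """Per-stage means ``M_j(t)`` summed over generations.

        Only meaningful when all generations share the same stage count.
        """
        ns = self.schedule.stage_counts
        _check(np.all(ns == ns[0]), "stage totals require a common stage count across generations")
        out = np.zeros((self.times.size, int(ns[0])))
        for s in self.block_slices:
            out += self.values[:, s]
        return out

    def total(self) -> np.ndarray:
        """Grand total ``M(t)`` over all compartments."""
        return self.values.sum(axis=1)
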