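"""Exact stochastic simulation of the MS-G branching process.

Cells are exchangeable within a (generation, stage) compartment, so the exact
Gillespie algorithm can race compartment-aggregated hazards instead of
per-cell clocks: a compartment holding ``n`` cells of generation ``g``
contributes hazard ``n * lambda_g`` for advancing (division when the cell is
in its last stage, sending two daughters to stage 1 of generation ``g + 1``)
and ``n * mu_g`` for death.  This preserves exactness while making runs with
tens of thousands of founder cells tractable.

Generations extend dynamically as divisions occur; the merged "5+"
observation class exists only at observation time, not in the dynamics.  The
event loop compiles with numba when available and otherwise runs as plain
Python (same code, same random sequence — both use the Mersenne-Twister
``np.random`` stream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenerationSchedule, StageChain, ModelValidationError, _check
from .model import MERGE_CUTOFF
from .ode import merge_tail_class

__all__ = [
    "CappedRunError",
    "SimulationResult",
    "ExtinctionEstimate",
    "simulate",
    "simulate_ensemble",
    "estimate_extinction",
]

#: Practical ceiling on the number of generations tracked by one realisation.
#: The process itself has no ceiling; reaching this many divisions within a
#: run is flagged as an error rather than silently truncated.
DEFAULT_G_CAP = 256
#: Default runaway-growth guard (total cells).
DEFAULT_CELL_CAP = 1_000_000_000

_STATUS_OK = 0
_STATUS_CAPPED = 1
_STATUS_ESCAPED = 2
_STATUS_GEN_CEILING = 3


class CappedRunError(RuntimeError):
    """A realisation exceeded the configured cell-count cap."""


def _gillespie_core(seed, n_stages, birth, death, init_count, sample_times,
                    cell_cap, escape):
    """Event loop shared by the numba and pure-Python paths.

    Returns ``(sampled_counts, status, final_total)`` where ``sampled_counts``
    has shape ``(len(sample_times), G_cap, N_max)`` and records the state by
    last-event carry-forward.  ``escape > 0`` stops a run early (flagged
    ESCAPED) once the population reaches that size — used by extinction
    estimation to declare survival without simulating unbounded growth.
    """
    np.random.seed(seed)
    G_cap = n_stages.shape[0]
    N_max = 0
    for g in range(G_cap):
        if n_stages[g] > N_max:
            N_max = n_stages[g]
    counts = np.zeros((G_cap, N_max), dtype=np.int64)
    gen_tot = np.zeros(G_cap, dtype=np.int64)
    counts[0, 0] = init_count
    gen_tot[0] = init_count
    total = init_count
    out = np.zeros((sample_times.shape[0], G_cap, N_max), dtype=np.int64)
    n_samples = sample_times.shape[0]
    t = 0.0
    si = 0
    g_lo = 0
    g_hi = 0
    status = _STATUS_OK
    # total hazard, maintained incrementally and refreshed periodically to
    # keep floating-point drift far below the Monte-Carlo noise floor
    rate = (birth[0] + death[0]) * gen_tot[0]
    events_since_refresh = 0
    while True:
        while g_lo <= g_hi and gen_tot[g_lo] == 0:
            g_lo += 1
        if events_since_refresh >= 1 << 22:
            rate = 0.0
            for g in range(g_lo, g_hi + 1):
                rate += (birth[g] + death[g]) * gen_tot[g]
            events_since_refresh = 0
        if rate <= 0.0 or total == 0:
            # extinct: state is frozen at zero for all remaining samples
            while si < n_samples:
                out[si] = counts
                si += 1
            break
        dt = -np.log(np.random.random()) / rate
        while si < n_samples and sample_times[si] < t + dt:
            out[si] = counts
            si += 1
        if si >= n_samples:
            break
        t += dt
        events_since_refresh += 1
        # one uniform picks (generation, death-vs-advance); a second the stage
        u = np.random.random() * rate
        g = g_hi
        is_death = False
        for gg in range(g_lo, g_hi + 1):
            r_part = death[gg] * gen_tot[gg]
            if u < r_part:
                g = gg
                is_death = True
                break
            u -= r_part
            r_part = birth[gg] * gen_tot[gg]
            if u < r_part:
                g = gg
                break
            u -= r_part
        u2 = np.random.random() * gen_tot[g]
        j = n_stages[g] - 1
        for jj in range(n_stages[g]):
            if u2 < counts[g, jj]:
                j = jj
                break
            u2 -= counts[g, jj]
        if is_death:
            counts[g, j] -= 1
            gen_tot[g] -= 1
            total -= 1
            rate -= birth[g] + death[g]
        elif j < n_stages[g] - 1:
            counts[g, j] -= 1
            counts[g, j + 1] += 1
        else:
            if g + 1 >= G_cap:
                status = _STATUS_GEN_CEILING
                break
            counts[g, j] -= 1
            gen_tot[g] -= 1
            counts[g + 1, 0] += 2
            gen_tot[g + 1] += 2
            total += 1
            rate += 2.0 * (birth[g + 1] + death[g + 1]) - (birth[g] + death[g])
            if g + 1 > g_hi:
                g_hi = g + 1
            if total >= cell_cap:
                status = _STATUS_CAPPED
                break
            if escape > 0 and total >= escape:
                status = _STATUS_ESCAPED
                break
    return out, status, total


try:  # optional acceleration; the plain function runs the same algorithm
    import numba

    _gillespie = numba.njit(cache=True)(_gillespie_core)
except ImportError:  # pragma: no cover - exercised only without numba
    _gillespie = _gillespie_core


def _rate_arrays(schedule: GenerationSchedule, G_cap: int):
    ext = schedule.extended(G_cap - 1)
    return (ext.stage_counts.astype(np.int64),
            ext.birth_rates.astype(np.float64),
            ext.death_rates.astype(np.float64))


@dataclass
class SimulationResult:
    """States of one realisation recorded at the requested sample times.

    ``counts`` has shape ``(n_samples, G+1, N_max)`` with ``G`` the largest
    generation reached; compartments beyond a generation's stage count are
    structural zeros.
    """

    times: np.ndarray
    counts: np.ndarray
    schedule: GenerationSchedule
    seed: int

    def generation_totals(self) -> np.ndarray:
        """Per-generation cell counts, shape ``(n_samples, G+1)``."""
        return self.counts.sum(axis=2)

    def merged_classes(self, cutoff: int = MERGE_CUTOFF) -> np.ndarray:
        """Counts in the observation classes ``{0..cutoff-1, cutoff+}``."""
        return merge_tail_class(self.generation_totals(), cutoff)


def simulate(
    schedule: GenerationSchedule,
    sample_times,
    seed: int,
    initial_count: int | None = None,
    G_cap: int = DEFAULT_G_CAP,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> SimulationResult:
    """Run one exact realisation and record it at ``sample_times``.

    Parameters
    ----------
    schedule
        MS-G parameterisation; generations beyond ``schedule.G_max`` inherit
        the last tracked generation's stage count and birth rate, with the
        death law extended accordingly.
    sample_times
        Nondecreasing observation times (hours).
    seed
        Seed for the realisation (below ``2**31``).
    initial_count
        Founder cells in stage 1 of generation 0; defaults to the schedule's
        ``C0`` (rounded to an integer).

    Raises
    ------
    CappedRunError
        If the population exceeds ``cell_cap`` (reported, never silently
        truncated).
    """
    t_arr = np.asarray(sample_times, dtype=float)
    _check(t_arr.ndim == 1 and t_arr.size >= 1 and np.all(np.diff(t_arr) >= 0)
           and np.all(t_arr >= 0), "sample times must be nondecreasing and >= 0")
    C0 = int(round(schedule.initial_count)) if initial_count is None else int(initial_count)
    _check(C0 >= 1, "need at least one founder cell")
    ns, birth, death = _rate_arrays(schedule, G_cap)
    out, status, _ = _gillespie(int(seed) % (2**31), ns, birth, death,
                                np.int64(C0), t_arr, np.int64(cell_cap), np.int64(0))
    if status == _STATUS_CAPPED:
        raise CappedRunError(
            f"realisation exceeded the cell-count cap ({cell_cap}); "
            "raise cell_cap or shorten the horizon")
    if status == _STATUS_GEN_CEILING:
        raise RuntimeError(f"realisation exceeded {G_cap} generations; raise G_cap")
    g_active = int(np.max(np.nonzero(out.sum(axis=(0, 2)))[0])) if out.any() else 0
    g_keep = max(g_active, schedule.G_max)
    return SimulationResult(times=t_arr, counts=out[:, :g_keep + 1, :],
                            schedule=schedule, seed=int(seed))


def _substream_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one master seed."""
    return (np.random.SeedSequence(seed).generate_state(n) % (2**31)).astype(np.int64)


def simulate_ensemble(
    schedule: GenerationSchedule,
    sample_times,
    n_replicates: int,
    seed: int,
    initial_count: int | None = None,
    G_cap: int = DEFAULT_G_CAP,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> list[SimulationResult]:
    """Independent replicates with deterministically derived substream seeds."""
    seeds = _substream_seeds(seed, n_replicates)
    return [
        simulate(schedule, sample_times, int(s), initial_count=initial_count,
                 G_cap=G_cap, cell_cap=cell_cap)
        for s in seeds
    ]


@dataclass(frozen=True)
class ExtinctionEstimate:
    """Binomial extinction frequency from replicate founder-cell runs."""

    frequency: float
    std_error: float
    n_extinct: int
    n_replicates: int


def estimate_extinction(
    chain: StageChain,
    n_replicates: int,
    t_end: float,
    seed: int,
    escape_threshold: int = 1000,
    G_cap: int = DEFAULT_G_CAP,
    founders: int = 1,
) -> ExtinctionEstimate:
    """Monte-Carlo estimate of the ultimate extinction probability.

    Each replicate starts from ``founders`` cells in stage 1 (by branching
    independence the ``m``-founder probability is ``p_1^m``).  A run
    counts as extinct when its population reaches zero before ``t_end``; runs
    that hit ``escape_threshold`` cells are declared survivors early (in a
    supercritical regime the probability that such a population later dies
    out is negligible), and runs still alive at ``t_end`` count as
    non-extinct.
    """
    if not chain.is_erlang:
        raise ModelValidationError(
            "extinction simulation requires equal per-stage rates (Erlang chain)")
    schedule = GenerationSchedule(
        stage_counts=np.array([chain.N]),
        birth_rates=np.array([chain.rate]),
        death_rates=np.array([chain.death_rate]),
        initial_count=1,
    )
    ns, birth, death = _rate_arrays(schedule, G_cap)
    t_arr = np.array([float(t_end)])
    seeds = _substream_seeds(seed, n_replicates)
    n_extinct = 0
    for s in seeds:
        out, status, total = _gillespie(int(s), ns, birth, death, np.int64(founders),
                                        t_arr, np.int64(DEFAULT_CELL_CAP),
                                        np.int64(escape_threshold))
        if status == _STATUS_GEN_CEILING:
            raise RuntimeError(f"extinction run exceeded {G_cap} generations; raise G_cap")
        if status == _STATUS_OK and total == 0:
            n_extinct += 1
    freq = n_extinct / n_replicates
    se = float(np.sqrt(freq * (1.0 - freq) / n_replicates))
    return ExtinctionEstimate(frequency=freq, std_error=se,
                              n_extinct=n_extinct, n_replicates=n_replicates)
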