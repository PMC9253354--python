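"""Mean-field solver for arbitrary MS-G parameterisations.

The stacked mean equations are linear, ``dM/dt = A M``, where the coefficient
matrix ``A`` is block lower-bidiagonal: each generation's diagonal block has
``-(lambda_g + mu_g)`` on the diagonal and ``lambda_g`` on its subdiagonal,
and the only coupling between generations is the division flux ``2
lambda_{g-1}`` from the last stage of generation ``g-1`` into the first stage
of generation ``g``.  In the generation-major stage ordering the whole matrix
is therefore *lower bidiagonal*, which the default solver exploits: the
action of ``exp(A t)`` is evaluated by uniformisation (a nonnegative Taylor
series in ``I + A/theta``), giving machine-accuracy results in O(dim) per
term with no cancellation.  A dense scaling-and-squaring route
(``scipy.linalg.expm``) is kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import GenerationSchedule, MeanTrajectory, ModelValidationError, _check
from .model import MERGE_CUTOFF

__all__ = [
    "GeneratorMatrix",
    "SolverFailureError",
    "build_generator",
    "solve_mean",
    "collapse_generations",
    "merge_tail_class",
]

#: Default largest tracked generation for inference runs; expanded
#: automatically whenever the terminal generation holds a non-negligible
#: share of the population (see :func:`erlangcell.inference.predict_classes`).
DEFAULT_G_MAX = 15
#: Maximum share of the population allowed in the terminal generation before
#: the truncation is considered unsafe.
TRUNCATION_SHARE = 1e-6
#: Largest theta * dt handled in one uniformisation leg (keeps the Poisson
#: weights inside normal double range).
_MAX_LEG = 500.0


class SolverFailureError(RuntimeError):
    """Mean-field solve produced non-finite values (population overflow)."""


@dataclass(frozen=True)
class GeneratorMatrix:
    """Bidiagonal representation of the MS-G coefficient matrix.

    ``diag[i]`` holds ``-(lambda_g + mu_g)`` for compartment ``i`` and
    ``sub[i]`` the entry at ``(i+1, i)``: ``lambda_g`` within a generation,
    ``2 lambda_{g-1}`` across the generation boundary.
    """

    diag: np.ndarray
    sub: np.ndarray
    block_slices: tuple[slice, ...]

    @property
    def dim(self) -> int:
        return self.diag.size

    def dense(self) -> np.ndarray:
        A = np.diag(self.diag)
        idx = np.arange(self.dim - 1)
        A[idx + 1, idx] = self.sub
        return A

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.diag * v
        out[1:] += self.sub * v[:-1]
        return out


def build_generator(schedule: GenerationSchedule) -> GeneratorMatrix:
    """Assemble the coefficient matrix for a schedule.

    The dimension is ``sum_g N_g``; stages are stacked generation-major.
    """
    ns = schedule.stage_counts
    diag = np.concatenate([
        np.full(int(n), -(lam + mu))
        for n, lam, mu in zip(ns, schedule.birth_rates, schedule.death_rates)
    ])
    sub = np.empty(diag.size - 1) if diag.size > 1 else np.empty(0)
    offsets = np.concatenate([[0], np.cumsum(ns)])
    slices = tuple(slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:]))
    for g, s in enumerate(slices):
        lam = schedule.birth_rates[g]
        if s.stop - s.start > 1:
            sub[s.start:s.stop - 1] = lam          # advance within generation
        if g + 1 <= schedule.G_max:
            sub[s.stop - 1] = 2.0 * lam            # division into next generation
    return GeneratorMatrix(diag=diag, sub=sub, block_slices=slices)


def _uniformization_core(diag, sub, v0, times, max_leg):
    """Loop form of the uniformisation recurrence (numba-compiled when available).

    Propagates ``v`` through each inter-observation leg, accumulating
    ``exp(-m) sum_k m^k/k! B^k v`` with ``B = I + A/theta``; all terms are
    nonnegative so there is no cancellation.  Returns (values, ok_flag).
    """
    n = diag.shape[0]
    theta = 0.0
    for i in range(n):
        if -diag[i] > theta:
            theta = -diag[i]
    out = np.empty((times.shape[0], n))
    v = v0.copy()
    term = np.empty(n)
    acc = np.empty(n)
    t_prev = 0.0
    for ti in range(times.shape[0]):
        dt = times[ti] - t_prev
        while dt > 0.0 and theta > 0.0:
            leg = dt if dt * theta <= max_leg else max_leg / theta
            m = theta * leg
            w = np.exp(-m)
            acc_sum = 0.0
            term_sum = 0.0
            for i in range(n):
                term[i] = v[i]
                acc[i] = w * v[i]
                acc_sum += acc[i]
                term_sum += abs(v[i])
            k_max = int(m + 15.0 * np.sqrt(m + 25.0) + 40.0)
            for k in range(1, k_max + 1):
                # in-place B @ term, sweeping high-to-low so term[i-1] is unread
                for i in range(n - 1, 0, -1):
                    term[i] += (diag[i] * term[i] + sub[i - 1] * term[i - 1]) / theta
                term[0] += diag[0] * term[0] / theta
                w *= m / k
                term_sum = 0.0
                for i in range(n):
                    acc[i] += w * term[i]
                    acc_sum += w * term[i]
                    term_sum += abs(term[i])
                if k > m and w * term_sum < 1e-16 * acc_sum:
                    break
            for i in range(n):
                v[i] = acc[i]
            if not np.isfinite(acc_sum):
                return out, False
            dt -= leg
        t_prev = times[ti]
        for i in range(n):
            out[ti, i] = v[i]
    return out, True


try:  # optional acceleration; identical algorithm either way
    import numba

    _uniformization = numba.njit(cache=True)(_uniformization_core)
except ImportError:  # pragma: no cover
    _uniformization = None


def _expm_action_numpy(gen: GeneratorMatrix, v0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Vectorised uniformisation (fallback when numba is unavailable)."""
    theta = float(np.max(-gen.diag))
    out = np.empty((times.size, gen.dim))
    v = v0.astype(float).copy()
    t_prev = 0.0
    for i, t in enumerate(times):
        dt = t - t_prev
        while dt > 0 and theta > 0:
            leg = min(dt, _MAX_LEG / theta)
            m = theta * leg
            acc = np.zeros_like(v)
            term = v.copy()
            w = np.exp(-m)
            acc += w * term
            k_max = int(m + 15.0 * np.sqrt(m + 25.0) + 40)
            for k in range(1, k_max + 1):
                term = term + gen.matvec(term) / theta     # B term
                w *= m / k
                acc += w * term
                if k > m and w * np.abs(term).sum() < 1e-16 * max(np.abs(acc).sum(), 1e-300):
                    break
            v = acc
            dt -= leg
            if not np.all(np.isfinite(v)):
                raise SolverFailureError(
                    f"non-finite mean trajectory at t={t - dt:g} h "
                    f"(population overflow; theta={theta:g})")
        t_prev = t
        out[i] = v
    return out


def _expm_action(gen: GeneratorMatrix, v0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Evaluate ``exp(A t_k) v0`` on an increasing grid by uniformisation."""
    if _uniformization is None:
        return _expm_action_numpy(gen, v0, times)
    values, ok = _uniformization(gen.diag, gen.sub, v0.astype(float),
                                 times.astype(float), _MAX_LEG)
    if not ok:
        raise SolverFailureError(
            "non-finite mean trajectory (population overflow in uniformisation)")
    return values


def solve_mean(
    schedule: GenerationSchedule,
    times,
    n0=None,
    method: str = "uniformization",
) -> MeanTrajectory:
    """Mean compartment counts ``M(t) = exp(A t) n0`` on a time grid.

    Parameters
    ----------
    schedule
        MS-G parameterisation (defines ``A``).
    times
        Strictly increasing grid of observation times (hours), ``>= 0``.
    n0
        Initial compartment vector (length ``sum_g N_g``, nonnegative).
        Default: ``C0`` cells in stage 1 of generation 0.
    method
        ``"uniformization"`` (default; exact bidiagonal action) or
        ``"expm"`` (dense scipy scaling-and-squaring, cross-check route).
    """
    gen = build_generator(schedule)
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    _check(np.all(t_arr >= 0) and (t_arr.size < 2 or np.all(np.diff(t_arr) > 0)),
           "times must be nonnegative and strictly increasing")
    if n0 is None:
        n0 = np.zeros(gen.dim)
        n0[0] = schedule.initial_count
    else:
        n0 = np.asarray(n0, dtype=float)
        _check(n0.shape == (gen.dim,), f"n0 must have length {gen.dim}, got {n0.shape}")
        _check(np.all(n0 >= 0), "initial compartment counts must be >= 0")
    if method == "uniformization":
        values = _expm_action(gen, n0, t_arr)
    elif method == "expm":
        values = np.empty((t_arr.size, gen.dim))
        for i, t in enumerate(t_arr):
            values[i] = scipy.linalg.expm(gen.dense() * t) @ n0
        if not np.all(np.isfinite(values)):
            raise SolverFailureError("dense expm produced non-finite values")
    else:
        raise ValueError(f"unknown method {method!r}")
    return MeanTrajectory(times=t_arr, values=values, schedule=schedule,
                          provenance="matrix-exponential")


def collapse_generations(traj: MeanTrajectory) -> np.ndarray:
    """Per-generation totals ``M^g(t) = sum_j M^g_j(t)``.

    Returns an array of shape ``(n_times, G_max + 1)``; summing it over
    generations reproduces the grand stage-sum exactly.
    """
    return traj.generation_totals()


def merge_tail_class(generation_totals: np.ndarray, cutoff: int = MERGE_CUTOFF) -> np.ndarray:
    """Fold generations ``>= cutoff`` into one merged class.

    CFSE quantification is unreliable once the dye has halved five times, so
    observations report classes ``{0, 1, 2, 3, 4, "5+"}``.  Input is the
    ``(n_times, G_max + 1)`` per-generation array; output has ``cutoff + 1``
    columns, the last being the merged class.  Totals are preserved.
    """
    gt = np.atleast_2d(np.asarray(generation_totals, dtype=float))
    G_max = gt.shape[1] - 1
    if G_max < cutoff:
        raise ModelValidationError(
            f"G_max={G_max} < cutoff={cutoff}: merged class not representable")
    merged = np.empty((gt.shape[0], cutoff + 1))
    merged[:, :cutoff] = gt[:, :cutoff]
    merged[:, cutoff] = gt[:, cutoff:].sum(axis=1)
    return merged


def terminal_share(traj: MeanTrajectory) -> float:
    """Share of the population in the last tracked generation at ``t_end``.

    Used as the truncation-error control: solves are repeated with a larger
    ``G_max`` whenever this exceeds :data:`TRUNCATION_SHARE`.
    """
    gt = traj.generation_totals()[-1]
    total = gt.sum()
    return float(gt[-1] / total) if total > 0 else 0.0
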