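"""Closed-form results for the Erlang multi-stage model.

For the MS model with a common advance rate ``lambda`` (Erlang(lambda, N)
division times) and death rate ``mu``, the mean compartment counts admit an
exact solution as a sum over the N-th roots of unity,

    M_j(t) = C0 * 2^{(1-j)/N} / N * e^{-mu t}
             * sum_k z^{(1-j)k} exp((2^{1/N} z^k - 1) lambda t),

with ``z = exp(2 pi i / N)``.  This module evaluates those sums, the ultimate
extinction probabilities from the first-step recursion, the late-time growth
exponent ``sigma_N = 2^{1/N} - 1``, the stationary stage occupancies, and the
closed forms for the generation-tracking (MS-G) variant when parameters are
shared across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .model import ModelValidationError, StageChain, _check

__all__ = [
    "ExtinctionResult",
    "UnsupportedParameterisationError",
    "DegenerateRatesError",
    "ms_mean_stages",
    "ms_mean_total",
    "growth_exponent",
    "extinction_probabilities",
    "stationary_stage_fractions",
    "msg_uniform_mean",
    "msg_exponential_mean",
]

#: Allowed imaginary residue (relative to C0) when collapsing the provably
#: real root-of-unity sums to their real part.
IMAG_TOL = 1e-9
#: Residual allowed when checking fixed-point identities (extinction
#: recursion, stationary occupancies).
FIXED_POINT_TOL = 1e-12


class UnsupportedParameterisationError(ModelValidationError):
    """Closed form does not cover this parameterisation; use the ODE engine."""


class DegenerateRatesError(ModelValidationError):
    """Coincident exponential rates break the partial-fraction closed form."""


def _require_erlang(chain: StageChain) -> tuple[int, float, float, float]:
    if not chain.is_erlang:
        raise UnsupportedParameterisationError(
            "closed forms require equal per-stage rates (Erlang chain); "
            "use erlangcell.ode.solve_mean for general chains")
    return chain.N, chain.rate, chain.death_rate, chain.initial_count


def _root_of_unity_sum(N: int, lam: float, t: np.ndarray, exponents: np.ndarray,
                       weights: np.ndarray | None = None) -> np.ndarray:
    """Evaluate sum_k w_k z^{e m k} style sums shared by the mean formulas.

    Returns, for each (row, time), ``sum_k coeff[row, k] * exp((2^{1/N} z^k - 1)
    lambda t)`` where ``coeff[row, k] = z^{exponents[row] * k}`` optionally
    multiplied by ``weights[k]``.
    """
    k = np.arange(N)
    z = np.exp(2j * np.pi / N)
    growth = (2.0 ** (1.0 / N)) * z**k - 1.0          # shape (N,)
    coeff = z ** (np.asarray(exponents)[:, None] * k[None, :])
    if weights is not None:
        coeff = coeff * weights[None, :]
    # (rows, k, t) summed over k
    expo = np.exp(growth[None, :, None] * lam * t[None, None, :])
    return (coeff[:, :, None] * expo).sum(axis=1)


def _real_part(values: np.ndarray, scale: float) -> np.ndarray:
    resid = np.abs(values.imag).max(initial=0.0)
    if resid >= IMAG_TOL * max(scale, 1.0):
        raise FloatingPointError(
            f"imaginary residue {resid:g} exceeds tolerance for scale {scale:g}")
    return values.real


def ms_mean_stages(chain: StageChain, t) -> np.ndarray:
    """Mean number of cells in each stage, ``M_j(t)``, for an Erlang chain.

    Parameters
    ----------
    chain
        Erlang :class:`~erlangcell.model.StageChain` (equal per-stage rates).
        All ``C0`` founder cells sit in stage 1 at ``t = 0``.
    t
        Time (hours), scalar or 1-D array, ``t >= 0``.

    Returns
    -------
    ndarray
        Shape ``(N,)`` for scalar ``t``, else ``(N, len(t))``.
    """
    N, lam, mu, C0 = _require_erlang(chain)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check(np.all(t_arr >= 0), "time must be >= 0")
    j = np.arange(1, N + 1)
    sums = _root_of_unity_sum(N, lam, t_arr, exponents=(1 - j))
    vals = (C0 * 2.0 ** ((1.0 - j[:, None]) / N) / N) * np.exp(-mu * t_arr)[None, :] * sums
    out = np.clip(_real_part(vals, scale=C0 * max(1.0, np.exp((2 ** (1 / N) - 1) * lam * t_arr.max()))), 0.0, None)
    return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out


def ms_mean_total(chain: StageChain, t) -> np.ndarray | float:
    """Expected total population ``M(t) = sum_j M_j(t)`` for an Erlang chain."""
    N, lam, mu, C0 = _require_erlang(chain)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check(np.all(t_arr >= 0), "time must be >= 0")
    k = np.arange(N)
    z = np.exp(2j * np.pi / N)
    weights = z**k / ((2.0 ** (1.0 / N)) * z**k - 1.0)
    sums = _root_of_unity_sum(N, lam, t_arr, exponents=np.array([0]), weights=weights)[0]
    vals = C0 * (2.0 ** (1.0 / N)) / (2 * N) * np.exp(-mu * t_arr) * sums
    out = np.clip(_real_part(vals, scale=C0 * max(1.0, np.exp((2 ** (1 / N) - 1) * lam * t_arr.max()))), 0.0, None)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def growth_exponent(N: int) -> float:
    """Late-time growth exponent ``sigma_N = 2^{1/N} - 1``.

    The asymptotic per-capita growth rate of the Erlang chain is
    ``sigma_N * lambda - mu``; note ``N * sigma_N -> log 2`` as N grows, so
    many short stages are *not* equivalent to one slow exponential step.
    """
    _check(int(N) == N and N >= 1, f"N must be an integer >= 1, got {N}")
    return float(np.expm1(np.log(2.0) / N))


@dataclass(frozen=True)
class ExtinctionResult:
    """Ultimate extinction probabilities of the MS model from one founder.

    ``p[j-1]`` is the probability that a population founded by a single cell
    in stage ``j`` eventually dies out.  ``certain`` flags the regime
    ``mu >= (2^{1/N} - 1) lambda`` in which extinction has probability one.
    ``r = mu / (mu + lambda)`` is the single-event death probability.
    """

    p: np.ndarray
    certain: bool
    r: float

    @property
    def p1(self) -> float:
        return float(self.p[0])


def extinction_probabilities(chain: StageChain) -> ExtinctionResult:
    """Solve the first-step extinction recursion for an Erlang chain.

    The per-stage probabilities satisfy
    ``p_i = mu/(lambda+mu) + lambda/(lambda+mu) p_{i+1}`` for ``i < N`` and
    ``p_N = mu/(lambda+mu) + lambda/(lambda+mu) p_1^2``; the closed-form
    branch gives ``p_1 = (1-r)^{-N} - 1`` in the supercritical regime and
    ``p_1 = 1`` otherwise.  The remaining stages are recovered by unrolling
    the recursion, and the fixed point is verified to ``1e-12``.
    """
    N, lam, mu, _ = _require_erlang(chain)
    _check(lam > 0, "lambda must be > 0")
    r = mu / (mu + lam)
    sigma = growth_exponent(N)
    certain = mu >= sigma * lam
    if certain:
        p = np.ones(N)
    else:
        p = np.empty(N)
        p[0] = (1.0 - r) ** (-N) - 1.0
        for i in range(N - 1):
            # invert p_i = mu/(lam+mu) + lam/(lam+mu) p_{i+1}
            p[i + 1] = ((lam + mu) * p[i] - mu) / lam
        p = np.clip(p, 0.0, 1.0)
        a = mu / (lam + mu)
        b = lam / (lam + mu)
        resid = np.max(np.abs(np.concatenate([
            p[:-1] - (a + b * p[1:]),
            [p[-1] - (a + b * p[0] ** 2)],
        ])))
        if resid >= FIXED_POINT_TOL * max(1.0, (1 - r) ** (-N)):
            raise FloatingPointError(f"extinction recursion residual {resid:g} too large")
    return ExtinctionResult(p=p, certain=bool(certain), r=float(r))


def stationary_stage_fractions(N: int) -> np.ndarray:
    """Late-time stage occupancies ``P*_j = (2^{1/N})^{N-j} (2^{1/N} - 1)``.

    Independent of ``lambda`` and ``mu`` and of the initial stage
    distribution; strictly decreasing in ``j`` and summing to one.
    """
    _check(int(N) == N and N >= 1, f"N must be an integer >= 1, got {N}")
    j = np.arange(1, N + 1)
    c = 2.0 ** (1.0 / N)
    frac = c ** (N - j) * (c - 1.0)
    # fixed-point system: P1 = 2 P_N / (1 + P_N); P_j = P_{j-1} / (1 + P_N)
    pn = frac[-1]
    resid = np.max(np.abs(np.concatenate([
        [frac[0] - 2 * pn / (1 + pn)],
        frac[1:] - frac[:-1] / (1 + pn),
    ])))
    if resid >= FIXED_POINT_TOL:
        raise FloatingPointError(f"stationary occupancy residual {resid:g} too large")
    return frac


def _uniform_g_cut(N: int, lam: float, mu: float, t_max: float, tail: float = 1e-12) -> int:
    """Generation cutoff so the truncated series tail is negligible.

    The compartment means are Poisson-like terms in ``x = 2^{1/N} lambda t``
    with index ``N g + j - 1``; the tail beyond the cutoff is bounded by the
    Poisson tail at ``x``, so the cutoff index is taken at tail mass < 1e-12.
    """
    x = 2.0 ** (1.0 / N) * lam * t_max
    m_star = int(poisson.isf(tail, max(x, 1e-12))) + N
    return max(int(np.ceil((m_star + 1) / N)), 1)


def msg_uniform_mean(N: int, lam: float, mu: float, C0: float, t,
                     G: int | None = None) -> np.ndarray:
    """Mean compartment counts of the MS-G model with shared parameters.

    When every generation has the same ``(N, lambda, mu)``,

        M^g_j(t) = 2^g C0 (lambda t)^{Ng+j-1} e^{-(lambda+mu) t} / (Ng+j-1)!

    evaluated in log space (log-gamma for the factorial) so large indices do
    not overflow.

    Parameters
    ----------
    G
        Largest generation to return.  Default: chosen adaptively so that the
        omitted tail carries less than ``1e-9`` of the total mass.

    Returns
    -------
    ndarray
        Shape ``(G+1, N)`` for scalar ``t``, else ``(G+1, N, len(t))``.
    """
    _check(int(N) == N and N >= 1, f"N must be an integer >= 1, got {N}")
    _check(lam > 0 and mu >= 0 and C0 >= 0, "need lambda > 0, mu >= 0, C0 >= 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check(np.all(t_arr >= 0), "time must be >= 0")
    g_cut = _uniform_g_cut(N, lam, mu, float(t_arr.max())) if G is None else int(G)
    g = np.arange(g_cut + 1)
    j = np.arange(1, N + 1)
    m = (N * g[:, None] + j[None, :] - 1).astype(float)      # (G+1, N)
    with np.errstate(divide="ignore"):
        log_lt = np.log(np.maximum(lam * t_arr, 0.0))        # -inf at t=0
    with np.errstate(invalid="ignore"):  # 0 * (-inf) at (m=0, t=0), patched below
        log_terms = (g[:, None, None] * np.log(2.0)
                     + m[:, :, None] * log_lt[None, None, :]
                     - gammaln(m + 1.0)[:, :, None]
                     - (lam + mu) * t_arr[None, None, :])
    # 0^0 = 1 for the (g=0, j=1) compartment at t=0
    log_terms = np.where((m[:, :, None] == 0) & (t_arr[None, None, :] == 0), 0.0, log_terms)
    vals = C0 * np.exp(log_terms)
    return vals[:, :, 0] if np.isscalar(t) or np.ndim(t) == 0 else vals


def msg_exponential_mean(birth_rates, death_rates, C0: float, t) -> np.ndarray:
    """Per-generation means of the single-stage (exponential) MS-G model.

    With one stage per generation the model is a birth–death process tracking
    generations, with partial-fraction closed form

        M^0(t) = C0 e^{-(lambda_0+mu_0) t},
        M^g(t) = 2^g C0 (prod_{l<g} lambda_l)
                 sum_i e^{-a_i t} prod_{k != i} 1 / (a_k - a_i),

    where ``a_i = lambda_i + mu_i``.  Coincident ``a_i`` values make the
    partial fractions singular and raise :class:`DegenerateRatesError`.

    Returns
    -------
    ndarray
        Shape ``(G+1,)`` for scalar ``t``, else ``(G+1, len(t))``.
    """
    lams = np.atleast_1d(np.asarray(birth_rates, dtype=float))
    mus = np.atleast_1d(np.asarray(death_rates, dtype=float))
    _check(lams.shape == mus.shape, "birth and death rate vectors must have equal length")
    _check(np.all(lams > 0) and np.all(mus >= 0), "need lambda_g > 0 and mu_g >= 0")
    a = lams + mus
    G = a.size - 1
    diffs = np.abs(a[:, None] - a[None, :])[np.triu_indices(G + 1, k=1)]
    if diffs.size and diffs.min() < 1e-10 * max(a.max(), 1.0):
        raise DegenerateRatesError(
            "coincident rate sums lambda_i + mu_i; partial-fraction form is singular "
            "— use erlangcell.ode.solve_mean")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _check(np.all(t_arr >= 0), "time must be >= 0")
    out = np.empty((G + 1, t_arr.size))
    out[0] = C0 * np.exp(-a[0] * t_arr)
    for g in range(1, G + 1):
        acc = np.zeros(t_arr.size)
        for i in range(g + 1):
            denom = np.prod([a[k] - a[i] for k in range(g + 1) if k != i])
            acc += np.exp(-a[i] * t_arr) / denom
        out[g] = 2.0**g * C0 * np.prod(lams[:g]) * acc
    return out[:, 0] if np.isscalar(t) or np.ndim(t) == 0 else out
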