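"""ABC-SMC calibration of the generation-tracking models to CFSE summaries.

The multi-stage variant has six free parameters, ``theta = (C0, N0, N,
lambda_0, lambda, alpha)``: the transferred cell number, the stage counts and
birth rates of generation 0 and of all later generations, and the slope of
the linear death law ``mu_g = alpha g``.  The single-stage (exponential)
variant pins ``N0 = N = 1``, leaving four.  Priors are uniform — over the
base-10 exponent for the parameters that span orders of magnitude, and
discrete uniform on ``{1..50}`` for the stage counts.

Fitting is likelihood-free: a parameter draw is scored by the distance
between its predicted per-class means and the data summaries,

    d = sqrt( sum_g sum_t [ (x_M^g(t) - x_D^g(t)) / sigma_D^g(t) ]^2 ),

over the six generation classes and the design time points.  The SMC
scheduler sets the first tolerance to the median distance of 10^4
prior-predictive draws, then each subsequent tolerance to the median of the
previously accepted distances, resampling and perturbing particles with a
uniform kernel and standard sequential importance weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import _check
from .ode import (DEFAULT_G_MAX, TRUNCATION_SHARE, SolverFailureError,
                  collapse_generations, merge_tail_class, solve_mean, terminal_share)
from .model import build_schedule
from .synth import CFSEDataset

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "Posterior",
    "distance",
    "predict_classes",
    "run_abc_smc",
    "aicc",
    "posterior_report",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("C0", "N0", "N", "lambda0", "lambda", "alpha")
#: Parameters sampled and perturbed on their base-10 exponent.
LOG_PARAMS = ("C0", "lambda0", "lambda", "alpha")
DISCRETE_PARAMS = ("N0", "N")
#: Hard ceiling for automatic G_max expansion in predict_classes.
G_MAX_CEILING = 95


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior supports (log10 bounds for the continuous parameters)."""

    x_C0: tuple = (4.0, 6.0)       # C0 = 10^x
    N_range: tuple = (1, 50)       # discrete uniform, both N0 and N
    y_lambda0: tuple = (-3.0, 1.0)  # lambda0 = 10^y  (1/h)
    z_lambda: tuple = (-3.0, 1.0)   # lambda  = 10^z  (1/h)
    w_alpha: tuple = (-5.0, -1.0)   # alpha   = 10^w  (1/h per division)

    def exponent_bounds(self) -> dict[str, tuple]:
        return {"C0": self.x_C0, "lambda0": self.y_lambda0,
                "lambda": self.z_lambda, "alpha": self.w_alpha}

    def sample(self, rng: np.random.Generator, n: int, variant: str = "ms") -> pd.DataFrame:
        """Draw ``n`` parameter vectors from the prior (natural scale)."""
        lo, hi = self.N_range
        df = pd.DataFrame({
            "C0": 10.0 ** rng.uniform(*self.x_C0, n),
            "N0": rng.integers(lo, hi + 1, n) if variant == "ms" else np.ones(n, dtype=int),
            "N": rng.integers(lo, hi + 1, n) if variant == "ms" else np.ones(n, dtype=int),
            "lambda0": 10.0 ** rng.uniform(*self.y_lambda0, n),
            "lambda": 10.0 ** rng.uniform(*self.z_lambda, n),
            "alpha": 10.0 ** rng.uniform(*self.w_alpha, n),
        })
        return df

    def in_support(self, exponents: dict[str, float], N0: int, N: int) -> bool:
        lo, hi = self.N_range
        if not (lo <= N0 <= hi and lo <= N <= hi):
            return False
        for name, (a, b) in self.exponent_bounds().items():
            if not (a <= exponents[name] <= b):
                return False
        return True


@dataclass(frozen=True)
class ABCConfig:
    """Tunable knobs of the SMC scheduler.

    ``n_iterations`` defaults to 16 for the multi-stage variant and 7 for the
    exponential one.  ``max_attempts_factor`` bounds the proposals per
    iteration at ``factor * n_particles``; exhausting it stops the run early
    with the last completed population (flagged), which guards against
    acceptance-rate collapse.
    """

    n_particles: int = 1000
    n_iterations: int | None = None
    n_prior_predictive: int = 10_000
    max_attempts_factor: int = 2000
    G_max: int = DEFAULT_G_MAX
    #: Uniform-kernel half-width as a multiple of the previous population's
    #: weighted SD (per exponent dimension).
    kernel_scale: float = 0.5

    def iterations_for(self, variant: str) -> int:
        if self.n_iterations is not None:
            return self.n_iterations
        return 16 if variant == "ms" else 7


def distance(model_classes: np.ndarray, data_means: np.ndarray,
             data_sds: np.ndarray) -> float:
    """Standardised Euclidean distance between model and data class means.

    All three arrays must share the ``(n_times, n_classes)`` layout (classes
    ``0..4, 5+`` on the design time grid); a shape mismatch means model and
    data were evaluated on different (g, t) cells and raises ``ValueError``.
    Non-finite model predictions (overflowing parameter draws) yield ``inf``.
    """
    xm = np.asarray(model_classes, dtype=float)
    xd = np.asarray(data_means, dtype=float)
    sd = np.asarray(data_sds, dtype=float)
    if not (xm.shape == xd.shape == sd.shape):
        raise ValueError(
            f"misaligned (generation, time) cells: model {xm.shape}, "
            f"data {xd.shape}, sd {sd.shape}")
    if not np.all(np.isfinite(xm)):
        return math.inf
    return float(np.sqrt(np.sum(((xm - xd) / sd) ** 2)))


def predict_classes(theta, times, G_max: int = DEFAULT_G_MAX) -> np.ndarray:
    """Model class means ``x_M^g(t)`` for a parameter draw.

    Builds the two-block schedule, solves the mean-field system by matrix
    exponential, collapses stages to generations and merges the tail class.
    If the terminal tracked generation holds more than ``1e-6`` of the
    population at the last time, the solve is repeated with a larger
    ``G_max`` (logged) so that truncation never distorts the merged class.

    ``theta`` is a mapping with keys ``C0, N0, N, lambda0, lambda, alpha``.

    Raises
    ------
    SolverFailureError
        If the population overflows double precision (callers treat the draw
        as infinitely distant) or the truncation rule cannot be satisfied
    """
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    G = int(G_max)
    while True:
        schedule = build_schedule(C0=theta["C0"], N0=int(theta["N0"]),
                                  lambda0=theta["lambda0"], N=int(theta["N"]),
                                  lam=theta["lambda"], alpha=theta["alpha"], G_max=G)
        traj = solve_mean(schedule, t_arr)
        if terminal_share(traj) < TRUNCATION_SHARE:
            break
        if G >= G_MAX_CEILING:
            raise SolverFailureError(
                f"truncation rule unsatisfied at G_max={G}; population outran "
                "the tracked generations")
        G = min(2 * G, G_MAX_CEILING)
        log.debug("expanding G_max to %d for theta=%s", G, dict(theta))
    return merge_tail_class(collapse_generations(traj))


@dataclass
class Posterior:
    """Weighted particle populations of one ABC-SMC run.

    ``populations[i]`` holds iteration ``i + 1``; columns are the parameters
    plus ``distance`` and (normalised) ``weight``.  ``epsilons`` is the
    strictly decreasing threshold history, ``attempts`` the proposals spent
    per iteration.
    """

    populations: list[pd.DataFrame]
    epsilons: list[float]
    attempts: list[int]
    seed: int
    variant: str
    early_stopped: bool = False
    n_truncation_expansions: int = 0

    @property
    def final(self) -> pd.DataFrame:
        return self.populations[-1]

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Weighted equal-tailed credible interval from the final population.

        Continuous parameters are summarised on their base-10 exponent (the
        scale on which they were sampled); stage counts on the natural scale.
        """
        vals = self.final[param].to_numpy(dtype=float)
        if param in LOG_PARAMS:
            vals = np.log10(vals)
        w = self.final["weight"].to_numpy()
        lo = _weighted_quantile(vals, w, (1 - level) / 2)
        hi = _weighted_quantile(vals, w, 1 - (1 - level) / 2)
        return lo, hi

    def best_distance(self) -> float:
        return float(min(p["distance"].min() for p in self.populations))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) / w.sum()
    return float(np.interp(q, cw, v))


def _weighted_std(values: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    m = np.sum(w * values)
    return float(np.sqrt(max(np.sum(w * (values - m) ** 2), 0.0)))


def _safe_distance(theta, times, data_means, data_sds, G_max) -> float:
    try:
        pred = predict_classes(theta, times, G_max=G_max)
    except SolverFailureError:
        return math.inf
    except FloatingPointError:
        return math.inf
    return distance(pred, data_means, data_sds)


def run_abc_smc(
    dataset: CFSEDataset,
    variant: str = "ms",
    config: ABCConfig | None = None,
    seed: int = 0,
    prior: PriorSpec | None = None,
) -> Posterior:
    """Sequential ABC posterior for one model variant on one dataset.

    Parameters
    ----------
    dataset
        Replicate-level CFSE counts; only the per-(class, time) summary
        means and floored SDs enter the distance.
    variant
        ``"ms"`` (six free parameters) or ``"exp"`` (``N0 = N = 1`` pinned).
    config, prior, seed
        Scheduler knobs, prior supports, and the master seed; identical
        inputs reproduce the run exactly.

    Notes
    -----
    The first tolerance is the median distance of ``n_prior_predictive``
    prior draws; those same draws, filtered at that tolerance, form the
    first population (they are exactly prior samples conditioned on
    acceptance).  Later iterations resample the previous population by
    weight, perturb with a uniform kernel — half-width equal to half the
    weighted SD of each exponent, ``{-1, 0, +1}`` on the stage counts,
    proposals outside the prior rejected and redrawn — and accept below the
    median of the previously accepted distances.
    """
    _check(variant in ("ms", "exp"), f"unknown model variant {variant!r}")
    config = config or ABCConfig()
    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    times = dataset.times
    data_means, data_sds = dataset.class_matrix()
    bounds = prior.exponent_bounds()
    T = config.iterations_for(variant)
    n_part = config.n_particles

    # --- preliminary prior-predictive stage: epsilon_1 and population 1 ----
    draws = prior.sample(rng, config.n_prior_predictive, variant)
    dists = np.array([
        _safe_distance(row, times, data_means, data_sds, config.G_max)
        for row in draws.to_dict("records")
    ])
    finite = dists[np.isfinite(dists)]
    eps1 = float(np.median(dists)) if finite.size == dists.size else float(np.median(dists))
    accepted_idx = np.flatnonzero(dists < eps1)
    if accepted_idx.size > n_part:
        accepted_idx = rng.choice(accepted_idx, size=n_part, replace=False)
    pop = draws.iloc[accepted_idx].reset_index(drop=True).copy()
    pop["distance"] = dists[accepted_idx]
    # top up in the rare case fewer prior draws fell below the median
    attempts_1 = config.n_prior_predictive
    while len(pop) < n_part:
        extra = prior.sample(rng, n_part, variant)
        for row in extra.to_dict("records"):
            d = _safe_distance(row, times, data_means, data_sds, config.G_max)
            attempts_1 += 1
            if d < eps1:
                row["distance"] = d
                pop.loc[len(pop)] = row
                if len(pop) >= n_part:
                    break
    pop["weight"] = 1.0 / len(pop)
    pop.insert(0, "iteration", 1)
    pop.insert(1, "particle", np.arange(len(pop)))
    posterior = Posterior(populations=[pop], epsilons=[eps1],
                          attempts=[attempts_1], seed=seed, variant=variant)

    # --- sequential refinement ------------------------------------------
    for it in range(2, T + 1):
        prev = posterior.populations[-1]
        eps = float(np.median(prev["distance"]))
        prev_w = prev["weight"].to_numpy()
        prev_exp = {p: np.log10(prev[p].to_numpy(dtype=float)) for p in LOG_PARAMS}
        half_width = {p: max(config.kernel_scale * _weighted_std(prev_exp[p], prev_w), 1e-9)
                      for p in LOG_PARAMS}
        kernel_norm = np.prod([2 * h for h in half_width.values()])
        accepted: list[dict] = []
        acc_dist: list[float] = []
        attempts = 0
        max_attempts = config.max_attempts_factor * n_part
        while len(accepted) < n_part and attempts < max_attempts:
            attempts += 1
            base = prev.iloc[int(rng.choice(len(prev), p=prev_w))]
            exps = {p: np.log10(float(base[p])) + rng.uniform(-half_width[p], half_width[p])
                    for p in LOG_PARAMS}
            if variant == "ms":
                N0 = int(base["N0"]) + int(rng.integers(-1, 2))
                N = int(base["N"]) + int(rng.integers(-1, 2))
            else:
                N0 = N = 1
            if not prior.in_support(exps, N0, N):
                continue
            theta = {"C0": 10.0 ** exps["C0"], "N0": N0, "N": N,
                     "lambda0": 10.0 ** exps["lambda0"],
                     "lambda": 10.0 ** exps["lambda"],
                     "alpha": 10.0 ** exps["alpha"]}
            d = _safe_distance(theta, times, data_means, data_sds, config.G_max)
            if d < eps:
                theta["distance"] = d
                theta["_exps"] = exps
                accepted.append(theta)
                acc_dist.append(d)
        if len(accepted) < n_part:
            posterior.early_stopped = True
            log.warning("acceptance collapsed at iteration %d (%d/%d particles in %d attempts)",
                        it, len(accepted), n_part, attempts)
            break
        # sequential importance weights: uniform prior => w ~ 1 / sum_k w_k K(theta | theta_k)
        new_rows = []
        for theta in accepted:
            exps = theta.pop("_exps")
            in_box = np.ones(len(prev), dtype=bool)
            for p in LOG_PARAMS:
                in_box &= np.abs(exps[p] - prev_exp[p]) <= half_width[p] + 1e-12
            if variant == "ms":
                in_box &= np.abs(prev["N0"].to_numpy() - theta["N0"]) <= 1
                in_box &= np.abs(prev["N"].to_numpy() - theta["N"]) <= 1
            denom = prev_w[in_box].sum() / kernel_norm
            theta["weight"] = 1.0 / denom if denom > 0 else 0.0
            new_rows.append(theta)
        new_pop = pd.DataFrame(new_rows)
        new_pop["weight"] /= new_pop["weight"].sum()
        new_pop.insert(0, "iteration", it)
        new_pop.insert(1, "particle", np.arange(len(new_pop)))
        new_pop = new_pop[["iteration", "particle", *PARAM_NAMES, "distance", "weight"]]
        posterior.populations.append(new_pop)
        posterior.epsilons.append(eps)
        posterior.attempts.append(attempts)
    return posterior


def aicc(d_min: float, n: int, k: int) -> float:
    """Corrected Akaike score from the best ABC distance.

    Treats the squared distance as a weighted residual sum of squares under a
    Gaussian working likelihood:

        AICc = n ln(d_min^2 / n) + 2k + 2k(k+1) / (n - k - 1),

    with ``n`` the number of (class, time) data cells and ``k`` the free
    parameters (6 multi-stage, 4 exponential).  This is one defensible
    reading of the small-sample correction for a chi-square-type distance;
    it is isolated here so an alternative convention can be swapped in.
    """
    _check(k >= 1 and n > k + 1, f"AICc undefined for n={n}, k={k} (need n > k+1)")
    _check(d_min > 0, "best distance must be positive")
    return float(n * math.log(d_min**2 / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def posterior_report(posterior: Posterior) -> pd.DataFrame:
    """Summary table of the final population: spread per parameter.

    Rows cover each free parameter (weighted mean/median/SD, plain min/max)
    plus the derived mean division times ``N0/lambda0`` and ``N/lambda``
    (hours) — the mean time to the first and to subsequent divisions.
    """
    pop = posterior.final
    w = pop["weight"].to_numpy()
    params = list(PARAM_NAMES) if posterior.variant == "ms" else ["C0", "lambda0", "lambda", "alpha"]
    rows = []
    series = {p: pop[p].to_numpy(dtype=float) for p in params}
    series["N0/lambda0"] = pop["N0"].to_numpy() / pop["lambda0"].to_numpy()
    series["N/lambda"] = pop["N"].to_numpy() / pop["lambda"].to_numpy()
    for name, v in series.items():
        wm = float(np.sum(w * v) / w.sum())
        rows.append({
            "parameter": name,
            "minimum": float(v.min()),
            "maximum": float(v.max()),
            "mean": wm,
            "median": _weighted_quantile(v, w, 0.5),
            "sd": _weighted_std(v, w),
        })
    return pd.DataFrame(rows)
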