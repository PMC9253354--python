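"""Distance, priors, predictions, the SMC scheduler and AICc."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

import erlangcell as ec
from erlangcell.inference import PriorSpec, predict_classes


class TestDistance:
    def test_zero_at_perfect_fit(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert ec.distance(x, x, np.ones_like(x)) == 0.0

    def test_single_cell_arithmetic(self):
        assert ec.distance([[3.0]], [[1.0]], [[2.0]]) == pytest.approx(1.0)

    def test_pythagorean_cells(self):
        model = np.array([[3.0, 4.0]])
        data = np.zeros((1, 2))
        sd = np.ones((1, 2))
        assert ec.distance(model, data, sd) == pytest.approx(5.0)

    def test_misaligned_cells_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            ec.distance(np.ones((2, 6)), np.ones((3, 6)), np.ones((3, 6)))

    def test_nonfinite_prediction_is_infinitely_distant(self):
        bad = np.array([[np.inf, 1.0]])
        assert ec.distance(bad, np.ones((1, 2)), np.ones((1, 2))) == np.inf


class TestPriors:
    def test_marginals_match_supports(self, rng):
        prior = PriorSpec()
        draws = prior.sample(rng, 10_000)
        # continuous parameters: uniform on the exponent
        for name, (lo, hi) in prior.exponent_bounds().items():
            u = (np.log10(draws[name]) - lo) / (hi - lo)
            assert kstest(u, "uniform").pvalue > 1e-3
        # stage counts: discrete uniform on 1..50
        for name in ("N0", "N"):
            observed = np.bincount(draws[name], minlength=51)[1:]
            assert chisquare(observed).pvalue > 1e-3

    def test_exponential_variant_pins_stage_counts(self, rng):
        draws = PriorSpec().sample(rng, 100, variant="exp")
        assert (draws["N0"] == 1).all() and (draws["N"] == 1).all()


class TestPredictClasses:
    def test_initial_mass_in_class_zero(self):
        theta = {"C0": 1234.0, "N0": 3, "N": 2, "lambda0": 0.1,
                 "lambda": 0.1, "alpha": 0.0}
        pred = predict_classes(theta, [0.0, 10.0])
        assert pred[0, 0] == pytest.approx(1234.0)
        assert pred[0, 1:] == pytest.approx(0.0)

    def test_exponential_reduction_matches_closed_form(self):
        lams = np.array([0.02, 0.03, 0.03, 0.03, 0.03])
        theta = {"C0": 500.0, "N0": 1, "N": 1, "lambda0": 0.02,
                 "lambda": 0.03, "alpha": 0.004}
        t = np.array([24.0, 72.0])
        pred = predict_classes(theta, t)
        mus = 0.004 * np.arange(16)
        ref_gen = ec.msg_exponential_mean([0.02] + [0.03] * 15, mus, 500.0, t).T
        ref = ec.merge_tail_class(ref_gen)
        # classes 0..4 are single low-generation partial fractions (well
        # conditioned); the merged class sums deep generations where the
        # closed form itself loses digits to cancellation
        assert pred[:, :5] == pytest.approx(ref[:, :5], rel=1e-8)
        assert pred[:, 5] == pytest.approx(ref[:, 5], rel=1e-4)

    def test_classes_conserve_the_total(self):
        theta = {"C0": 4.5e4, "N0": 3, "N": 5, "lambda0": 0.05,
                 "lambda": 0.12, "alpha": 2e-4}
        t = np.array([72.0, 168.0])
        pred = predict_classes(theta, t)
        sch = ec.build_schedule(G_max=15, N0=3, lambda0=0.05, N=5, lam=0.12,
                                alpha=2e-4, C0=4.5e4)
        total = ec.solve_mean(sch, t).total()
        assert pred.sum(axis=1) == pytest.approx(total, rel=1e-9)


# truth inside every prior support (C0 between 1e4 and 1e6, rates and death
# slope inside their log-uniform boxes)
TINY_TRUTH = {"C0": 2e4, "N0": 1, "N": 1, "lambda0": 0.01, "lambda": 0.02,
              "alpha": 1e-3}


@pytest.fixture(scope="module")
def tiny_dataset():
    sch = ec.build_schedule(C0=TINY_TRUTH["C0"], N0=1, lambda0=TINY_TRUTH["lambda0"],
                            N=1, lam=TINY_TRUTH["lambda"], alpha=TINY_TRUTH["alpha"],
                            G_max=10)
    design = ec.ExperimentDesign(days=(3, 6), mice_per_day=3)
    return ec.generate_dataset(sch, design, seed=40)


@pytest.fixture(scope="module")
def tiny_posterior(tiny_dataset):
    cfg = ec.ABCConfig(n_particles=60, n_iterations=3, n_prior_predictive=300)
    return ec.run_abc_smc(tiny_dataset, "exp", cfg, seed=5)


class TestSmcScheduler:

    def test_thresholds_strictly_decrease(self, tiny_posterior):
        eps = tiny_posterior.epsilons
        assert all(b < a for a, b in zip(eps, eps[1:]))

    def test_rerun_is_identical(self, tiny_dataset, tiny_posterior):
        cfg = ec.ABCConfig(n_particles=60, n_iterations=3, n_prior_predictive=300)
        again = ec.run_abc_smc(tiny_dataset, "exp", cfg, seed=5)
        for a, b in zip(tiny_posterior.populations, again.populations):
            assert a.equals(b)

    def test_population_contract(self, tiny_posterior):
        final = tiny_posterior.final
        assert len(final) == 60
        assert final["weight"].sum() == pytest.approx(1.0)
        assert (final["weight"] > 0).all()
        assert (final["N0"] == 1).all() and (final["N"] == 1).all()
        prior = PriorSpec()
        assert final["lambda"].between(10.0**-3, 10.0).all()
        assert final["alpha"].between(1e-5, 1e-1).all()

    def test_best_distance_shrinks_on_noiseless_data(self):
        # dataset equal to a (rounded) noiseless model prediction: the best
        # particle homes in on the identifiable optimum as iterations pass
        theta = TINY_TRUTH
        times = np.array([72.0, 144.0])
        pred = np.rint(predict_classes(theta, times)).astype(int)
        rows = [(t, rep, cls, int(pred[ti, ci]))
                for ti, t in enumerate(times)
                for rep in (1, 2)
                for ci, cls in enumerate(("0", "1", "2", "3", "4", "5+"))]
        import pandas as pd
        noiseless = ec.CFSEDataset(pd.DataFrame(
            rows, columns=["time_h", "replicate_id", "generation_class", "cell_count"]))
        cfg = ec.ABCConfig(n_particles=100, n_iterations=14, n_prior_predictive=500)
        post = ec.run_abc_smc(noiseless, "exp", cfg, seed=13)
        first = post.populations[0]["distance"].min()
        assert post.best_distance() < 0.2 * first

    def test_self_consistency_exponential_recovery(self, tiny_dataset):
        """The exponential variant fitted to exponential-generated data keeps
        the truth inside its (broad, early-iteration) credible intervals."""
        cfg = ec.ABCConfig(n_particles=150, n_iterations=6, n_prior_predictive=1000)
        post = ec.run_abc_smc(tiny_dataset, "exp", cfg, seed=31)
        truth_log10 = {p: np.log10(TINY_TRUTH[p])
                       for p in ("C0", "lambda0", "lambda", "alpha")}
        covered = 0
        for p, v in truth_log10.items():
            lo, hi = post.credible_interval(p)
            covered += lo <= v <= hi
        assert covered >= 3


class TestAicc:
    def test_reference_value(self):
        # n ln(d^2/n) = 0, then 2k + 2k(k+1)/(n-k-1) = 2 + 0.5
        assert ec.aicc(np.sqrt(10.0), n=10, k=1) == pytest.approx(2.5)

    def test_smaller_distance_scores_better(self):
        assert ec.aicc(5.0, 30, 6) > ec.aicc(2.5, 30, 6)

    def test_undefined_correction_rejected(self):
        with pytest.raises(Exception):
            ec.aicc(1.0, n=5, k=4)


class TestReport:
    def test_summary_rows_and_derived_division_times(self, tiny_dataset):
        cfg = ec.ABCConfig(n_particles=40, n_iterations=2, n_prior_predictive=200)
        post = ec.run_abc_smc(tiny_dataset, "exp", cfg, seed=9)
        table = ec.posterior_report(post)
        assert set(table["parameter"]) == {"C0", "lambda0", "lambda", "alpha",
                                           "N0/lambda0", "N/lambda"}
        assert (table["minimum"] <= table["maximum"]).all()
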