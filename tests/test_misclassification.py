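"""Patient-misclassification simulation against exact and analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from neutralqol import (
    EmptyInputError,
    SimulationConfig,
    analytic_fdr,
    analytic_for,
    export_panels,
    false_discovery_proportion,
    false_omission_proportion,
    run_misclassification,
    simulate_study,
    threshold_census,
)
from neutralqol.misclassification import derive_instrument_seed


def exact_outcome_probability(tp, fp, fn, tn, se, sp, p):
    """Closed-form probability of one (tp, fp, fn, tn) study outcome.

    The cohort size fixes everything: D = tp + fn truly-poor patients arise
    with binomial probability, then tp of D are detected and fp of n−D are
    falsely flagged — an independent oracle for the two-stage sampler.
    """
    n = tp + fp + fn + tn
    d = tp + fn
    return (
        binom.pmf(d, n, p) * binom.pmf(tp, d, se) * binom.pmf(fp, n - d, 1 - sp)
    )


class TestSimulateStudy:
    def test_perfect_classifier_never_errs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = simulate_study(1.0, 1.0, 0.3, 40, rng)
            assert fp == 0 and fn == 0

    def test_all_poor_boundary(self):
        # p = 1 forces D = n: nobody is left to misclassify as positive
        rng = np.random.default_rng(0)
        tp, fp, fn, tn = simulate_study(0.7, 0.4, 1.0, 30, rng)
        assert fp == 0 and tn == 0 and tp + fn == 30

    @settings(max_examples=100, derandomize=True)
    @given(
        se=st.floats(0, 1), sp=st.floats(0, 1),
        p=st.floats(0, 1), n=st.integers(1, 200), seed=st.integers(0, 2**20),
    )
    def test_count_conservation(self, se, sp, p, n, seed):
        counts = simulate_study(se, sp, p, n, np.random.default_rng(seed))
        assert all(c >= 0 for c in counts)
        assert sum(counts) == n

    def test_matches_exhaustive_enumeration(self):
        """Empirical outcome frequencies at n=3 match the closed-form tree
        probabilities within 4 standard errors over 1e5 draws."""
        se, sp, p, n, draws = 0.5, 0.5, 0.5, 3, 100_000
        rng = np.random.default_rng(1234)
        freq: dict[tuple, int] = {}
        for _ in range(draws):
            out = simulate_study(se, sp, p, n, rng)
            freq[out] = freq.get(out, 0) + 1
        # enumerate every outcome with positive probability
        total_prob = 0.0
        for d in range(n + 1):
            for tp in range(d + 1):
                for fp in range(n - d + 1):
                    outcome = (tp, fp, d - tp, n - d - fp)
                    prob = exact_outcome_probability(*outcome, se, sp, p)
                    total_prob += prob
                    observed = freq.get(outcome, 0) / draws
                    stderr = np.sqrt(prob * (1 - prob) / draws)
                    assert abs(observed - prob) < 4 * stderr + 1e-12, outcome
        assert total_prob == pytest.approx(1.0)


class TestProportions:
    @pytest.mark.parametrize(
        "tp,fp,expected", [(0, 5, 1.0), (5, 5, 0.5), (0, 0, None)]
    )
    def test_false_discovery(self, tp, fp, expected):
        assert false_discovery_proportion(tp, fp) == expected

    @pytest.mark.parametrize(
        "fn,tn,expected", [(5, 0, 1.0), (0, 5, 0.0), (0, 0, None)]
    )
    def test_false_omission(self, fn, tn, expected):
        assert false_omission_proportion(fn, tn) == expected

    @pytest.mark.parametrize(
        "se,sp,p,expected",
        [
            (1.0, 1.0, 0.5, 0.0),
            (0.5, 0.5, 0.5, 0.5),
            (0.3, 0.2, 0.2, 0.64 / 0.70),
        ],
    )
    def test_analytic_fdr(self, se, sp, p, expected):
        assert analytic_fdr(se, sp, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "se,sp,p,expected",
        [
            (1.0, 1.0, 0.5, 0.0),
            (0.5, 0.5, 0.5, 0.5),
            (0.3, 0.2, 0.8, 0.56 / 0.60),
        ],
    )
    def test_analytic_for(self, se, sp, p, expected):
        assert analytic_for(se, sp, p) == pytest.approx(expected)

    def test_analytic_undefined(self):
        assert analytic_fdr(0.0, 1.0, 0.5) is None
        assert analytic_for(1.0, 0.0, 0.5) is None


class TestRunMisclassification:
    def test_perfect_instrument_all_zero(self):
        r = run_misclassification(
            1.0, 1.0, SimulationConfig(prevalence=0.5, n_studies=200, seed=7)
        )
        for field in ("fdr_median", "fdr_lo", "fdr_hi",
                      "for_median", "for_lo", "for_hi"):
            assert getattr(r, field) == 0.0

    def test_median_matches_analytic_oracle(self):
        """Large-cohort median converges to the closed form."""
        cfg = SimulationConfig(
            prevalence=0.5, n_studies=1000, n_patients=10_000, seed=11
        )
        r = run_misclassification(0.9, 0.9, cfg)
        assert r.fdr_median == pytest.approx(analytic_fdr(0.9, 0.9, 0.5), abs=0.01)
        assert r.for_median == pytest.approx(analytic_for(0.9, 0.9, 0.5), abs=0.01)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(prevalence=0.2, n_studies=300, seed=42)
        a = run_misclassification(0.4, 0.3, cfg)
        b = run_misclassification(0.4, 0.3, cfg)
        assert np.array_equal(a.fdr_draws, b.fdr_draws)
        assert np.array_equal(a.for_draws, b.for_draws)
        assert (a.fdr_median, a.fdr_lo, a.fdr_hi) == (b.fdr_median, b.fdr_lo, b.fdr_hi)

    def test_percentile_ordering_and_undefined_accounting(self):
        cfg = SimulationConfig(
            prevalence=0.05, n_studies=500, n_patients=10, seed=3
        )
        r = run_misclassification(0.3, 0.99, cfg)
        assert r.fdr_lo <= r.fdr_median <= r.fdr_hi
        assert r.for_lo <= r.for_median <= r.for_hi
        # low prevalence and tiny cohorts: some studies flag nobody
        assert r.n_undefined_fdr > 0
        assert len(r.fdr_draws) + r.n_undefined_fdr == cfg.n_studies

    def test_prevalence_monotonicity(self):
        """Discovery error falls and omission error rises with prevalence."""
        meds = [
            run_misclassification(
                0.4, 0.2,
                SimulationConfig(prevalence=p, n_studies=500, seed=9),
            )
            for p in (0.2, 0.5, 0.8)
        ]
        fdr = [m.fdr_median for m in meds]
        fo = [m.for_median for m in meds]
        assert fdr[0] >= fdr[1] >= fdr[2]
        assert fo[0] <= fo[1] <= fo[2]

    def test_prevalence_bounds_enforced(self):
        with pytest.raises(Exception, match="prevalence"):
            SimulationConfig(prevalence=0.0)

    def test_alternate_percentile_set(self):
        cfg5 = SimulationConfig(prevalence=0.5, n_studies=400, seed=2)
        cfg25 = cfg5.model_copy(update={"percentile_set": "p2.5_p97.5"})
        r5 = run_misclassification(0.4, 0.3, cfg5)
        r25 = run_misclassification(0.4, 0.3, cfg25)
        assert r25.fdr_lo <= r5.fdr_lo and r25.fdr_hi >= r5.fdr_hi


class TestCensusAndPanels:
    def _result(self, fdr, fo):
        cfg = SimulationConfig(prevalence=0.5, n_studies=10, seed=0)
        r = run_misclassification(0.5, 0.5, cfg)
        object.__setattr__(r, "fdr_median", fdr)
        object.__setattr__(r, "for_median", fo)
        return r

    def test_census_counts(self):
        results = {f"i{k}": self._result(v, v) for k, v in
                   enumerate([0.4, 0.6, 0.8])}
        assert threshold_census(results, "fdr_median", 0.5, "gt") == 2
        assert threshold_census(results, "fdr_median", 0.5, "lt") == 1
        assert threshold_census(results, "for_median", 0.75, "gt") == 1

    def test_census_empty_input(self):
        with pytest.raises(EmptyInputError):
            threshold_census({}, "fdr_median", 0.5, "gt")

    def test_panels_shape(self):
        one = {"inst": self._result(0.5, 0.5)}
        single = export_panels({0.5: one})
        assert len(single) == 3
        assert set(single["point"]) == {"lo", "median", "hi"}
        nine = export_panels({0.2: one, 0.5: one, 0.8: one})
        assert len(nine) == 9
        assert list(nine.columns) == ["prevalence", "point", "instrument",
                                      "fnr", "fpr"]

    def test_perfect_instrument_panel_is_zero(self):
        cfg = SimulationConfig(prevalence=0.5, n_studies=100, seed=1)
        r = run_misclassification(1.0, 1.0, cfg)
        panel = export_panels({0.5: {"perfect": r}})
        assert (panel[["fnr", "fpr"]].to_numpy() == 0).all()


def test_instrument_seed_streams_are_stable_and_distinct():
    seeds = [derive_instrument_seed(99, k) for k in range(50)]
    assert seeds == [derive_instrument_seed(99, k) for k in range(50)]
    assert len(set(seeds)) == 50
    assert all(0 <= s < 2**31 for s in seeds)
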