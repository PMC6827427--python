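"""Survival estimation, log-rank, Cox and the exact r x c Fisher test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvcerna.clinical import (
    ContingencyTable,
    SurvivalStratum,
    associate_cnv_clinical,
    cox_fit,
    fisher_exact_rxc,
    km_estimate,
    logrank_test,
    strata_for_gene,
)
from cnvcerna.io import ClinicalTable


class TestKaplanMeier:
    def test_hand_product_limit_three_events(self):
        s = km_estimate(SurvivalStratum("x", [1.0, 2.0, 3.0], [1, 1, 1]))
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(1 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_single_censored_observation_flat_at_one(self):
        s = km_estimate(SurvivalStratum("x", [5.0], [0]))
        assert (s == 1.0).all()

    def test_order_invariance(self, rng):
        t = rng.exponential(100, 30)
        e = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        a = km_estimate(SurvivalStratum("a", t, e))
        b = km_estimate(SurvivalStratum("b", t[perm], e[perm]))
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_censoring_between_events(self):
        # censored subject at t=1.5 leaves risk set before the t=2 event
        s = km_estimate(SurvivalStratum("x", [1.0, 1.5, 2.0], [1, 0, 1]))
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(0.0)


def _logrank_oracle(ta, ea, tb, eb):
    """Observed-minus-expected log-rank chi-square built from first principles."""
    events = sorted({t for t, e in zip(list(ta) + list(tb), list(ea) + list(eb)) if e})
    O = E = V = 0.0
    for t in events:
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        da = np.sum((ta == t) & (ea == 1))
        db = np.sum((tb == t) & (eb == 1))
        n, d = na + nb, da + db
        if n < 2:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogRank:
    def test_identical_strata(self):
        a = SurvivalStratum("a", [1.0, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank_test(a, SurvivalStratum("b", a.times, a.events))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_separated_strata_match_oe_oracle(self):
        ta = np.array([1.0, 2, 3, 4, 5]); ea = np.ones(5, int)
        tb = np.array([10.0, 11, 12, 13, 14]); eb = np.ones(5, int)
        chi2, p = logrank_test(SurvivalStratum("a", ta, ea),
                               SurvivalStratum("b", tb, eb))
        assert chi2 == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_random_strata_match_oe_oracle(self, rng):
        ta = np.round(rng.exponential(50, 40), 1); ea = rng.integers(0, 2, 40)
        tb = np.round(rng.exponential(80, 35), 1); eb = rng.integers(0, 2, 35)
        chi2, _ = logrank_test(SurvivalStratum("a", ta, ea),
                               SurvivalStratum("b", tb, eb))
        assert chi2 == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_label_swap_symmetry(self, rng):
        ta = rng.exponential(50, 20); ea = rng.integers(0, 2, 20)
        tb = rng.exponential(90, 25); eb = rng.integers(0, 2, 25)
        c1, p1 = logrank_test(SurvivalStratum("a", ta, ea), SurvivalStratum("b", tb, eb))
        c2, p2 = logrank_test(SurvivalStratum("b", tb, eb), SurvivalStratum("a", ta, ea))
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)

    def test_no_events_is_error(self):
        a = SurvivalStratum("a", [1.0, 2], [0, 0])
        b = SurvivalStratum("b", [3.0], [0])
        with pytest.raises(ValueError):
            logrank_test(a, b)


def _clin(df):
    df = df.copy()
    df["subtype"] = "A"
    df.index = [f"S{i}" for i in range(len(df))]
    return ClinicalTable(df)


class TestCox:
    def test_null_covariate_recovers_hr_one(self):
        rng = np.random.default_rng(42)
        n = 1000
        t = rng.exponential(500, n); c = rng.uniform(0, 1500, n)
        df = pd.DataFrame({"os_days": np.minimum(t, c),
                           "os_event": (t <= c).astype(int),
                           "x": rng.normal(size=n)})
        hr = cox_fit(_clin(df), ["x"]).iloc[0]["HR"]
        assert 0.85 <= hr <= 1.18

    def test_true_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        lam = math.log(2) / 500 * np.exp(math.log(2) * x)
        t = rng.exponential(1 / lam); c = rng.uniform(0, 1800, n)
        df = pd.DataFrame({"os_days": np.minimum(t, c),
                           "os_event": (t <= c).astype(int), "x": x})
        assert 0.25 <= 1 - df["os_event"].mean() <= 0.40  # ~30% censoring
        hr = cox_fit(_clin(df), ["x"]).iloc[0]["HR"]
        assert 1.6 <= hr <= 2.5

    def test_duplicating_observations_leaves_hr_nearly_unchanged(self):
        # exactly invariant under Breslow ties; Efron introduces a tiny shift
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(300 * np.exp(-0.5 * x))
        df = pd.DataFrame({"os_days": t, "os_event": 1, "x": x})
        hr1 = cox_fit(_clin(df), ["x"]).iloc[0]["HR"]
        hr2 = cox_fit(_clin(pd.concat([df, df], ignore_index=True)), ["x"]).iloc[0]["HR"]
        assert hr2 == pytest.approx(hr1, rel=0.01)

    def test_constant_covariate_is_error(self):
        df = pd.DataFrame({"os_days": [1.0, 2, 3], "os_event": [1, 1, 1],
                           "x": [1.0, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(_clin(df), ["x"])

    def test_multivariate_joint_fit_returns_all_covariates(self):
        rng = np.random.default_rng(3)
        n = 300
        df = pd.DataFrame({
            "os_days": rng.exponential(300, n),
            "os_event": rng.integers(0, 2, n),
            "x": rng.normal(size=n), "y": rng.normal(size=n),
        })
        out = cox_fit(_clin(df), ["x", "y"], mode="multivariate")
        assert list(out["covariate"]) == ["x", "y"]
        assert (out["mode"] == "multivariate").all()


def _fisher_enumeration_oracle(counts):
    """Sum multivariate-hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed table."""
    counts = np.asarray(counts, int)
    rs = counts.sum(1); cs = counts.sum(0); n = counts.sum()

    def prob(tbl):
        num = math.prod(math.factorial(int(v)) for v in rs) * \
            math.prod(math.factorial(int(v)) for v in cs)
        den = math.factorial(int(n)) * \
            math.prod(math.factorial(int(v)) for v in np.ravel(tbl))
        return num / den

    # enumerate all 2 x c tables via the first row
    ranges = [range(0, min(rs[0], c) + 1) for c in cs]
    p_obs = prob(counts)
    total = check = 0.0
    for first in itertools.product(*ranges):
        if sum(first) != rs[0]:
            continue
        second = cs - np.array(first)
        if (second < 0).any():
            continue
        p = prob(np.array([first, second]))
        check += p
        if p <= p_obs * (1 + 1e-7):
            total += p
    assert check == pytest.approx(1.0, abs=1e-10)  # margin class sums to 1
    return total


class TestFisherRxC:
    def test_uniform_table_is_the_mode(self):
        assert fisher_exact_rxc(np.array([[5, 5, 5], [5, 5, 5]])) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[8, 2], [1, 5]], [[2, 7], [8, 2]], [[0, 5], [6, 1]],
    ])
    def test_2x2_matches_scipy(self, table):
        ours = fisher_exact_rxc(np.array(table))
        ref = stats.fisher_exact(np.array(table)).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    @pytest.mark.parametrize("table", [
        [[5, 2, 1], [1, 4, 6]], [[10, 0, 3], [2, 8, 1]], [[1, 1, 1], [4, 4, 4]],
    ])
    def test_2x3_matches_enumeration_oracle(self, table):
        assert fisher_exact_rxc(np.array(table)) == pytest.approx(
            _fisher_enumeration_oracle(table), rel=1e-9)

    def test_3x3_matches_r_reference_value(self):
        # value frozen from R fisher.test on the same table
        table = np.array([[8, 2, 1], [2, 6, 2], [1, 2, 7]])
        assert fisher_exact_rxc(table) == pytest.approx(0.003401837, rel=1e-5)

    def test_budget_guard(self):
        big = np.full((4, 5), 400)
        with pytest.raises(ValueError, match="Monte-Carlo"):
            fisher_exact_rxc(big)

    def test_paper_style_2x3_subtype_table(self):
        counts = np.array([[117, 101, 150], [39, 12, 13]])
        assert fisher_exact_rxc(counts) == pytest.approx(5.61e-05, rel=5e-3)

    def test_contingency_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(["a"], ["x", "y"], np.array([[1, 2]]))


class TestAssociation:
    def test_survival_linked_driver_detected_with_power(self):
        """The deletion driver the generator ties survival to is flagged by
        the log-rank stage in at least 90% of seeds (cohorts sized so the
        expected log-rank z is ~3.6)."""
        from cnvcerna.clinical import logrank_test as lr
        from cnvcerna.simulate import SimulationConfig, generate_cohort

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_samples=300, n_mrna=20, n_lncrna=4, n_mirna=4,
                n_driver_genes=2, n_weakened_pairs=2, targets_per_mirna=2,
                seed=seed)
            co = generate_cohort(cfg)
            t = co.truth.planted_drivers[cfg.survival_driver_index]
            state = 2 if t["direction"] == "amplification" else -2
            carrier, neutral, _ = strata_for_gene(
                co.cnv, co.clinical, t["gene"], state)
            _, p = lr(carrier, neutral)
            hits += p < 0.05
        assert hits >= 0.9 * n_seeds

    def test_association_table_complete(self, small_cohort):
        co = small_cohort
        drivers = pd.DataFrame([
            {"gene_id": t["gene"], "direction": t["direction"], "is_driver": True}
            for t in co.truth.planted_drivers
        ])
        expr = pd.concat([co.mrna.values, co.lncrna.values])
        out = associate_cnv_clinical(drivers, co.cnv, expr, co.clinical)
        assert len(out) == len(drivers)
        assert out["logrank_p"].between(0, 1).all()
        assert out["fisher_subtype_p"].between(0, 1).all()
        assert (out["n_carriers"] >= 3).all()

    def test_strata_exclude_low_level_states(self, small_cohort):
        co = small_cohort
        gene = co.truth.planted_drivers[0]["gene"]
        state = 2 if co.truth.planted_drivers[0]["direction"] == "amplification" else -2
        carrier, neutral, indicator = strata_for_gene(co.cnv, co.clinical, gene, state)
        calls = co.cnv.calls.loc[gene]
        assert carrier.times.size == int((calls == state).sum())
        assert neutral.times.size == int((calls == 0).sum())
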