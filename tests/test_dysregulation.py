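"""The dR statistic and its label-permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cnvcerna.dysregulation import (
    ENHANCED,
    WEAKENED,
    call_dysregulated_pairs,
    delta_r,
    permutation_test,
)
from cnvcerna.triplets import CandidateTriplet


class TestDeltaR:
    @pytest.mark.parametrize(
        "cor_v,cor_n,delta,direction",
        [(0.2, 0.8, 0.6, WEAKENED), (0.9, 0.6, 0.3, ENHANCED),
         (0.5, 0.5, 0.0, WEAKENED)],
    )
    def test_formula_and_direction(self, cor_v, cor_n, delta, direction):
        d, dirn = delta_r(cor_v, cor_n)
        assert d == pytest.approx(delta) and dirn == direction


def _series(x, prefix):
    return pd.Series(x, index=[f"{prefix}{i}" for i in range(len(x))])


def _exact_perm_p(x, y, na):
    """Exact permutation p by enumerating every label assignment."""
    n = len(x)
    def dr(idx_a):
        idx_a = list(idx_a)
        idx_n = [i for i in range(n) if i not in idx_a]
        rv = np.corrcoef(x[idx_a], y[idx_a])[0, 1]
        rn = np.corrcoef(x[idx_n], y[idx_n])[0, 1]
        return abs(rv - rn)
    obs = dr(range(na))
    vals = [dr(c) for c in itertools.combinations(range(n), na)]
    return np.mean([v >= obs - 1e-12 for v in vals]), obs


class TestPermutationTest:
    def test_zero_observed_delta_gives_p_one(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(0, 0.1, 10)
        xs = _series(np.concatenate([x, x]), "s")
        ys = _series(np.concatenate([y, y]), "s")
        ab, no = set(xs.index[:10]), set(xs.index[10:])
        p, d, *_ = permutation_test(xs, ys, ab, no, n_perm=300, seed=0)
        assert d == pytest.approx(0.0) and p == 1.0

    def test_matches_exact_enumeration_at_4_plus_4(self, rng):
        """Monte-Carlo p within 3 MC standard errors of the 70-assignment
        exact value."""
        for trial in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact, _ = _exact_perm_p(x, y, 4)
            xs, ys = _series(x, "s"), _series(y, "s")
            ab, no = set(xs.index[:4]), set(xs.index[4:])
            n_perm = 1000
            p, *_ = permutation_test(xs, ys, ab, no, n_perm=n_perm, seed=trial)
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(p - exact) <= 3 * se + 2 / n_perm

    def test_seed_reproducibility(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        xs, ys = _series(x, "s"), _series(y, "s")
        ab, no = set(xs.index[:10]), set(xs.index[10:])
        p1, *_ = permutation_test(xs, ys, ab, no, seed=7)
        p2, *_ = permutation_test(xs, ys, ab, no, seed=7)
        assert p1 == p2

    def test_invariant_to_pair_labelling_and_sample_order(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        xs, ys = _series(x, "s"), _series(y, "s")
        ab, no = set(xs.index[:12]), set(xs.index[12:])
        p1, d1, cv1, cn1 = permutation_test(xs, ys, ab, no, seed=3)
        # swap the two ceRNAs
        p2, d2, cv2, cn2 = permutation_test(ys, xs, ab, no, seed=3)
        # shuffle the storage order of the series
        perm = np.random.default_rng(0).permutation(30)
        p3, d3, *_ = permutation_test(xs.iloc[perm], ys.iloc[perm], ab, no, seed=3)
        assert p1 == p2 == p3
        assert d1 == pytest.approx(d2) == pytest.approx(d3)
        assert (cv1, cn1) == (cv2, cn2)

    def test_p_never_zero_and_bounded(self, rng):
        # strong planted attenuation: the smallest achievable p is 1/(n_perm+1)
        a = rng.normal(size=200)
        eps1, eps2 = rng.normal(0, 0.3, 200), rng.normal(0, 0.3, 200)
        coup = np.where(np.arange(200) < 100, 0.05, 0.9)
        x = _series(5 - coup * a + eps1, "s")
        y = _series(5 - coup * a + eps2, "s")
        ab, no = set(x.index[:100]), set(x.index[100:])
        p, *_ = permutation_test(x, y, ab, no, n_perm=500, seed=1)
        assert p == pytest.approx(1 / 501)

    def test_constant_group_raises(self):
        xs = _series([1.0] * 6 + [1, 2, 3, 4, 5, 6], "s")
        ys = _series(np.arange(12, dtype=float), "s")
        with pytest.raises(ValueError, match="undefined"):
            permutation_test(xs, ys, set(xs.index[:6]), set(xs.index[6:]),
                             n_perm=100, seed=0)

    def test_power_on_planted_attenuation(self, rng):
        """Attenuation 0.1 at coupling 0.8, 150+150 samples: p <= 0.005 in
        at least 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            a = r.normal(size=300)
            coup = np.where(np.arange(300) < 150, 0.08, 0.8)
            x = _series(5 - coup * a + r.normal(0, 0.3, 300), "s")
            y = _series(5 - coup * a + r.normal(0, 0.3, 300), "s")
            p, *_ = permutation_test(x, y, set(x.index[:150]), set(x.index[150:]),
                                     n_perm=1000, seed=seed)
            hits += p <= 0.005
        assert hits >= 0.9 * n_seeds


def _triplet(a, b, m, status):
    return CandidateTriplet(a, b, m, status, 0.8, 0.01, -0.8, 0.01, -0.8, 0.01, 50)


class TestCallPairs:
    def test_near_equal_correlations_not_returned(self, rng):
        a = rng.normal(size=200)
        expr = pd.DataFrame(
            [5 - 0.8 * a + rng.normal(0, 0.3, 200),
             5 - 0.8 * a + rng.normal(0, 0.3, 200)],
            index=["A", "B"], columns=[f"s{i}" for i in range(200)],
        )
        ab = set(expr.columns[:60]); no = set(expr.columns[60:])
        sig, tested = call_dysregulated_pairs(
            {"deletion": [_triplet("A", "B", "mi1", "deletion")]},
            "DRV", "deletion", expr, ab, no, n_perm=300, seed=0)
        assert sig == []
        assert len(tested) == 1 and not tested["significant"].iloc[0]

    def test_pair_qualifying_in_one_status_still_gets_other_status_correlation(self, rng):
        a = rng.normal(size=200)
        coup = np.where(np.arange(200) < 60, 0.05, 0.9)  # decoupled in aberrant
        expr = pd.DataFrame(
            [5 - coup * a + rng.normal(0, 0.25, 200),
             5 - coup * a + rng.normal(0, 0.25, 200)],
            index=["A", "B"], columns=[f"s{i}" for i in range(200)],
        )
        ab = set(expr.columns[:60]); no = set(expr.columns[60:])
        # candidate only in the normal status; aberrant-side correlation must
        # still be computed from the aberrant samples
        sig, tested = call_dysregulated_pairs(
            {"normal": [_triplet("A", "B", "mi1", "normal")]},
            "DRV", "deletion", expr, ab, no, n_perm=500, seed=0)
        assert len(sig) == 1
        pair = sig[0]
        assert pair.direction == WEAKENED
        assert pair.cor_n > 0.5 and pair.cor_v < 0.5
        assert pair.supporting_mirnas == {"mi1"}

    def test_mirnas_accumulate_on_one_pair(self, rng):
        a = rng.normal(size=150)
        coup = np.where(np.arange(150) < 50, 0.05, 0.9)
        expr = pd.DataFrame(
            [5 - coup * a + rng.normal(0, 0.25, 150),
             5 - coup * a + rng.normal(0, 0.25, 150)],
            index=["A", "B"], columns=[f"s{i}" for i in range(150)],
        )
        ab = set(expr.columns[:50]); no = set(expr.columns[50:])
        sig, tested = call_dysregulated_pairs(
            {"normal": [_triplet("A", "B", "mi1", "normal"),
                        _triplet("A", "B", "mi2", "normal")]},
            "DRV", "deletion", expr, ab, no, n_perm=500, seed=0)
        assert len(tested) == 1  # tested once, not per miRNA
        assert sig[0].supporting_mirnas == {"mi1", "mi2"}

    def test_small_status_produces_nothing(self, rng):
        expr = pd.DataFrame(
            np.abs(rng.normal(5, 1, size=(2, 10))),
            index=["A", "B"], columns=[f"s{i}" for i in range(10)],
        )
        sig, tested = call_dysregulated_pairs(
            {"normal": [_triplet("A", "B", "mi1", "normal")]},
            "DRV", "deletion", expr, set(expr.columns[:3]), set(expr.columns[3:]),
            n_perm=100, seed=0, min_samples=5)
        assert sig == [] and tested.empty


class TestFisherZCrossCheck:
    def test_large_correlation_difference_is_significant(self):
        from cnvcerna.dysregulation import fisher_z_test

        z, p = fisher_z_test(0.1, 0.85, 100, 100)
        assert p < 1e-6 and z < 0

    def test_equal_correlations_give_z_zero(self):
        from cnvcerna.dysregulation import fisher_z_test

        z, p = fisher_z_test(0.5, 0.5, 50, 80)
        assert z == 0.0 and p == 1.0

    def test_agrees_with_permutation_on_strong_effect(self, rng):
        from cnvcerna.dysregulation import fisher_z_test

        a = rng.normal(size=200)
        coup = np.where(np.arange(200) < 100, 0.1, 0.9)
        x = _series(5 - coup * a + rng.normal(0, 0.3, 200), "s")
        y = _series(5 - coup * a + rng.normal(0, 0.3, 200), "s")
        ab, no = set(x.index[:100]), set(x.index[100:])
        perm_p, _, cv, cn = permutation_test(x, y, ab, no, n_perm=500, seed=0)
        _, z_p = fisher_z_test(cv, cn, 100, 100)
        assert perm_p < 0.01 and z_p < 0.01
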