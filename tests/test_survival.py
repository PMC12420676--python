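import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoquant import survival, synthdata
from nucleoquant.survival import (
    assign_quadrant,
    cohort_analysis,
    fisher_exact,
    km_fit,
    km_median,
    logrank,
)


class TestAssignQuadrant:
    def test_paper_style_point(self):
        assert assign_quadrant(600.0, 4000.0) == "G3+/O-"

    def test_boundary_is_negative(self):
        assert assign_quadrant(533.0, 4133.0) == "G3-/O-"

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(-1.0, 100.0)

    def test_matches_brute_force_grid(self):
        grid = np.linspace(0, 8000, 33)
        for g3 in grid:
            for ot in grid:
                q = assign_quadrant(g3, ot)
                expected = (
                    ("G3+" if g3 > 533 else "G3-") + "/" + ("O+" if ot > 4133 else "O-")
                )
                assert q == expected

    def test_partition_is_exhaustive(self, rng):
        pts = rng.uniform(0, 10000, size=(500, 2))
        quads = {assign_quadrant(a, b) for a, b in pts}
        assert quads <= set(survival.QUADRANTS)


def _km_oracle(times, events):
    """Hand product-limit: S multiplies (1 - d/n) at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out.append((t, s))
    return out


class TestKaplanMeier:
    def test_hand_example(self):
        curve = km_fit([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        assert curve.median == 3.0

    def test_all_censored(self):
        curve = km_fit([5, 6, 7], [0, 0, 0])
        assert curve.survival.size == 0
        assert km_median(curve) is None

    def test_median_at_exact_half_is_inclusive(self):
        # 2 subjects, 1 event -> S drops to exactly 0.5 at t=1? use 4 subjects
        curve = km_fit([1, 1, 2, 2], [1, 1, 0, 0])
        assert curve.survival[0] == pytest.approx(0.5)
        assert curve.median == 1.0

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 100))
            times = np.round(rng.exponential(10, n), 1)
            events = (rng.random(n) < 0.7).astype(int)
            if events.sum() == 0:
                events[0] = 1
            curve = km_fit(times, events)
            oracle = _km_oracle(times, events)
            assert len(oracle) == curve.survival.size
            for (t, s), tc, sc in zip(oracle, curve.event_times, curve.survival):
                assert t == tc and s == pytest.approx(sc)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(100, 80)
        events = (rng.random(80) < 0.6).astype(int)
        curve = km_fit(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert kmf.survival_function_at_times(t).iloc[0] == pytest.approx(s)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(3)
        lam = 1 / 500.0
        times = rng.exponential(1 / lam, 5000)
        curve = km_fit(times, np.ones(5000, int))
        t_half = np.log(2) / lam
        assert curve.survival_at(t_half) == pytest.approx(0.5, abs=0.03)
        assert curve.median == pytest.approx(t_half, rel=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])


def _logrank_2sample_oracle(t1, e1, t2, e2):
    """Independently coded closed-form 2-sample statistic."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at = t >= ti
        n = at.sum()
        n1 = (at & (g == 0)).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = logrank([(t, e), (t, e)])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_sample_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            t1 = rng.exponential(10, 25)
            t2 = rng.exponential(20, 30)
            e1 = (rng.random(25) < 0.8).astype(int)
            e2 = (rng.random(30) < 0.8).astype(int)
            res = logrank([(t1, e1), (t2, e2)])
            assert res.chi2 == pytest.approx(
                _logrank_2sample_oracle(t1, e1, t2, e2), rel=1e-9
            )

    def test_matches_lifelines_k_sample(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(50, 90)
        e = (rng.random(90) < 0.7).astype(int)
        g = rng.integers(0, 4, 90)
        res = logrank([(t[g == k], e[g == k]) for k in range(4)])
        ref = multivariate_logrank_test(t, g, e)
        assert res.chi2 == pytest.approx(ref.test_statistic)
        assert res.p == pytest.approx(ref.p_value)

    def test_group_relabel_invariance(self, rng):
        t = rng.exponential(30, 60)
        e = (rng.random(60) < 0.8).astype(int)
        g = rng.integers(0, 3, 60)
        groups = [(t[g == k], e[g == k]) for k in range(3)]
        a = logrank(groups)
        b = logrank(groups[::-1])
        assert a.chi2 == pytest.approx(b.chi2)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            logrank([([1.0], [1])])


class TestFisherExact:
    def test_2x2_matches_hypergeom_enumeration(self):
        table = np.array([[1, 9], [11, 3]])
        res = fisher_exact(table)
        # direct hypergeometric tail enumeration oracle
        n = table.sum()
        r1 = table[0].sum()
        c1 = table[:, 0].sum()
        p_obs = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        p_oracle = sum(
            stats.hypergeom.pmf(k, n, r1, c1)
            for k in range(max(0, c1 - table[1].sum()), min(c1, r1) + 1)
            if stats.hypergeom.pmf(k, n, r1, c1) <= p_obs * (1 + 1e-7)
        )
        assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_2x2_matches_scipy(self, rng):
        for _ in range(10):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            res = fisher_exact(table)
            ref = stats.fisher_exact(table)[1]
            assert res.p == pytest.approx(ref, rel=1e-7)

    def test_identical_rows_p_one(self):
        res = fisher_exact([[5, 5, 5], [5, 5, 5]])
        assert res.p == pytest.approx(1.0)

    def test_rxc_exact_vs_monte_carlo(self):
        table = np.array([[4, 1, 2], [1, 5, 1], [2, 2, 8], [5, 6, 3]])
        assert table.sum() == 40
        exact = fisher_exact(table)
        assert exact.method == "exact"
        mc = fisher_exact(table, exact_total_limit=0, mc_draws=100_000, seed=1)
        assert mc.method == "monte-carlo"
        assert abs(mc.p - exact.p) <= 3 * mc.se

    def test_rxc_exact_matches_r_reference(self):
        # fisher.test reference value for this 3x3 table (R 4.3.3): 0.002156575
        table = [[10, 3, 2], [2, 8, 3], [1, 2, 7]]
        res = fisher_exact(table)
        assert res.method == "exact"
        assert res.p == pytest.approx(0.002156575, abs=1e-6)

    def test_zero_margin_dropped(self):
        res = fisher_exact([[3, 0, 4], [2, 0, 6]])
        ref = stats.fisher_exact([[3, 4], [2, 6]])[1]
        assert res.p == pytest.approx(ref, rel=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


class TestCohortAnalysis:
    def test_single_quadrant_skips_logrank(self):
        mix = {"G3+/O-": 1.0, "G3+/O+": 0.0, "G3-/O-": 0.0, "G3-/O+": 0.0}
        df = synthdata.make_cohort(
            synthdata.CohortSpec(n_samples=20, quadrant_mix=mix, seed=0)
        )
        report = cohort_analysis(df)
        assert report["logrank"]["skipped"]

    def test_report_structure(self):
        df = synthdata.make_cohort(synthdata.CohortSpec(n_samples=60, seed=5))
        report = cohort_analysis(df, seed=5)
        assert set(report["quadrants"]) == set(survival.QUADRANTS)
        assert not report["logrank"]["skipped"]
        assert 0.0 <= report["logrank"]["p"] <= 1.0
        assert "fisher" in report and 0.0 <= report["fisher"]["p"] <= 1.0
        ctab = np.array(report["contingency"]["table"])
        assert ctab.sum() == 60
        for q, entry in report["quadrants"].items():
            if entry["n"]:
                surv = entry["km"]["survival"]
                assert all(a >= b - 1e-12 for a, b in zip(surv, surv[1:]))

    def test_quadrant_counts_match_brute_force(self, rng):
        df = synthdata.make_cohort(synthdata.CohortSpec(n_samples=50, seed=7))
        report = cohort_analysis(df)
        for q in survival.QUADRANTS:
            brute = sum(
                1
                for g3, ot in zip(df["dens_g3"], df["dens_other"])
                if ((g3 > 533) == q.startswith("G3+")) and ((ot > 4133) == q.endswith("O+"))
            )
            assert report["quadrants"][q]["n"] == brute
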