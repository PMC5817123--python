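import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cannorm.population_norm import (
    anova_planned_contrasts,
    census_correlation_suite,
    population_distribution_stats,
    skewness,
    summaries_to_blocks,
)


class TestSkewness:
    def test_symmetric_triple_zero(self):
        assert skewness([-1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # m3/m2^1.5 = (2/27) / (2/9)^1.5 = 1/sqrt(2)
        assert skewness([0, 0, 1]) == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_sign_flip_under_negation(self, rng):
        v = rng.normal(size=20) ** 2
        assert skewness(-v) == pytest.approx(-skewness(v), abs=1e-12)

    def test_scipy_oracles(self, rng):
        v = rng.gamma(2, size=50)
        assert skewness(v) == pytest.approx(sps.skew(v, bias=True), abs=1e-12)
        assert skewness(v, bias_corrected=True) == pytest.approx(
            sps.skew(v, bias=False), abs=1e-12
        )

    def test_scale_invariance(self, rng):
        v = rng.gamma(2, size=30)
        assert skewness(3 * v + 7) == pytest.approx(skewness(v), abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            skewness([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            skewness([1.0, 2.0])


def _scores_frame(tanks):
    rows = []
    for tank_id, category, size, shape in tanks:
        for s, sh in zip(size, shape):
            rows.append(dict(tank_id=tank_id, category=category, pc1_size=s, pc1_shape=sh))
    return pd.DataFrame(rows)


class TestPopulationStats:
    def test_perfect_anticorrelation(self, rng):
        s = rng.normal(size=10)
        df = _scores_frame([("g1", "NonCannibal", s, -s), ("sol", "Solitary", s, s + rng.normal(size=10))])
        (sol, g1) = population_distribution_stats(df)
        assert g1.tank_id == "g1"
        assert g1.y1 == pytest.approx(-1.0, abs=1e-9)

    def test_solitary_pooled_first_with_zero_census(self, rng):
        s = rng.normal(size=8)
        df = _scores_frame(
            [("t7", "Solitary", s, rng.normal(size=8)), ("g1", "NonCannibal", s, s)]
        )
        out = population_distribution_stats(df)
        assert out[0].tank_id == "sol"
        assert (out[0].x1, out[0].x2) == (0, 0)

    def test_small_tank_excluded_with_warning(self, rng):
        df = _scores_frame(
            [
                ("g1", "NonCannibal", rng.normal(size=2), rng.normal(size=2)),
                ("g2", "NonCannibal", rng.normal(size=10), rng.normal(size=10)),
                ("sol", "Solitary", rng.normal(size=5), rng.normal(size=5)),
            ]
        )
        with pytest.warns(UserWarning, match="g1"):
            out = population_distribution_stats(df)
        assert [s.tank_id for s in out] == ["sol", "g2"]

    def test_independent_scores_small_y1(self):
        """Solitary-style tanks: |y1| mostly small at n = 200."""
        rng = np.random.default_rng(3)
        count = 0
        for _ in range(100):
            y1 = np.corrcoef(rng.normal(size=200), rng.normal(size=200))[0, 1]
            count += abs(y1) < 0.15
        assert count >= 95

    def test_generator_correlation_recovered(self):
        """Mean per-tank y1 over replicates matches the configured correlation."""
        rng = np.random.default_rng(4)
        target = -0.8
        vals = []
        for _ in range(200):
            z = rng.normal(size=30)
            shape = target * z + np.sqrt(1 - target**2) * rng.normal(size=30)
            vals.append(np.corrcoef(z, shape)[0, 1])
        assert np.mean(vals) == pytest.approx(target, abs=0.1)


class TestCensusSuite:
    def test_reproduces_published_census_statistics(self, census_summaries):
        suite = census_correlation_suite(census_summaries, n_perm=0)
        assert suite["rv_X_Y"]["value"] == pytest.approx(0.4847, abs=5e-5)
        assert suite["r_pls1_X_Y"]["value"] == pytest.approx(0.7083, abs=5e-5)
        assert suite["rv_x1_Y"]["value"] == pytest.approx(0.2481, abs=5e-5)
        assert suite["r_pls1_x1_Y"]["value"] == pytest.approx(0.5097, abs=5e-5)
        assert suite["r_pls1_x2_Y"]["value"] == pytest.approx(0.7213, abs=5e-5)
        assert suite["r_x2_y1"]["value"] == pytest.approx(-0.6845, abs=5e-5)
        assert suite["r_x2_y3"]["value"] == pytest.approx(-0.6035, abs=5e-5)

    def test_y2_statistics_match_definitional_recomputation(self, census_summaries):
        """The y2-involving entries equal a direct evaluation of their
        definitions on the table (independent of the suite plumbing)."""
        df, X, Y = summaries_to_blocks(census_summaries)
        suite = census_correlation_suite(census_summaries, n_perm=0)
        r_direct = np.corrcoef(df["x2"], df["y2"])[0, 1]
        assert suite["r_x2_y2"]["value"] == pytest.approx(r_direct, abs=1e-12)
        xc = X[:, [1]] - X[:, [1]].mean(0)
        yc = Y - Y.mean(0)
        num = np.trace(xc.T @ yc @ yc.T @ xc)
        den = np.sqrt(np.trace((xc.T @ xc) ** 2) * np.trace((yc.T @ yc) @ (yc.T @ yc)))
        assert suite["rv_x2_Y"]["value"] == pytest.approx(num / den, abs=1e-12)

    def test_permutation_p_values_present_and_significant(self, census_summaries):
        suite = census_correlation_suite(census_summaries, n_perm=999, seed=5)
        assert suite["rv_X_Y"]["p_value"] < 0.05
        assert suite["rv_x1_Y"]["p_value"] > 0.05  # cannibal count alone: ns

    def test_deterministic_given_seed(self, census_summaries):
        s1 = census_correlation_suite(census_summaries, n_perm=99, seed=8)
        s2 = census_correlation_suite(census_summaries, n_perm=99, seed=8)
        assert s1 == s2

    def test_shuffled_y_null_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(100):
            from cannorm.population_norm import PopulationSummary

            rows = [
                PopulationSummary(
                    f"g{i}", int(rng.integers(1, 5)), int(rng.integers(1, 9)),
                    float(rng.uniform(-0.9, 0.9)), float(rng.normal()), float(rng.normal()),
                )
                for i in range(11)
            ]
            suite = census_correlation_suite(rows, n_perm=49, seed=int(rng.integers(2**31)))
            ps.append(suite["rv_X_Y"]["p_value"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


def _anova_data(rng, means, n=20, sigma=1.0):
    values, pops, vics = [], [], []
    for i, (vic, mu) in enumerate(means):
        pop = "sol" if vic == 0 else f"g{i}"
        values.append(mu + sigma * rng.normal(size=n))
        pops += [pop] * n
        vics += [vic] * n
    return np.concatenate(values), np.array(pops), np.array(vics, float)


class TestPlannedContrastAnova:
    def test_ss_additivity_exact(self, rng):
        v, p, x = _anova_data(rng, [(0, 0), (1, 0.5), (3, 1.0), (5, 2.0), (7, 1.5)])
        tab = anova_planned_contrasts(v, p, x, decomposition="regression").rows
        ss = dict(zip(tab["source"], tab["SS"]))
        assert ss["Regression slope"] + ss["Deviation from regression"] == pytest.approx(
            ss["Among groups"], abs=1e-9
        )
        tab2 = anova_planned_contrasts(v, p, x, decomposition="nonzero").rows
        ss2 = dict(zip(tab2["source"], tab2["SS"]))
        assert ss2["Solitary vs rest"] + ss2["Among nonzero victim groups"] == pytest.approx(
            ss2["Among groups"], abs=1e-9
        )

    def test_linear_means_zero_deviation(self, rng):
        # group means exactly linear in victim count, equal group sizes
        means = [(v, 0.3 * v) for v in (0, 2, 4, 6, 8)]
        v, p, x = _anova_data(rng, means, sigma=0.0)
        v = v + 0.0
        tab = anova_planned_contrasts(v, p, x).rows
        ss = dict(zip(tab["source"], tab["SS"]))
        assert ss["Deviation from regression"] == pytest.approx(0.0, abs=1e-9)

    def test_df_pattern_mirrors_mixed_testing_scheme(self, rng):
        v, p, x = _anova_data(rng, [(0, 0), (1, 0), (3, 0), (5, 0), (9, 0)])
        tab = anova_planned_contrasts(v, p, x).rows.set_index("source")
        assert tab.loc["Regression slope", ["df_num", "df_den"]].tolist() == [1, 3]
        assert tab.loc["Deviation from regression", "df_den"] == len(v) - 5
        assert tab.loc["Solitary vs rest", "df_den"] == len(v) - 5

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(17)
        rej = {"Solitary vs rest": 0, "Regression slope": 0}
        n_sim = 400
        for _ in range(n_sim):
            v, p, x = _anova_data(
                rng, [(v_, 0.0) for v_ in (0, 1, 2, 4, 6, 9)], n=12, sigma=1.0
            )
            tab = anova_planned_contrasts(v, p, x).rows.set_index("source")
            for key in rej:
                rej[key] += tab.loc[key, "p"] < 0.05
        for key, count in rej.items():
            assert count / n_sim == pytest.approx(0.05, abs=0.025), key

    def test_solitary_shift_detected(self):
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(100):
            v, p, x = _anova_data(
                rng, [(0, 2.0), (1, 0), (3, 0), (5, 0), (7, 0)], n=15, sigma=1.0
            )
            tab = anova_planned_contrasts(v, p, x).rows.set_index("source")
            hits += tab.loc["Solitary vs rest", "p"] < 0.01
        assert hits >= 95

    def test_insufficient_groups_rejected(self, rng):
        v, p, x = _anova_data(rng, [(0, 0), (3, 0)])
        with pytest.raises(ValueError):
            anova_planned_contrasts(v, p, x)
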