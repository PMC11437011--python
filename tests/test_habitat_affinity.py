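import numpy as np
import pandas as pd
import pytest

from seascape_biogeo import (NullSettings, TableValidationError,
                             affinity_ensemble, aggregate_affinity,
                             exact_null_p, habitat_means, null_affinity_p,
                             relative_abundance, rng_for)
from conftest import make_ensemble, labels_series


class TestRelativeAbundance:
    def test_arithmetic(self):
        member = np.array([[2], [3], [5]])
        props = relative_abundance(member, depth=10)
        np.testing.assert_allclose(props.ravel(), [0.2, 0.3, 0.5])

    def test_boundaries(self):
        member = np.array([[0], [10]])
        props = relative_abundance(member, depth=10)
        assert props[0, 0] == 0.0 and props[1, 0] == 1.0

    def test_zero_depth_rejected(self):
        with pytest.raises(TableValidationError, match="depth"):
            relative_abundance(np.zeros((1, 1)), depth=0)


class TestHabitatMeans:
    def test_uniform_taxon(self):
        props = np.full(6, 0.01)
        labels = np.array(["A", "A", "B", "B", "C", "C"])
        mu, overall = habitat_means(props, labels, ("A", "B", "C"))
        np.testing.assert_allclose(mu, 0.01)
        assert overall == pytest.approx(0.01)

    def test_two_habitat_example(self):
        props = np.array([0.4, 0.2, 0.0, 0.0])
        labels = np.array(["A", "A", "B", "B"])
        mu, overall = habitat_means(props, labels, ("A", "B"))
        np.testing.assert_allclose(mu, [0.3, 0.0])
        assert overall == pytest.approx(0.15)

    def test_weighted_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 12)
            props = rng.random(n)
            labels = rng.choice(["A", "B", "C"], size=n)
            habs = tuple(h for h in ("A", "B", "C") if (labels == h).any())
            mu, overall = habitat_means(props, labels, habs)
            n_h = np.array([(labels == h).sum() for h in habs])
            assert (n_h * mu).sum() == pytest.approx(n * overall)

    def test_empty_habitat_flagged_nan(self):
        mu, overall = habitat_means(np.array([0.1, 0.2]),
                                    np.array(["A", "A"]), ("A", "B"))
        assert np.isnan(mu[1])


class TestNullP:
    def test_actual_at_maximum_gives_zero(self):
        # habitat A holds the two unique maximal values: no surrogate mean
        # can strictly exceed the actual mean
        props = np.array([0.6, 0.6, 0.1, 0.1])
        labels = np.array(["A", "A", "B", "B"])
        p = null_affinity_p(props, labels, ("A", "B"),
                            NullSettings(surrogate_count=500, seed=0),
                            rng_for(0, "t"))
        assert p[0] == 0.0

    def test_constant_taxon_guard_reports_one(self):
        props = np.full(6, 0.25)
        labels = np.array(["A", "A", "B", "B", "C", "C"])
        p = null_affinity_p(props, labels, ("A", "B", "C"),
                            NullSettings(surrogate_count=100, seed=0),
                            rng_for(0, "t"))
        np.testing.assert_array_equal(p, 1.0)

    def test_exact_enumeration_closed_form(self):
        # N=5, proportions (0.5,0,0,0,0), habitats (A,A,B,B,B):
        # p_A = P(both A draws pick the 0.5 sample) = 1/25
        # p_B = P(at least one of 3 B draws picks it) = 1 - (4/5)^3 = 61/125
        props = np.array([0.5, 0, 0, 0, 0.0])
        labels = np.array(["A", "A", "B", "B", "B"])
        p = exact_null_p(props, labels, ("A", "B"))
        assert p[0] == pytest.approx(1 / 25)
        assert p[1] == pytest.approx(61 / 125)

    def test_monte_carlo_matches_enumeration(self):
        props = np.array([0.5, 0, 0, 0, 0.0])
        labels = np.array(["A", "A", "B", "B", "B"])
        exact = exact_null_p(props, labels, ("A", "B"))
        B = 2000
        p = null_affinity_p(props, labels, ("A", "B"),
                            NullSettings(surrogate_count=B, seed=1),
                            rng_for(1, "t"))
        for j in range(2):
            tol = 3 * np.sqrt(exact[j] * (1 - exact[j]) / B)
            assert abs(p[j] - exact[j]) <= tol

    def test_monotone_in_habitat_proportions(self):
        # raising the taxon only within habitat A must not raise p_A
        rng = np.random.default_rng(2)
        for _ in range(10):
            props = rng.random(5).round(2)
            labels = np.array(["A", "A", "B", "B", "B"])
            p0 = exact_null_p(props, labels, ("A", "B"))[0]
            boosted = props.copy()
            boosted[:2] += rng.random(2).round(2) + 0.01
            p1 = exact_null_p(boosted, labels, ("A", "B"))[0]
            assert p1 <= p0 + 1e-12


class TestAggregate:
    def test_mean_p_against_alpha(self):
        settings = NullSettings(alpha=0.05)
        res = aggregate_affinity(np.array([[0.02], [0.04], [0.06]]),
                                 settings, ("A",))
        assert res["p_bar"][0] == pytest.approx(0.04)
        assert res["affinity_set"] == {"A"}

    def test_all_ones_no_affinity(self):
        res = aggregate_affinity(np.ones((5, 3)), NullSettings(), ("A", "B", "C"))
        assert res["affinity_count"] == 0

    def test_absent_members_skipped_and_counted(self):
        pvals = np.array([[0.01, 1.0], [np.nan, np.nan], [0.03, 1.0]])
        res = aggregate_affinity(pvals, NullSettings(), ("A", "B"))
        assert res["members_skipped"] == 1
        assert res["p_bar"][0] == pytest.approx(0.02)

    def test_fully_absent_rejected(self):
        with pytest.raises(TableValidationError, match="absent"):
            aggregate_affinity(np.full((3, 2), np.nan), NullSettings(), ("A", "B"))


class TestAffinityEnsemble:
    def planted_ensemble(self, boost_habitats=("PSUW", "ENPCW"), n_per=16):
        """Three habitats of n_per samples; taxon 0 strongly enriched in
        boost_habitats, taxon 1 the complement."""
        rng = np.random.default_rng(5)
        labels = ["PSUW"] * n_per + ["ENPCW"] * n_per + ["PEW"] * n_per
        sample_ids = [f"s{j}" for j in range(3 * n_per)]
        depth = 200
        members = []
        for _ in range(6):
            m = np.empty((2, 3 * n_per), dtype=int)
            for j, lab in enumerate(labels):
                hi = lab in boost_habitats
                a = rng.integers(95, 106) if hi else rng.integers(1, 6)
                m[0, j] = a
                m[1, j] = depth - a
            members.append(m)
        return make_ensemble(members, depth=depth, sample_ids=sample_ids), \
            labels_series(labels, sample_ids)

    def test_planted_two_habitat_affinity_recovered(self):
        ens, series = self.planted_ensemble()
        res = affinity_ensemble(ens, series,
                                NullSettings(surrogate_count=400, seed=3))
        row = res.table.set_index("asv_id").loc["asv0"]
        assert set(row["affinity_set"].split(",")) == {"PSUW", "ENPCW"}
        assert row["affinity_count"] == 2

    def test_affinity_count_never_three(self):
        rng = np.random.default_rng(7)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        sample_ids = [f"s{j}" for j in range(9)]
        members = [rng.multinomial(100, np.ones(4) / 4, size=9).T
                   for _ in range(4)]
        ens = make_ensemble(members, depth=100, sample_ids=sample_ids)
        res = affinity_ensemble(ens, labels_series(labels, sample_ids),
                                NullSettings(surrogate_count=200, seed=7))
        assert res.table["affinity_count"].max() <= 2

    def test_mu_columns_satisfy_weighted_identity(self):
        ens, series = self.planted_ensemble()
        res = affinity_ensemble(ens, series,
                                NullSettings(surrogate_count=100, seed=1))
        n_h = series.value_counts()
        for _, row in res.table.iterrows():
            lhs = sum(n_h[h] * row[f"mu_{h}"] for h in res.habitats)
            assert lhs == pytest.approx(len(series) * row["mu_overall"])

    def test_absent_policy_error_raises(self):
        m1 = np.array([[5, 5, 0, 0, 0, 0], [0, 0, 5, 5, 5, 5]])
        m2 = np.array([[0, 0, 0, 0, 0, 0], [5, 5, 5, 5, 5, 5]])
        sample_ids = [f"s{j}" for j in range(6)]
        labels = labels_series(["A"] * 3 + ["B"] * 3, sample_ids)
        ens = make_ensemble([m1, m2], depth=5, sample_ids=sample_ids)
        with pytest.raises(TableValidationError, match="absent"):
            affinity_ensemble(ens, labels,
                              NullSettings(surrogate_count=10, seed=0,
                                           absent_policy="error"))
        res = affinity_ensemble(ens, labels,
                                NullSettings(surrogate_count=10, seed=0))
        assert res.table.set_index("asv_id").loc["asv0", "members_skipped"] == 1

    def test_per_taxon_seeding_is_order_independent(self):
        ens, series = self.planted_ensemble()
        full = affinity_ensemble(ens, series,
                                 NullSettings(surrogate_count=300, seed=9))
        sub = affinity_ensemble(ens.select_asvs(np.array([True, False])), series,
                                NullSettings(surrogate_count=300, seed=9))
        pd.testing.assert_series_equal(
            full.table.iloc[0].drop("asv_id"),
            sub.table.iloc[0].drop("asv_id"), check_names=False)
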