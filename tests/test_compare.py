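"""Exclusion filters, exact paired tests and multiplicity adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aerospore.compare import (
    ALLERGEN_GENERA,
    GROUPS,
    coverage_exclude,
    holm_adjust,
    io_ratio,
    log10_with_pseudocount,
    mann_whitney,
    paired_compare,
    pairwise_group_tests,
    prevalence_filter,
    wilcoxon_exact,
)


def _design(n_residences=12):
    rows = []
    for r in range(n_residences):
        for loc in ("indoor", "outdoor"):
            for group in GROUPS:
                rows.append(
                    dict(
                        sample_id=f"R{r + 1:02d}_{loc}_{group}",
                        residence_id=f"R{r + 1:02d}",
                        location=loc,
                        group=group,
                    )
                )
    return pd.DataFrame(rows)


class TestCoverageExclude:
    def test_two_bad_residences_leave_sixty_samples(self):
        design = _design(12)
        cov = pd.Series(1.0, index=design["sample_id"])
        cov["R03_indoor_passive_1day"] = 0.95
        cov["R07_outdoor_active_combined"] = 0.90
        retained, excluded = coverage_exclude(design, cov)
        assert excluded == ["R03", "R07"]
        assert len(retained) == 60
        assert retained["residence_id"].nunique() == 10

    def test_all_above_threshold_identity(self):
        design = _design(5)
        cov = pd.Series(0.999, index=design["sample_id"])
        retained, excluded = coverage_exclude(design, cov)
        assert excluded == []
        assert len(retained) == len(design)

    def test_single_low_sample_drops_whole_residence(self):
        design = _design(3)
        cov = pd.Series(1.0, index=design["sample_id"])
        cov["R02_indoor_passive_1day"] = 0.72
        retained, excluded = coverage_exclude(design, cov)
        assert excluded == ["R02"]
        assert len(retained) == 12  # 2 residences x 2 locations x 3 groups

    def test_missing_coverage_rejected(self):
        design = _design(2)
        cov = pd.Series(1.0, index=design["sample_id"][:-1])
        with pytest.raises(ValueError):
            coverage_exclude(design, cov)


class TestPrevalenceFilter:
    def test_boundary_at_half(self):
        n = 60
        table = pd.DataFrame(
            {f"s{i}": [1 if i < 30 else 0, 1 if i < 29 else 0, 1]
             for i in range(n)},
            index=["in30", "in29", "everywhere"],
        )
        kept = prevalence_filter(table, 0.5)
        assert "in30" in kept and "everywhere" in kept
        assert "in29" not in kept

    def test_allergen_intersection(self):
        genera = list(ALLERGEN_GENERA) + ["Rarus"]
        table = pd.DataFrame(
            {f"s{i}": [1] * 8 + [1 if i == 0 else 0] for i in range(10)},
            index=genera,
        )
        kept = prevalence_filter(table)
        assert sorted(set(kept) & set(ALLERGEN_GENERA)) == sorted(ALLERGEN_GENERA)
        assert "Rarus" not in kept


class TestLog10Pseudocount:
    @pytest.mark.parametrize("value,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_reference_points(self, value, expected):
        assert log10_with_pseudocount([value])[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log10_with_pseudocount([-1.0])


def _wilcoxon_oracle(d):
    """Full 2^n enumeration of sign assignments on mid-ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_low = (ws <= w_obs + 1e-9).mean()
    p_high = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxonExact:
    def test_all_positive_differences_minimum_p(self):
        w, p, degen = wilcoxon_exact(np.array([1, 2, 3, 4, 5.0]), np.zeros(5))
        assert w == pytest.approx(15.0)
        assert p == pytest.approx(2 / 32)
        assert not degen

    def test_identical_series_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        w, p, degen = wilcoxon_exact(x, x)
        assert p == 1.0 and degen

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            # half-integer values force ties and occasional zeros
            d = np.round(rng.normal(0, 2, n) * 2) / 2
            if np.all(d == 0):
                continue
            _, p, _ = wilcoxon_exact(d, np.zeros(n))
            assert p == pytest.approx(_wilcoxon_oracle(d), abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            d = rng.normal(0.5, 1.0, 9)  # continuous: no ties, no zeros
            _, p, _ = wilcoxon_exact(d, np.zeros(9))
            expected = stats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(expected, abs=1e-12)


class TestPairedCompare:
    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [2, 3, 4])

    def test_identical_pairs_flagged(self):
        r = paired_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.p_raw == 1.0 and r.degenerate

    def test_normal_homoscedastic_selects_paired_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 1, 12)
        y = x + rng.normal(0.5, 1, 12)
        r = paired_compare(x, y)
        assert r.test_used == "paired_t"
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert r.p_raw == pytest.approx(stats.ttest_rel(x, y).pvalue, rel=1e-12)

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 1, 12) ** 2
        y = np.zeros(12)
        r = paired_compare(x, y)
        assert r.test_used == "wilcoxon_exact"

    def test_power_and_type_i_error(self):
        """At n = 10 pairs the gate+test keeps type-I error near nominal and
        has reasonable power for a 1-SD shift."""
        rng = np.random.default_rng(99)
        n_sim = 1000
        rejections_null = rejections_alt = 0
        for _ in range(n_sim):
            x = rng.normal(0, 1, 10)
            y_null = x + rng.normal(0, 1, 10)
            y_alt = x + rng.normal(1.0, 1, 10)
            if paired_compare(x, y_null).p_raw < 0.05:
                rejections_null += 1
            if paired_compare(x, y_alt).p_raw < 0.05:
                rejections_alt += 1
        assert rejections_null / n_sim <= 0.07
        assert rejections_alt / n_sim >= 0.5


class TestHolm:
    def test_hand_step_down(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_adjusted_dominates_raw_and_caps_at_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, 10)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_idempotent_on_monotone_adjusted(self):
        adj = holm_adjust([0.01, 0.02, 0.03])
        # dividing by family-size factors reconstructs inputs whose second
        # pass reproduces the same adjusted values
        np.testing.assert_allclose(holm_adjust(adj / [3, 2, 1]), adj)

    def test_matches_hand_rolled_step_down_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(1e-4, 1, int(rng.integers(1, 8)))
            order = np.argsort(p)
            m = len(p)
            running, out = 0.0, np.empty(m)
            for k, idx in enumerate(order):
                running = max(running, (m - k) * p[idx])
                out[idx] = min(1.0, running)
            np.testing.assert_allclose(holm_adjust(p), out, atol=1e-12)


class TestIORatio:
    def test_simple_ratio(self):
        assert io_ratio(10.0, 5.0).ratio == pytest.approx(2.0)

    def test_equal_values(self):
        assert io_ratio(7.0, 7.0).ratio == pytest.approx(1.0)

    def test_zero_indoor_invalid(self):
        r = io_ratio(0.0, 5.0)
        assert not r.valid and r.invalid_reason == "zero"

    def test_zero_outdoor_undefined(self):
        r = io_ratio(5.0, 0.0)
        assert not r.valid and r.invalid_reason == "undefined"


def _mw_oracle(x, y):
    """Exhaustive rank-split enumeration, written independently."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        ranks[list(c)].sum() - n1 * (n1 + 1) / 2
        for c in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.array(us)
    lo = (us <= u_obs + 1e-9).mean()
    hi = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_complete_separation_small_groups(self):
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_identical_multisets_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p, _ = mann_whitney(x, x)
        assert p == 1.0

    def test_matches_independent_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            x = np.round(rng.normal(0, 2, n1))
            y = np.round(rng.normal(0.5, 2, n2))
            _, p, method = mann_whitney(x, y)
            assert method == "exact"
            assert p == pytest.approx(_mw_oracle(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n10_10(self):
        rng = np.random.default_rng(31)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 10)
        _, p_exact, _ = mann_whitney(x, y, method="exact")
        _, p_asym, _ = mann_whitney(x, y, method="asymptotic")
        assert abs(p_exact - p_asym) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPairwiseGroupTests:
    def test_family_structure_and_holm_within_location(self):
        rng = np.random.default_rng(44)
        rows = []
        for r in range(10):
            for loc in ("indoor", "outdoor"):
                base = rng.normal(5, 1)
                for g, shift in zip(GROUPS, (0.0, 0.2, 2.0)):
                    rows.append(
                        dict(residence_id=f"R{r:02d}", location=loc, group=g,
                             value=base + shift + rng.normal(0, 0.3))
                    )
        results = pairwise_group_tests(pd.DataFrame(rows), metric="demo")
        assert len(results) == 6  # 3 pairs x 2 locations
        for loc in ("indoor", "outdoor"):
            family = [r for r in results if r.location == loc]
            assert len(family) == 3
            raws = [r.p_raw for r in family]
            np.testing.assert_allclose(
                [r.p_holm for r in family], holm_adjust(raws), atol=1e-12
            )
            assert all(r.n_pairs == 10 for r in family)
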