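"""Group-equalized point-biserial statistic, combo search, permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from orchardnet.containers import CountMatrix
from orchardnet.indicator import (
    association_network,
    best_combination,
    indicator_analysis,
    indicator_analysis_array,
    permutation_test,
    rg_statistic,
    stratum_combinations,
)

LABELS6 = np.array(["g1", "g1", "g1", "g2", "g2", "g2"], dtype=object)


class TestRgStatistic:
    def test_hand_computed_value(self):
        # r = 7.5 / sqrt(41.5 * 1.5); equal groups => r.g equals plain r
        got = rg_statistic([5, 6, 7, 0, 1, 2], {"g1"}, LABELS6)
        assert got == pytest.approx(7.5 / np.sqrt(41.5 * 1.5), abs=1e-9)
        assert got == pytest.approx(0.9506, abs=1e-3)

    def test_complement_combo_flips_sign(self):
        a = rg_statistic([5, 6, 7, 0, 1, 2], {"g1"}, LABELS6)
        b = rg_statistic([5, 6, 7, 0, 1, 2], {"g2"}, LABELS6)
        assert b == pytest.approx(-a)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rg_statistic([3, 3, 3, 3, 3, 3], {"g1"}, LABELS6)

    @given(st.lists(st.integers(0, 100), min_size=6, max_size=6)
           .filter(lambda v: len(set(v)) > 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equal_groups_reduce_to_pearson_point_biserial(self, abundance):
        ours = rg_statistic(abundance, {"g1"}, LABELS6)
        indicator_vec = [1, 1, 1, 0, 0, 0]
        ref = sps.pearsonr(abundance, indicator_vec).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_unequal_groups_equalized_weights(self):
        # stratum g1 has 1 site, g2 has 3: equalization gives the g1 site
        # the same total weight as the three g2 sites combined
        labels = np.array(["g1", "g2", "g2", "g2"], dtype=object)
        x = [10.0, 1.0, 2.0, 3.0]
        w = np.array([2.0, 2 / 3, 2 / 3, 2 / 3])
        y = np.array([1.0, 0, 0, 0])
        mx = (w * x).sum() / w.sum()
        my = (w * y).sum() / w.sum()
        num = (w * (x - mx) * (y - my)).sum()
        den = np.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum())
        assert rg_statistic(x, {"g1"}, labels) == pytest.approx(num / den, abs=1e-12)


class TestBestCombination:
    def test_combo_count_and_ordering(self):
        combos = stratum_combinations(["a", "b", "c"])
        assert len(combos) == 6
        assert combos[0] == ("a",) and combos[-1] == ("b", "c")
        assert len(stratum_combinations(list("abcde"))) == 30

    def test_planted_single_stratum_maximum(self):
        labels = np.array(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3, dtype=object)
        x = [9, 8, 10, 0, 1, 2, 1, 0, 2]
        combo, stat = best_combination(x, labels)
        assert combo == ("g1",)
        assert stat > 0.9

    def test_pair_combo_by_exhaustive_evaluation(self):
        labels = np.array(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3, dtype=object)
        x = np.array([7, 8, 9, 8, 7, 9, 0, 1, 0], dtype=float)
        combos = stratum_combinations(["g1", "g2", "g3"])
        stats = [rg_statistic(x, c, labels) for c in combos]
        combo, stat = best_combination(x, labels)
        assert combo == combos[int(np.argmax(stats))] == ("g1", "g2")
        assert stat == pytest.approx(max(stats))

    def test_too_many_strata_rejected(self):
        labels = np.array([f"g{i}" for i in range(6)], dtype=object)
        with pytest.raises(ValueError, match="capped"):
            best_combination(np.arange(6), labels)


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all(self):
        rng = np.random.default_rng(0)
        labels = np.array(["g1"] * 10 + ["g2"] * 10, dtype=object)
        x = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)])
        p, combo, stat = permutation_test(x, labels, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert combo == ("g1",)

    def test_n99_floor(self):
        rng = np.random.default_rng(0)
        labels = np.array(["g1"] * 10 + ["g2"] * 10, dtype=object)
        x = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)])
        p, _, _ = permutation_test(x, labels, n_perm=99, seed=1)
        assert p == pytest.approx(0.01)

    def test_n_perm_below_99_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1, 2, 3, 4], np.array(["a", "a", "b", "b"], dtype=object),
                             n_perm=10)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        labels = np.array(["g1"] * 8 + ["g2"] * 8, dtype=object)
        x = rng.poisson(5, 16).astype(float)
        r1 = permutation_test(x, labels, n_perm=199, seed=42)
        r2 = permutation_test(x, labels, n_perm=199, seed=42)
        assert r1 == r2

    def test_monotone_transform_invariance(self):
        """Permutation p depends on ranks of the permuted statistic, which a
        strictly monotone abundance transform shifts identically for observed
        and permuted values here (same permutations under the same seed)."""
        rng = np.random.default_rng(9)
        labels = np.array(["g1"] * 12 + ["g2"] * 12, dtype=object)
        x = rng.lognormal(1, 1, 24)
        p1, c1, _ = permutation_test(x, labels, n_perm=199, seed=3)
        p2, c2, _ = permutation_test(np.log(x), labels, n_perm=199, seed=3)
        # log is monotone but not linear: combo choice is preserved while the
        # p-value may move slightly; both must flag the same direction
        assert c1 == c2

    def test_type_one_error_calibration(self):
        """Exchangeable null: rejection rate at alpha=0.05 stays near 0.05."""
        rng = np.random.default_rng(123)
        n_taxa, n_sites = 400, 30
        labels = np.array(["g1", "g2", "g3"] * 10, dtype=object)
        X = rng.lognormal(2.0, 1.0, size=(n_taxa, n_sites))
        table = indicator_analysis_array(
            X, labels, [f"t{i}" for i in range(n_taxa)], n_perm=199, seed=77)
        rate = float((table["p_value"] < 0.05).mean())
        # 3 binomial SEs around 0.05 at n=400
        se = np.sqrt(0.05 * 0.95 / n_taxa)
        assert abs(rate - 0.05) <= 3 * se


class TestAssociationNetwork:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["taxon_id", "best_combo", "stat",
                                           "p_value", "n_perm"])

    def test_threshold_application(self):
        t = self.table([("t1", "g1", 0.9, 0.01, 999), ("t2", "g1+g2", 0.5, 0.2, 999)])
        g, summary = association_network(t)
        assert summary["n_significant"] == 1
        assert g.number_of_edges() == 1
        assert set(g.nodes) == {"t1", "g1"}

    def test_all_nonsignificant_empty(self):
        t = self.table([("t1", "g1", 0.9, 0.2, 999)])
        g, summary = association_network(t)
        assert g.number_of_edges() == 0 and summary["n_significant"] == 0

    def test_specialist_fraction(self):
        rows = [(f"t{i}", "g1", 0.9, 0.01, 999) for i in range(6)]
        rows += [(f"u{i}", "g1+g2", 0.9, 0.01, 999) for i in range(4)]
        _, summary = association_network(self.table(rows))
        assert summary["specialist_fraction"] == pytest.approx(0.6)
        assert summary["by_cardinality"] == {1: 6, 2: 4}
        assert summary["shared_pairs"] == {("g1", "g2"): 4}


def test_indicator_analysis_on_count_matrix(two_strata_metadata):
    rng = np.random.default_rng(21)
    ids = two_strata_metadata.sample_ids
    counts = rng.poisson(20, size=(4, len(ids)))
    counts[0, [j for j, s in enumerate(ids) if s.startswith("grassland")]] += 200
    m = CountMatrix([f"t{i}" for i in range(4)], ids, counts)
    table = indicator_analysis(m, two_strata_metadata, n_perm=199, seed=0)
    row = table.set_index("taxon_id").loc["t0"]
    assert row["best_combo"] == "grassland"
    assert row["p_value"] < 0.05
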