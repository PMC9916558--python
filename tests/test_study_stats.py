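"""Normalization, pooling and nonparametric tests, with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from explantkit.study_stats import (
    box_summary,
    kruskal_dunn,
    mw_holm_sidak,
    normalize_es,
    normalize_nt,
    pool_equal_shares,
    significance_stars,
    spearman_matrix,
)
from explantkit.synthetic_data import StudyGroup, StudySpec, generate_study_table


def _table(rows):
    return pd.DataFrame(rows)


class TestNormalizeNT:
    @staticmethod
    def _df():
        return _table(
            [
                {"treatment": "NT CTRL", "n_endings": v} for v in (80, 100, 120, 140)
            ]
            + [{"treatment": "BDNF", "n_endings": v} for v in (200, 300, 110)]
        )

    def test_control_median_maps_to_one(self):
        normed = normalize_nt(self._df(), "n_endings")
        ctrl = normed[normed.treatment == "NT CTRL"]["fold_change"]
        assert ctrl.median() == pytest.approx(1.0)

    def test_record_at_control_median(self):
        normed = normalize_nt(self._df(), "n_endings")
        assert normed.loc[normed.n_endings == 110, "fold_change"].iloc[0] == pytest.approx(1.0)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            normalize_nt(self._df(), "n_endings", control="nope")

    def test_zero_control_median_rejected(self):
        df = _table([{"treatment": "NT CTRL", "n_endings": 0}] * 4)
        with pytest.raises(ValueError, match="> 0"):
            normalize_nt(df, "n_endings")

    def test_treatment_effect_recovered(self):
        groups = (
            StudyGroup("NT CTRL", "apical", 200, 107.0, 316.0, is_control=True),
            StudyGroup("BDNF 25", "apical", 200, 9.93 * 107.0, 576.0),
        )
        tab = generate_study_table(StudySpec(groups=groups, seed=1))
        normed = normalize_nt(tab, "n_endings")
        fc = normed.loc[normed.treatment == "BDNF 25", "fold_change"].median()
        assert fc == pytest.approx(9.93, rel=0.10)


class TestNormalizeES:
    def test_per_plate_arithmetic(self):
        df = _table(
            [
                {"plate": "p1", "is_control": True, "n_endings": 100},
                {"plate": "p1", "is_control": False, "n_endings": 100},
                {"plate": "p2", "is_control": True, "n_endings": 200},
                {"plate": "p2", "is_control": False, "n_endings": 100},
            ]
        )
        normed = normalize_es(df, "n_endings")
        stim = normed[~normed.is_control].set_index("plate")["fold_change"]
        assert stim["p1"] == pytest.approx(1.0)
        assert stim["p2"] == pytest.approx(0.5)

    def test_plate_without_control_rejected(self):
        df = _table([{"plate": "p9", "is_control": False, "n_endings": 5}] * 3)
        with pytest.raises(ValueError, match="p9"):
            normalize_es(df, "n_endings")

    def test_effect_recovered_despite_plate_variance(self):
        # 6 plates of 8 wells (4 stimulated + 4 in-plate controls)
        groups = tuple(
            StudyGroup(t, turn, 8, m, 520.0, is_control=ctrl)
            for turn in ("apical", "middle", "basal")
            for t, m, ctrl in (("ES CTRL", 385.0, True), ("ES 1000", 0.62 * 385.0, False))
        )
        spec = StudySpec(
            groups=groups, design="es", plate_sd=0.25, endings_sigma=0.35,
            wells_per_plate=8, seed=0,
        )
        normed = normalize_es(generate_study_table(spec), "n_endings")
        fc = normed.loc[~normed.is_control, "fold_change"].median()
        assert fc == pytest.approx(0.62, rel=0.15)


class TestPooling:
    @staticmethod
    def _df(n_ap=24, n_mid=30, n_bas=18):
        rows = (
            [{"turn": "apical", "v": i} for i in range(n_ap)]
            + [{"turn": "middle", "v": i} for i in range(n_mid)]
            + [{"turn": "basal", "v": i} for i in range(n_bas)]
        )
        return _table(rows)

    def test_min_rule(self):
        pooled = pool_equal_shares(self._df(), seed=1)
        assert len(pooled) == 54
        assert (pooled["turn"].value_counts() == 18).all()

    def test_equal_n_is_identity(self):
        df = self._df(10, 10, 10)
        pooled = pool_equal_shares(df, seed=5)
        assert sorted(pooled.index) == sorted(df.index)

    def test_seed_determinism(self):
        a = pool_equal_shares(self._df(), seed=7)
        b = pool_equal_shares(self._df(), seed=7)
        assert a.index.tolist() == b.index.tolist()

    def test_absent_turn_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            pool_equal_shares(self._df(n_bas=0), seed=0)


class TestKruskalDunn:
    def test_identical_distributions_high_p(self):
        df = _table(
            [{"g": "ctrl", "v": v} for v in (1, 2, 3, 4, 5)]
            + [{"g": "t1", "v": v} for v in (1, 2, 3, 4, 5)]
        )
        # tied mean ranks: omnibus H is 0
        rep = kruskal_dunn(df, "v", "g", "ctrl")
        assert rep.omnibus["p"] > 0.99

    def test_all_identical_values(self):
        df = _table([{"g": g, "v": 7.0} for g in ("ctrl", "a", "b") for _ in range(5)])
        rep = kruskal_dunn(df, "v", "g", "ctrl")
        assert rep.omnibus["p"] == 1.0
        assert rep.comparisons.empty

    def test_matches_brute_force_oracle(self):
        # control + two groups; z and p recomputed from the rank formula
        ctrl = [1.0, 2.0, 3.0, 4.0, 5.0]
        g1 = [11.0, 12.0, 13.0, 14.0, 15.0]
        g2 = [2.5, 3.5, 6.0, 7.5, 9.0]
        df = _table(
            [{"g": "ctrl", "v": v} for v in ctrl]
            + [{"g": "g1", "v": v} for v in g1]
            + [{"g": "g2", "v": v} for v in g2]
        )
        rep = kruskal_dunn(df, "v", "g", "ctrl")
        pooled = np.array(ctrl + g1 + g2)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        ties = np.sum(counts**3 - counts)
        var = (n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))) * (1 / 5 + 1 / 5)
        for label, grp in (("g1 vs ctrl", slice(5, 10)), ("g2 vs ctrl", slice(10, 15))):
            z = (ranks[grp].mean() - ranks[:5].mean()) / np.sqrt(var)
            p_raw = 2 * stats.norm.sf(abs(z))
            row = rep.comparisons.set_index("label").loc[label]
            assert row["statistic"] == pytest.approx(z, abs=1e-10)
            assert row["p_raw"] == pytest.approx(p_raw, abs=1e-10)
            assert row["p_adj"] == pytest.approx(min(1.0, 2 * p_raw), abs=1e-10)

    def test_small_groups_rejected(self):
        df = _table([{"g": "ctrl", "v": 1}, {"g": "ctrl", "v": 2}, {"g": "a", "v": 3},
                     {"g": "a", "v": 4}, {"g": "a", "v": 5}])
        with pytest.raises(ValueError, match="n="):
            kruskal_dunn(df, "v", "g", "ctrl")


def _holm_sidak_oracle(raws):
    raws = np.asarray(raws, dtype=float)
    order = np.argsort(raws)
    m = len(raws)
    adj_sorted = 1.0 - (1.0 - raws[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestMWHolmSidak:
    def test_single_pair_unadjusted(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        rep = mw_holm_sidak({"only": (a, b)})
        row = rep.comparisons.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"], abs=1e-12)

    def test_matches_stepdown_oracle(self, rng):
        pairs = {}
        for i, shift in enumerate((0.0, 0.8, 1.6, 0.3)):
            pairs[f"pair{i}"] = (rng.normal(0, 1, 12), rng.normal(shift, 1, 12))
        rep = mw_holm_sidak(pairs)
        raws = rep.comparisons["p_raw"].to_numpy()
        expect = _holm_sidak_oracle(raws)
        assert np.allclose(rep.comparisons["p_adj"].to_numpy(), expect, atol=1e-12)

    def test_stepdown_formula_frozen_example(self):
        # raw (0.01, 0.04, 0.03) -> (0.029701, 0.0591, 0.0591)
        adj = _holm_sidak_oracle([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.029701, 0.059100, 0.059100], abs=1e-12)

    def test_identical_samples_not_significant(self):
        a = np.arange(10.0)
        rep = mw_holm_sidak({"same": (a, a.copy())})
        assert rep.comparisons["p_adj"].iloc[0] > 0.9

    def test_adjusted_at_least_raw(self, rng):
        pairs = {f"p{i}": (rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)) for i in range(5)}
        rep = mw_holm_sidak(pairs)
        assert (rep.comparisons["p_adj"] >= rep.comparisons["p_raw"] - 1e-15).all()


class TestSpearman:
    def test_monotone_extremes(self):
        df = _table([{"x": i, "y": i**3, "z": -i} for i in range(1, 11)])
        rho, _ = spearman_matrix(df, ["x", "y", "z"])
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        df = _table([{"x": a, "y": b} for a, b in zip(x, y)])
        rho, _ = spearman_matrix(df, ["x", "y"])
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(oracle, abs=1e-10)

    def test_constant_variable_nan(self):
        df = _table([{"x": i, "y": 5.0} for i in range(10)])
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert np.isnan(rho.loc["x", "y"])

    def test_generator_correlation_structure(self):
        groups = (StudyGroup("NT CTRL", "apical", 200, 107.0, 316.0, is_control=True),)
        tab = generate_study_table(StudySpec(groups=groups, seed=13))
        rho, _ = spearman_matrix(
            tab, ["n_endings", "total_length_um", "n_branch_points", "median_length_um"]
        )
        assert rho.loc["n_endings", "total_length_um"] > 0.9
        assert rho.loc["n_endings", "n_branch_points"] > 0.9


class TestBoxSummary:
    def test_quartile_convention(self):
        box = box_summary(np.arange(1.0, 101.0))
        assert box.q25 == pytest.approx(25.75)
        assert box.median == pytest.approx(50.5)
        assert box.q75 == pytest.approx(75.25)

    def test_constant_sample(self):
        box = box_summary([3.0] * 8)
        assert box.q25 == box.median == box.q75 == 3.0
        assert box.whisker_low == box.whisker_high == 3.0
        assert box.outliers == []

    def test_extreme_point_is_outlier(self):
        values = list(np.arange(1.0, 21.0)) + [2000.0]
        box = box_summary(values)
        assert box.outliers == [2000.0]
        assert box.whisker_high <= 20.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_invariants(self, values):
        box = box_summary(values)
        assert box.q25 <= box.median <= box.q75
        arr = np.asarray(values)
        assert box.whisker_low in arr and box.whisker_high in arr
        iqr = box.q75 - box.q25
        assert all(v < box.q25 - 1.5 * iqr or v > box.q75 + 1.5 * iqr for v in box.outliers)


class TestStars:
    @pytest.mark.parametrize(
        "p, s",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00005, "****")],
    )
    def test_thresholds(self, p, s):
        assert significance_stars(p) == s
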