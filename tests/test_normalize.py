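"""Reference profile, control ranking, ΔCt arithmetic, and fold changes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seromir import (
    CtMatrix,
    SimulationConfig,
    build_reference_profile,
    compute_delta_ct,
    fold_change,
    rank_endogenous_controls,
    select_and_normalize,
    simulate_profiling,
)
from seromir.normalize import excluded_mirnas


def matrix(values: dict, flags: dict | None = None) -> CtMatrix:
    ct = pd.DataFrame(values).T  # rows = miRNAs
    flag = pd.DataFrame(False, index=ct.index, columns=ct.columns)
    for (row, col) in (flags or {}):
        flag.at[row, col] = True
    return CtMatrix(ct.astype(float), flag)


class TestReferenceProfile:
    def test_median_and_mean_without_flags(self, tiny_ct):
        prof = build_reference_profile(tiny_ct)
        assert prof.median.tolist() == [30.0, 31.0]
        assert prof.mean.tolist() == [30.0, 31.0]
        assert prof.excluded == frozenset()

    def test_one_flag_excludes_the_whole_row_from_both_samples(self, tiny_ct):
        flagged = CtMatrix(tiny_ct.ct, tiny_ct.flag.copy(), None)
        flagged.flag.at["m2", "s1"] = True
        prof = build_reference_profile(flagged)
        assert prof.excluded == frozenset({"m2"})
        # statistics over rows {m1, m3} only: (20, 40) and (21, 41)
        assert prof.median.tolist() == [30.0, 31.0]
        assert prof.mean.tolist() == [30.0, 31.0]

    def test_all_rows_flagged_is_hard_error(self):
        m = matrix(
            {"m1": {"s1": 20, "s2": 21}, "m2": {"s1": 22, "s2": 23}},
            flags={("m1", "s1"), ("m2", "s2")},
        )
        with pytest.raises(ValueError, match="unflagged"):
            build_reference_profile(m)

    def test_flagged_ct_value_is_never_consumed(self, tiny_ct):
        """Poisoning a flagged well must not change any statistic."""
        poisoned = CtMatrix(tiny_ct.ct.copy(), tiny_ct.flag.copy(), None)
        poisoned.flag.at["m2", "s1"] = True
        poisoned.ct.at["m2", "s1"] = 9.9e9
        clean = CtMatrix(tiny_ct.ct.copy(), tiny_ct.flag.copy(), None)
        clean.flag.at["m2", "s1"] = True
        p1 = build_reference_profile(poisoned)
        p2 = build_reference_profile(clean)
        pd.testing.assert_series_equal(p1.median, p2.median)
        pd.testing.assert_series_equal(p1.mean, p2.mean)
        r1 = rank_endogenous_controls(poisoned, p1, k=1)
        r2 = rank_endogenous_controls(clean, p2, k=1)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        d1 = compute_delta_ct(poisoned, r1.selected)
        d2 = compute_delta_ct(clean, r2.selected)
        pd.testing.assert_frame_equal(d1.values, d2.values)


class TestControlRanking:
    def test_profile_plus_constant_ranks_first(self):
        """Affine invariance: a row equal to the median profile plus a
        constant has r = 1 and tops the median-profile ranking."""
        rng = np.random.default_rng(0)
        base = {f"m{i}": dict(zip("abcd", rng.uniform(24, 34, 4))) for i in range(5)}
        m0 = matrix(base)
        prof0 = build_reference_profile(m0)
        base["shifted"] = dict(zip("abcd", prof0.median.to_numpy() + 2.0))
        m = matrix(base)
        ranking = rank_endogenous_controls(m, prof0, k=1, by="median")
        assert ranking.table.index[0] == "shifted"
        assert ranking.table.loc["shifted", "r"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_allpairs_correlation_oracle(self, seed):
        """Ranking equals exhaustive per-row correlation on small matrices."""
        rng = np.random.default_rng(seed)
        n_mir = int(rng.integers(4, 7))
        n_smp = int(rng.integers(3, 7))
        ct = pd.DataFrame(
            rng.uniform(20, 35, (n_mir, n_smp)),
            index=[f"m{i}" for i in range(n_mir)],
            columns=[f"s{j}" for j in range(n_smp)],
        )
        m = CtMatrix(ct, ct * 0 > 1)
        prof = build_reference_profile(m)
        ranking = rank_endogenous_controls(m, prof, k=2, m=n_mir)
        for mirna in ct.index:
            r_med = stats.pearsonr(ct.loc[mirna], prof.median).statistic
            r_mean = stats.pearsonr(ct.loc[mirna], prof.mean).statistic
            assert ranking.table.loc[mirna, "r"] == pytest.approx(
                (r_med + r_mean) / 2.0, abs=1e-12
            )
        oracle_order = (
            ranking.table["r"].sort_values(ascending=False, kind="stable").index
        )
        assert list(ranking.table.index) == list(oracle_order)

    def test_zero_variance_row_excluded_from_ranking(self):
        m = matrix(
            {
                "const": {"s1": 40, "s2": 40, "s3": 40},
                "m1": {"s1": 20, "s2": 22, "s3": 24},
                "m2": {"s1": 30, "s2": 31, "s3": 35},
            }
        )
        ranking = rank_endogenous_controls(m, build_reference_profile(m), k=1)
        assert "const" not in ranking.table.index

    def test_selection_prefers_abundant_among_stable(self):
        """Among equally stable (r = 1) candidates the lowest mean Ct wins."""
        v = np.array([25.0, 27.0, 29.0])
        m = matrix(
            {
                "abundant": dict(zip("abc", v - 5.0)),
                "abundant2": dict(zip("abc", v - 4.9)),
                "scarce": dict(zip("abc", v + 5.0)),
                "scarce2": dict(zip("abc", v + 5.1)),
            }
        )
        ranking = rank_endogenous_controls(m, build_reference_profile(m), k=1, m=2)
        assert ranking.selected == ("abundant",)

    @pytest.mark.parametrize("seed", range(25))
    def test_designated_stable_controls_occupy_top_ranks(self, seed):
        """Near-zero-biological-variance controls win the stability ranking;
        the final selection keeps only the most abundant of the short-list,
        so it is checked against the stability short-list, not equality."""
        cfg = SimulationConfig(
            seed=seed, n_mirnas_per_panel=80, panels=("A",), flag_prob=0.0
        )
        panels, truth = simulate_profiling(cfg)
        _, ranking, _ = select_and_normalize(panels["A"], k=3)
        controls = set(truth.stable_controls["A"])
        assert set(ranking.table.index[:3]) == controls
        assert set(ranking.selected) <= set(ranking.table.index[:10])

    def test_adding_a_flag_only_shrinks_the_rankable_set(self, quiet_config):
        panels, _ = simulate_profiling(quiet_config)
        m = panels["A"]
        flagged = CtMatrix(m.ct.copy(), m.flag.copy(), m.panel)
        flagged.flag.iloc[10, 3] = True
        before = set(m.mirnas) - excluded_mirnas(m)
        after = set(flagged.mirnas) - excluded_mirnas(flagged)
        assert after < before
        assert before - after == {m.mirnas[10]}


class TestDeltaCt:
    def test_single_control_against_itself_is_zero(self, tiny_ct):
        dct = compute_delta_ct(tiny_ct, ["m2"])
        assert (dct.values.loc["m2"] == 0.0).all()

    def test_arithmetic_with_two_controls(self):
        m = matrix(
            {
                "target": {"s1": 25.0},
                "c1": {"s1": 20.0},
                "c2": {"s1": 22.0},
            }
        )
        dct = compute_delta_ct(m, ["c1", "c2"])
        assert dct.values.at["target", "s1"] == pytest.approx(4.0)

    def test_round_trip_reconstructs_ct(self, quiet_config):
        panels, _ = simulate_profiling(quiet_config)
        m = panels["A"]
        dct, _, _ = select_and_normalize(m, k=3)
        reconstructed = dct.values.add(dct.reference, axis=1)
        pd.testing.assert_frame_equal(reconstructed, m.masked, check_like=True)

    def test_flagged_control_well_errors_or_drops_sample(self, tiny_ct):
        flagged = CtMatrix(tiny_ct.ct, tiny_ct.flag.copy(), None)
        flagged.flag.at["m1", "s2"] = True
        with pytest.raises(ValueError, match="s2"):
            compute_delta_ct(flagged, ["m1"])
        dct = compute_delta_ct(flagged, ["m1"], on_flagged_control="drop_sample")
        assert list(dct.samples) == ["s1"]

    def test_normalizing_by_controls_matches_true_loading_offsets(self):
        """Top-3 control normalization agrees with the (simulation-known)
        per-sample loading offsets on group differences within 0.2 cycles."""
        cfg = SimulationConfig(
            seed=9, n_mirnas_per_panel=100, panels=("A",), flag_prob=0.0, control_sd=0.1
        )
        panels, truth = simulate_profiling(cfg)
        m = panels["A"]
        dct, _, _ = select_and_normalize(m, k=3)
        loading = pd.Series(truth.loading_offsets).reindex(m.samples)
        dct_true = m.masked.sub(loading, axis=1)
        asd = [s for s, g in truth.sample_groups.items() if g == "ASD"]
        nc = [s for s, g in truth.sample_groups.items() if g == "NC"]
        gap_sel = dct.values[asd].mean(axis=1) - dct.values[nc].mean(axis=1)
        gap_true = dct_true[asd].mean(axis=1) - dct_true[nc].mean(axis=1)
        assert (gap_sel - gap_true).abs().max() < 0.2


class TestFoldChange:
    def test_equal_means_give_unit_fold_change(self):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [1.0], "s4": [2.0]},
                              index=["m"])
        fc = fold_change(values, ["s1", "s2"], ["s3", "s4"], "m")
        assert fc.fold_change == pytest.approx(1.0)
        assert fc.delta_delta_ct == pytest.approx(0.0)

    @pytest.mark.parametrize("ddct,expected", [(-1.0, 2.0), (2.0, 0.25)])
    def test_closed_form(self, ddct, expected):
        values = pd.DataFrame({"s1": [ddct], "s2": [0.0]}, index=["m"])
        fc = fold_change(values, ["s1"], ["s2"], "m")
        assert fc.fold_change == pytest.approx(expected)

    def test_antisymmetry_on_random_data(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.normal(3, 1, (5, 8)),
            index=[f"m{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(8)],
        )
        g1, g2 = list(values.columns[:4]), list(values.columns[4:])
        for mirna in values.index:
            fwd = fold_change(values, g1, g2, mirna).fold_change
            rev = fold_change(values, g2, g1, mirna).fold_change
            assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_empty_group_after_missingness_errors(self):
        values = pd.DataFrame({"s1": [np.nan], "s2": [1.0]}, index=["m"])
        with pytest.raises(ValueError, match="empty group"):
            fold_change(values, ["s1"], ["s2"], "m")
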