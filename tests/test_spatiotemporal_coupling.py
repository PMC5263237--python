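import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microturn import spatiotemporal_coupling as stc
from microturn.synthetic_population import (
    ConfigurationError,
    SimulationConfig,
    render_all,
    simulate,
)

from conftest import make_table


def simulate_table(seed, mode="local_replacement", **kwargs):
    cfg = SimulationConfig(seed=seed, coupling_mode=mode, **kwargs)
    return render_all(simulate(cfg))


class TestCouplingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [{"radius_um": 0.0}, {"window_days": 0}, {"n_permutations": 10}],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            stc.CouplingConfig(**kwargs)


class TestAnnotateEvents:
    def test_no_events(self):
        rows = [(d, "c0", "", 1.0, 2.0, 3.0, "none", "") for d in range(3)]
        deaths, divisions = stc.annotate_events(make_table(rows))
        assert len(deaths) == 0 and len(divisions) == 0

    def test_toy_positions_hand_checked(self):
        rows = [
            (0, "a", "", 10.0, 0.0, 0.0, "none", ""),
            (0, "b", "", 20.0, 0.0, 0.0, "none", ""),
            (0, "c", "", 30.0, 0.0, 0.0, "none", ""),
            (0, "d", "", 40.0, 0.0, 0.0, "none", ""),
            (0, "e", "", 50.0, 0.0, 0.0, "none", ""),
            (1, "a", "", 11.0, 0.0, 0.0, "died", ""),
            (1, "b", "", 20.0, 0.0, 0.0, "divided", ""),
            (1, "c", "", 30.0, 0.0, 0.0, "died", ""),
            (1, "d", "", 40.0, 0.0, 0.0, "divided", ""),
            (1, "e", "", 50.0, 0.0, 0.0, "none", ""),
            (2, "e", "", 50.0, 0.0, 0.0, "divided", ""),
        ]
        deaths, divisions = stc.annotate_events(make_table(rows))
        assert len(deaths) == 2 and len(divisions) == 3
        assert set(deaths["cell_id"]) == {"a", "c"}
        assert deaths.set_index("cell_id").loc["a", "x_um"] == 11.0
        assert set(divisions["cell_id"]) == {"b", "d", "e"}
        assert divisions.set_index("cell_id").loc["e", "day"] == 2

    def test_dead_cell_reappearing_rejected(self):
        rows = [
            (0, "z", "", 0.0, 0.0, 0.0, "died", ""),
            (2, "z", "", 0.0, 0.0, 0.0, "none", ""),
        ]
        with pytest.raises(ValueError, match="z"):
            stc.annotate_events(make_table(rows))

    def test_counts_match_simulator_event_log(self):
        cfg = SimulationConfig(seed=51)
        tracksets = simulate(cfg)
        deaths, divisions = stc.annotate_events(render_all(tracksets))
        assert len(deaths) == sum(ts.n_death_events for ts in tracksets)
        assert len(divisions) == sum(ts.n_division_events for ts in tracksets)


class TestTemporalCoupling:
    def test_constructed_single_death(self):
        # death day 5; division day 6 at 50 um counted (after); division
        # day 3 at 300 um excluded by radius
        rows = [
            (5, "dead", "", 0.0, 0.0, 0.0, "died", ""),
            (6, "near", "", 50.0, 0.0, 0.0, "divided", ""),
            (3, "far", "", 300.0, 0.0, 0.0, "divided", ""),
        ]
        deaths, divisions = stc.annotate_events(make_table(rows))
        result = stc.temporal_coupling(deaths, divisions, stc.CouplingConfig())
        assert (result.n_before, result.n_during, result.n_after) == (0, 0, 1)
        assert result.frac_after == 1.0
        assert result.asymmetry == 1.0

    def test_empty_result_flagged(self):
        rows = [
            (5, "dead", "", 0.0, 0.0, 0.0, "died", ""),
            (6, "far", "", 500.0, 0.0, 0.0, "divided", ""),
        ]
        deaths, divisions = stc.annotate_events(make_table(rows))
        result = stc.temporal_coupling(deaths, divisions, stc.CouplingConfig())
        assert result.empty
        assert result.frac_after is None

    def test_lineage_pairs_excluded(self):
        # dying daughter one day after her mother's division: not a
        # before-death proliferation signal
        rows = [
            (0, "m", "", 0.0, 0.0, 0.0, "divided", ""),
            (1, "d1", "m", 5.0, 0.0, 0.0, "died", ""),
            (1, "d2", "m", -5.0, 0.0, 0.0, "none", ""),
        ]
        deaths, divisions = stc.annotate_events(make_table(rows))
        result = stc.temporal_coupling(deaths, divisions, stc.CouplingConfig())
        assert result.empty

    def test_uncoupled_asymmetry_centered_on_zero(self):
        asyms = []
        for s in range(60):
            deaths, divisions = stc.annotate_events(
                simulate_table(100_000 + s, mode="uncoupled")
            )
            tc = stc.temporal_coupling(deaths, divisions, stc.CouplingConfig())
            asyms.append(tc.asymmetry)
        asyms = np.asarray(asyms)
        se = asyms.std(ddof=1) / np.sqrt(len(asyms))
        assert abs(asyms.mean()) <= max(3 * se, 0.03)

    def test_coupled_after_exceeds_before(self):
        after, before = 0, 0
        for s in range(12):
            deaths, divisions = stc.annotate_events(simulate_table(101_000 + s))
            tc = stc.temporal_coupling(deaths, divisions, stc.CouplingConfig())
            after += tc.n_after
            before += tc.n_before
        assert after > before
        # binomial test against symmetric null
        assert stats.binomtest(after, after + before, 0.5, alternative="greater").pvalue < 1e-6


def brute_force_distances(deaths, divisions, table, config):
    """O(n^2) oracle for the nearest-event distance block."""
    df = table.copy()
    if "fov" not in df.columns:
        df.insert(0, "fov", "fov0")
    parents = {}
    for _, r in df.drop_duplicates("cell_id").iterrows():
        if str(r["parent_id"]):
            parents[str(r["cell_id"])] = str(r["parent_id"])
    out = []
    for _, death in deaths.iterrows():
        excl = {death["cell_id"]}
        if parents.get(death["cell_id"]):
            excl.add(parents[death["cell_id"]])
        for child, parent in parents.items():
            if parent == death["cell_id"]:
                excl.add(child)
        p0 = np.array([death["x_um"], death["y_um"], death["z_um"]])
        residents = []
        for _, row in df.iterrows():
            if (
                row["fov"] == death["fov"]
                and row["day"] == death["day"]
                and row["cell_id"] not in excl
            ):
                q = np.array([row["x_um"], row["y_um"], row["z_um"]])
                residents.append(np.sqrt(((p0 - q) ** 2).sum()))
        if not residents:
            continue
        best_div = np.inf
        for _, row in divisions.iterrows():
            if (
                row["fov"] == death["fov"]
                and abs(row["day"] - death["day"]) <= config.window_days
                and row["cell_id"] not in excl
            ):
                q = np.array([row["x_um"], row["y_um"], row["z_um"]])
                best_div = min(best_div, np.sqrt(((p0 - q) ** 2).sum()))
        rank = (
            1 + sum(1 for r in residents if r < best_div)
            if np.isfinite(best_div)
            else np.nan
        )
        out.append(
            (
                death["cell_id"],
                min(residents),
                best_div if np.isfinite(best_div) else np.nan,
                rank,
            )
        )
    return out


class TestNearestEventDistances:
    def test_constructed_rank_two(self):
        # resident at 30 um, division at 50 um -> rank 2
        rows = [
            (0, "dead", "", 0.0, 0.0, 0.0, "none", ""),
            (0, "res", "", 30.0, 0.0, 0.0, "none", ""),
            (0, "div", "", 50.0, 0.0, 0.0, "none", ""),
            (1, "dead", "", 0.0, 0.0, 0.0, "died", ""),
            (1, "res", "", 30.0, 0.0, 0.0, "none", ""),
            (1, "div", "", 50.0, 0.0, 0.0, "divided", ""),
        ]
        table = make_table(rows)
        deaths, divisions = stc.annotate_events(table)
        result = stc.nearest_event_distances(
            deaths, divisions, table, stc.CouplingConfig()
        )
        rec = result.records.iloc[0]
        assert rec["nearest_resident_um"] == 30.0
        assert rec["nearest_proliferating_um"] == 50.0
        assert rec["rank_of_nearest_proliferating"] == 2

    def test_colocated_division_is_rank_one(self):
        rows = [
            (1, "dead", "", 0.0, 0.0, 0.0, "died", ""),
            (1, "div", "", 20.0, 0.0, 0.0, "divided", ""),
            (1, "res", "", 20.0, 0.0, 0.0, "none", ""),
        ]
        table = make_table(rows)
        deaths, divisions = stc.annotate_events(table)
        result = stc.nearest_event_distances(
            deaths, divisions, table, stc.CouplingConfig()
        )
        rec = result.records.iloc[0]
        assert rec["nearest_proliferating_um"] == rec["nearest_resident_um"] == 20.0
        assert rec["rank_of_nearest_proliferating"] == 1

    def test_matches_brute_force_oracle(self):
        cfg = SimulationConfig(
            n_fov=2, initial_cells_per_fov=40, n_days=8,
            division_hazard=0.05, resident_death_hazard=0.05,
            newborn_death_hazard=0.05, seed=57,
        )
        table = render_all(simulate(cfg))
        deaths, divisions = stc.annotate_events(table)
        ccfg = stc.CouplingConfig()
        result = stc.nearest_event_distances(deaths, divisions, table, ccfg)
        oracle = brute_force_distances(deaths, divisions, table, ccfg)
        assert len(result.records) == len(oracle)
        for (_, rec), (cell, nr, nprolif, rank) in zip(
            result.records.iterrows(), oracle
        ):
            assert rec["death_id"] == cell
            assert rec["nearest_resident_um"] == pytest.approx(nr)
            if np.isnan(nprolif):
                assert np.isnan(rec["nearest_proliferating_um"])
            else:
                assert rec["nearest_proliferating_um"] == pytest.approx(nprolif)
                assert rec["rank_of_nearest_proliferating"] == rank

    def test_coupled_distances_shorter_than_uncoupled(self):
        med = {}
        for mode in ("local_replacement", "uncoupled"):
            vals = []
            for s in range(10):
                table = simulate_table(102_000 + s, mode=mode)
                deaths, divisions = stc.annotate_events(table)
                result = stc.nearest_event_distances(
                    deaths, divisions, table, stc.CouplingConfig()
                )
                vals.append(result.median_proliferating)
            med[mode] = np.mean(vals)
        assert med["local_replacement"] < med["uncoupled"]

    def test_no_residents_skipped_with_warning(self):
        rows = [
            (0, "only", "", 0.0, 0.0, 0.0, "died", ""),
            (1, "div", "", 10.0, 0.0, 0.0, "divided", ""),
        ]
        table = make_table(rows)
        deaths, divisions = stc.annotate_events(table)
        with pytest.warns(RuntimeWarning, match="no resident"):
            with pytest.raises(ValueError):
                stc.nearest_event_distances(
                    deaths, divisions, table, stc.CouplingConfig()
                )

    def test_rigid_motion_invariance(self):
        table = simulate_table(59, n_fov=1, initial_cells_per_fov=40, n_days=8,
                               division_hazard=0.05, resident_death_hazard=0.05,
                               newborn_death_hazard=0.05)
        ccfg = stc.CouplingConfig()
        deaths, divisions = stc.annotate_events(table)
        base = stc.nearest_event_distances(deaths, divisions, table, ccfg)

        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = np.array([120.0, -40.0, 60.0])
        moved = table.copy()
        xyz = moved[["x_um", "y_um", "z_um"]].to_numpy() @ rot.T + shift
        moved[["x_um", "y_um", "z_um"]] = xyz
        deaths2, divisions2 = stc.annotate_events(moved)
        transformed = stc.nearest_event_distances(deaths2, divisions2, moved, ccfg)
        np.testing.assert_allclose(
            base.records["nearest_proliferating_um"],
            transformed.records["nearest_proliferating_um"],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            base.records["nearest_resident_um"],
            transformed.records["nearest_resident_um"],
            rtol=1e-9,
        )

    def test_monotone_coupling_response(self):
        meds = []
        for frac in (0.0, 0.5, 0.95):
            vals = []
            for s in range(10):
                table = simulate_table(103_000 + s, coupling_fraction=frac)
                deaths, divisions = stc.annotate_events(table)
                res = stc.nearest_event_distances(
                    deaths, divisions, table, stc.CouplingConfig()
                )
                vals.append(res.median_proliferating)
            meds.append(np.mean(vals))
        assert meds[0] > meds[1] > meds[2]


class TestPermutationNull:
    def test_invariant_data_gives_p_one(self):
        # all division days identical: every permutation reproduces the
        # observed asymmetry exactly
        rows = []
        for i in range(5):
            rows.append((5, f"dead{i}", "", 20.0 * i, 0.0, 0.0, "died", ""))
        for j in range(5):
            rows.append((3, f"div{j}", "", 20.0 * j, 10.0, 0.0, "divided", ""))
        table = make_table(rows)
        deaths, divisions = stc.annotate_events(table)
        null = stc.permutation_null(
            deaths, divisions, stc.CouplingConfig(n_permutations=200)
        )
        assert null.p_value == 1.0

    def test_too_few_events_rejected(self):
        rows = [
            (0, "d0", "", 0.0, 0.0, 0.0, "died", ""),
            (1, "v0", "", 10.0, 0.0, 0.0, "divided", ""),
        ]
        deaths, divisions = stc.annotate_events(make_table(rows))
        with pytest.raises(ValueError, match="at least 5"):
            stc.permutation_null(deaths, divisions, stc.CouplingConfig())

    def test_seed_reproducible(self):
        table = simulate_table(61)
        deaths, divisions = stc.annotate_events(table)
        cfg = stc.CouplingConfig(seed=9, n_permutations=200)
        a = stc.permutation_null(deaths, divisions, cfg)
        b = stc.permutation_null(deaths, divisions, cfg)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_asymmetry, b.null_asymmetry)

    def test_power_on_coupled_simulations(self):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            deaths, divisions = stc.annotate_events(simulate_table(104_000 + s))
            null = stc.permutation_null(
                deaths, divisions, stc.CouplingConfig(seed=s, n_permutations=1000)
            )
            hits += null.p_value < 0.05
        assert hits >= 0.8 * n_seeds

    def test_null_calibration_uniform(self):
        pvals = []
        for s in range(200):
            deaths, divisions = stc.annotate_events(
                simulate_table(105_000 + s, mode="uncoupled")
            )
            null = stc.permutation_null(
                deaths, divisions, stc.CouplingConfig(seed=s, n_permutations=200)
            )
            pvals.append(null.p_value)
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


def enumerate_wilcoxon_p(diffs):
    """Exact two-sided p by full enumeration of sign assignments."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    n = len(diffs)
    w_obs = ranks[diffs > 0].sum()
    w_all = [
        np.sum([r for r, s in zip(ranks, signs) if s])
        for signs in itertools.product([False, True], repeat=n)
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxonSignedRank:
    def test_identical_samples(self):
        a = np.arange(8.0)
        result = stc.wilcoxon_signed_rank(a, a)
        assert result.p_value == 1.0
        assert result.all_zero

    def test_textbook_eight_pairs_vs_enumeration(self):
        a = np.array([125.0, 115, 130, 140, 140, 115, 140, 125])
        b = np.array([110.0, 122, 125, 120, 140, 124, 123, 137])
        mine = stc.wilcoxon_signed_rank(a, b)
        assert mine.method == "exact"
        assert mine.p_value == pytest.approx(enumerate_wilcoxon_p(a - b))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_cases_vs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        mine = stc.wilcoxon_signed_rank(a, b)
        assert mine.p_value == pytest.approx(enumerate_wilcoxon_p(a - b))

    def test_ties_vs_enumeration(self):
        a = np.array([3.0, 5.0, 4.0, 1.0, 1.0, 6.0, 2.0])
        b = np.array([1.0, 3.0, 2.0, 3.0, 3.0, 2.0, 4.0])
        mine = stc.wilcoxon_signed_rank(a, b)
        assert mine.p_value == pytest.approx(enumerate_wilcoxon_p(a - b))

    def test_tie_free_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        mine = stc.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="exact", alternative="two-sided")
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.3, 1.0, size=60)
        b = rng.normal(0.0, 1.0, size=60)
        mine = stc.wilcoxon_signed_rank(a, b)
        assert mine.method == "normal"
        ref = stats.wilcoxon(a, b, correction=True, mode="approx")
        assert mine.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_length_mismatch_and_short_inputs(self):
        with pytest.raises(ValueError):
            stc.wilcoxon_signed_rank([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            stc.wilcoxon_signed_rank([1.0] * 4, [2.0] * 4)

    def test_coupled_simulation_distance_comparison_significant(self):
        # Fig 7E-style paired comparison on coupled simulations
        pvals = []
        for s in range(9):
            table = simulate_table(106_000 + s)
            deaths, divisions = stc.annotate_events(table)
            res = stc.nearest_event_distances(
                deaths, divisions, table, stc.CouplingConfig()
            )
            pvals.append(res.wilcoxon_pvalue)
        assert np.median(pvals) < 0.001
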