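"""Spearman engine, response classification, and Table-2-style aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import autoreg as ar
from autoreg.data import DoseWindow
from autoreg.oximetry import ResponseState


def d2_spearman(x, y):
    """Textbook tie-free formula 1 - 6 sum(d^2) / (n (n^2 - 1))."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))


def midrank_pearson(x, y):
    """Brute-force mid-rank Pearson oracle (handles ties)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanRho:
    def test_perfect_monotone(self):
        assert ar.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_known_value_from_rank_formula(self):
        # sum d^2 = 4 -> 1 - 24/60 = 0.6
        assert ar.spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_d2_formula_for_all_permutations(self, n):
        x = np.arange(1.0, n + 1)
        for perm in itertools.permutations(range(n)):
            y = x[list(perm)]
            assert ar.spearman_rho(x, y) == pytest.approx(d2_spearman(x, y), abs=1e-12)

    def test_tie_case_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0]):
            y = np.array(perm)
            assert ar.spearman_rho(x, y) == pytest.approx(midrank_pearson(x, y), abs=1e-12)

    def test_matches_scipy_on_noisy_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30) + 0.5 * x
            assert ar.spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_and_short_input_undefined(self):
        assert math.isnan(ar.spearman_rho([1, 2, 3], [5, 5, 5]))
        assert math.isnan(ar.spearman_rho([1, 2], [3, 4]))

    def test_nan_pairs_excluded(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, np.nan, 4.0, 5.0]
        assert ar.spearman_rho(x, y) == 1.0

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True).map(np.array),
    )
    def test_symmetry_and_sign_flip(self, x):
        rng = np.random.default_rng(1)
        y = rng.permutation(x)
        rho = ar.spearman_rho(x, y)
        assert ar.spearman_rho(y, x) == pytest.approx(rho, abs=1e-12)
        assert ar.spearman_rho(x, -y) == pytest.approx(-rho, abs=1e-12)

    @given(
        st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True)
        .map(lambda v: np.asarray(v, float))
    )
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(2)
        y = rng.permutation(x)
        rho = ar.spearman_rho(x, y)
        assert ar.spearman_rho(np.exp(x / 50), y) == pytest.approx(rho, abs=1e-12)
        assert ar.spearman_rho(x, y**3) == pytest.approx(rho, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "rho,state",
        [
            (0.5, ResponseState.PRESSURE_PASSIVE),
            (0.0, ResponseState.INTACT),
            (-0.5, ResponseState.PARADOXICAL),
            (0.36, ResponseState.INTACT),  # boundary belongs to intact
            (-0.36, ResponseState.INTACT),
            (1.0, ResponseState.PRESSURE_PASSIVE),
            (-1.0, ResponseState.PARADOXICAL),
            (float("nan"), ResponseState.UNDEFINED),
        ],
    )
    def test_threshold_rule(self, rho, state):
        assert ar.classify_response(rho) is state

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ar.classify_response(1.5)

    @given(st.floats(-1, 1))
    def test_partitions_interval(self, rho):
        state = ar.classify_response(rho)
        assert state in (
            ResponseState.PRESSURE_PASSIVE,
            ResponseState.INTACT,
            ResponseState.PARADOXICAL,
        )


def _window(map_values, toi_values, **kw):
    defaults = dict(
        animal_id="A01", condition="baseline", drug="phenylephrine",
        dose=0.0, site="cerebral",
    )
    defaults.update(kw)
    return DoseWindow(
        map_values=np.asarray(map_values, float),
        toi_values=np.asarray(toi_values, float),
        **defaults,
    )


class TestComputeIndex:
    def test_passive_simulated_window(self):
        rng = np.random.default_rng(0)
        m = np.linspace(60, 110, 60)
        profile = ar.default_site_profiles()["cerebral"]
        regime = ar.RegimeSpec("pressure_passive", 0.2, noise_sd=0.0)
        toi = ar.simulate_toi_from_map(m, profile, regime, "baseline", rng)
        ix = ar.compute_oximetry_index(_window(m, toi))
        assert ix.rho == 1.0
        assert ix.state is ResponseState.PRESSURE_PASSIVE
        assert ix.n == 60

    def test_paradoxical_simulated_window(self):
        rng = np.random.default_rng(0)
        m = np.linspace(60, 110, 60)
        profile = ar.default_site_profiles()["cerebral"]
        regime = ar.RegimeSpec("paradoxical", -0.2, noise_sd=0.0)
        toi = ar.simulate_toi_from_map(m, profile, regime, "baseline", rng)
        ix = ar.compute_oximetry_index(_window(m, toi))
        assert ix.rho == -1.0
        assert ix.state is ResponseState.PARADOXICAL

    def test_constant_toi_is_undefined_not_intact(self):
        ix = ar.compute_oximetry_index(_window(np.arange(60.0), np.full(60, 50.0)))
        assert math.isnan(ix.rho)
        assert ix.state is ResponseState.UNDEFINED


class TestAggregation:
    @staticmethod
    def _index_frame(states, rhos=None, **fixed):
        base = dict(
            animal_id="A01", condition="baseline", drug="phenylephrine",
            dose_ug_kg_min=0.0, site="cerebral", n=60,
        )
        base.update(fixed)
        rows = []
        for i, s in enumerate(states):
            rho = rhos[i] if rhos is not None else 0.0
            rows.append({**base, "animal_id": f"A{i + 1:02d}", "rho": rho, "state": s})
        return pd.DataFrame(rows, columns=[*base.keys(), "rho", "state"])

    def test_pattern_counts(self):
        df = self._index_frame(
            ["pressure_passive"] * 3 + ["intact"] * 4 + ["paradoxical"] * 3
        )
        counts = ar.count_response_patterns(df)
        row = counts.iloc[0]
        assert (
            row["pressure_passive"], row["intact"], row["paradoxical"], row["undefined"]
        ) == (3, 4, 3, 0)

    def test_undefined_counted_separately(self):
        df = self._index_frame(["intact", "undefined"], rhos=[0.0, float("nan")])
        row = ar.count_response_patterns(df).iloc[0]
        assert row["intact"] == 1 and row["undefined"] == 1

    def test_empty_group_counts(self):
        counts = ar.count_response_patterns(self._index_frame([]))
        assert counts.empty

    @pytest.mark.parametrize(
        "rhos,median,lo,hi",
        [
            ([0.1, 0.5, 0.9], 0.5, 0.1, 0.9),
            ([0.2, 0.4], 0.3, 0.2, 0.4),  # even n: midpoint of central pair
            ([0.76], 0.76, 0.76, 0.76),
        ],
    )
    def test_summaries(self, rhos, median, lo, hi):
        df = self._index_frame(["intact"] * len(rhos), rhos=rhos)
        s = ar.summarize_indices(df).iloc[0]
        assert s["median_rho"] == pytest.approx(median)
        assert (s["min_rho"], s["max_rho"]) == (lo, hi)

    def test_all_undefined_group_flagged_empty(self):
        df = self._index_frame(["undefined"], rhos=[float("nan")])
        s = ar.summarize_indices(df).iloc[0]
        assert s["n"] == 0 and math.isnan(s["median_rho"])

    def test_counts_conserve_windows_on_synthetic_experiment(self, default_indices, default_sim):
        _, ds, truth = default_sim
        counts = ar.count_response_patterns(default_indices)
        state_cols = ["pressure_passive", "intact", "paradoxical", "undefined"]
        assert counts[state_cols].to_numpy().sum() == len(truth) == 725
        # each group's count equals the animals with that site present
        sites_present = ds.sites_present
        for row in counts.itertuples(index=False):
            expected = sum(1 for a, s in sites_present.items() if row.site in s)
            assert sum(getattr(row, c) for c in state_cols) == expected


class TestParadoxicalTally:
    def test_any_dose_rule(self):
        df = TestAggregation._index_frame(
            ["intact", "paradoxical", "intact", "pressure_passive"]
        )
        df["animal_id"] = "A01"  # one animal, one arm, four doses
        df["dose_ug_kg_min"] = [0.0, 0.5, 1.0, 2.0]
        tally = ar.paradoxical_window_tally(df, "cerebral")
        assert tally.n_paradoxical_infusions == 1
        assert tally.n_infusions == 1
        assert tally.n_paradoxical_animals == 1

    def test_no_paradoxical_anywhere(self):
        df = TestAggregation._index_frame(["intact"] * 5)
        tally = ar.paradoxical_window_tally(df, "cerebral")
        assert tally.n_paradoxical_infusions == 0
        assert tally.n_infusions == 5

    def test_denominator_is_arms_times_animals(self, default_indices):
        tally = ar.paradoxical_window_tally(default_indices, "cerebral")
        assert tally.n_infusions == 50  # 10 animals x 5 arms
        assert tally.n_animals == 10
        lumbar = ar.paradoxical_window_tally(default_indices, "lumbar")
        assert lumbar.n_infusions == 45  # 9 animals with the lumbar site
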