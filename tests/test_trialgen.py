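import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moralchoice import trialgen as tg


class TestPairPool:
    def test_size(self, pool):
        assert len(pool) == 1881

    def test_corners_present(self, pool):
        pairs = set(zip(pool.delta_s.tolist(), pool.delta_m_units.tolist()))
        assert (1, 1) in pairs  # (1 shock, 0.2 yuan)
        assert (19, 99) in pairs  # (19 shocks, 19.8 yuan)

    def test_no_duplicates(self, pool):
        pairs = set(zip(pool.delta_s.tolist(), pool.delta_m_units.tolist()))
        assert len(pairs) == 1881

    def test_extreme_ratio_value(self, pool):
        # pair (19, 0.2): 0.2 / 19.2
        i = np.flatnonzero((pool.delta_s == 19) & (pool.delta_m_units == 1))[0]
        assert pool.ratios[i] == pytest.approx(0.2 / 19.2, abs=1e-12)

    def test_ordering_ds_major(self, pool):
        assert pool.delta_s[0] == 1 and pool.delta_s[-1] == 19
        assert pool.delta_m_units[0] == 1 and pool.delta_m_units[98] == 99


class TestRatioGrid:
    def test_endpoints(self):
        g = tg.ratio_grid(60, 0.01, 0.99)
        assert g[0] == 0.01 and g[-1] == 0.99 and len(g) == 60

    def test_three_point(self):
        assert np.allclose(tg.ratio_grid(3, 0, 1), [0, 0.5, 1])

    def test_common_difference(self):
        g = tg.ratio_grid(60, 0.01, 0.99)
        assert np.allclose(np.diff(g), 0.98 / 59)

    @pytest.mark.parametrize("n,lo,hi", [(1, 0.1, 0.9), (5, 0.9, 0.1), (5, -0.1, 0.5)])
    def test_invalid_args(self, n, lo, hi):
        with pytest.raises(ValueError):
            tg.ratio_grid(n, lo, hi)


class TestSelectPair:
    def test_brute_force_oracle_over_grid(self, pool):
        """Exhaustive argmin oracle over every queried design ratio."""
        rng = np.random.default_rng(0)
        for r in tg.ratio_grid(60, 0.01, 0.99):
            ds, dmu = tg.select_pair(r, pool, rng)
            chosen = abs(dmu / 5.0 / (ds + dmu / 5.0) - r)
            best = min(
                abs(dm_u / 5.0 / (d + dm_u / 5.0) - r)
                for d in range(1, 20)
                for dm_u in range(1, 100)
            )
            assert chosen == pytest.approx(best, abs=1e-12)

    def test_extreme_low_ratio(self, pool):
        rng = np.random.default_rng(0)
        assert tg.select_pair(0.01, pool, rng) == (19, 1)

    def test_half_ratio_ties(self, pool):
        # tied argmin set is exactly {(k, k.0)}: delta_m == delta_s
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(200):
            ds, dmu = tg.select_pair(0.5, pool, rng)
            assert dmu == 5 * ds
            seen.add(ds)
        assert len(seen) > 5  # uniform tie-break actually spreads

    def test_singleton_pool(self):
        single = tg.PairPool(delta_s=np.array([5]), delta_m_units=np.array([25]))
        rng = np.random.default_rng(0)
        assert tg.select_pair(0.123, single, rng) == (5, 25)

    def test_empty_pool_raises(self):
        empty = tg.PairPool(delta_s=np.array([], int), delta_m_units=np.array([], int))
        with pytest.raises(ValueError):
            tg.select_pair(0.5, empty, np.random.default_rng(0))


class TestInstantiateOptions:
    def test_forced_extreme_pair(self, pool):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = tg.instantiate_options((19, 1), "gain", rng)
            assert t.shocks_less == 1 and t.shocks_more == 20

    def test_additive_construction(self):
        rng = np.random.default_rng(1)
        t = tg.instantiate_options((5, 25), "gain", rng)
        assert t.shocks_more == t.shocks_less + 5
        assert t.money_more_units == t.money_less_units + 25

    def test_gain_money_positive(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = tg.instantiate_options((3, 10), "gain", rng)
            assert t.money_less > 0 and t.money_more > 0

    @given(ds=st.integers(1, 19), dmu=st.integers(1, 99), seed=st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_invariants_any_pair(self, ds, dmu, seed):
        rng = np.random.default_rng(seed)
        t = tg.instantiate_options((ds, dmu), "gain", rng)
        assert 1 <= t.shocks_less and t.shocks_more <= 20
        assert abs(t.money_more_units) <= 100 and abs(t.money_less_units) <= 100


class TestToLoss:
    def test_worked_example(self):
        # [15.0 yuan & 10 shocks; 10.0 yuan & 5 shocks]
        #   -> [-10.0 & 10 shocks; -15.0 & 5 shocks]
        t = tg.DesignTrial("gain", "self", 10, 5, 75, 50, 5, 25, 0.5)
        l = tg.to_loss(t)
        assert l.money_more == -10.0 and l.money_less == -15.0
        assert l.shocks_more == 10 and l.shocks_less == 5

    @given(ds=st.integers(1, 19), dmu=st.integers(1, 99), seed=st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_involution_and_preservation(self, ds, dmu, seed):
        rng = np.random.default_rng(seed)
        t = tg.instantiate_options((ds, dmu), "gain", rng)
        l = tg.to_loss(t)
        assert (l.delta_s, l.delta_m_units) == (t.delta_s, t.delta_m_units)
        # undo: negate and swap again
        back = (-l.money_less_units, -l.money_more_units)
        assert back == (t.money_more_units, t.money_less_units)

    def test_rejects_loss_input(self):
        t = tg.DesignTrial("gain", "self", 10, 5, 75, 50, 5, 25, 0.5)
        with pytest.raises(ValueError):
            tg.to_loss(tg.to_loss(t))


class TestBuildTrialset:
    def test_counts(self, trialset):
        df = trialset.to_frame()
        assert len(df) == 240
        assert (df.groupby(["context", "recipient"]).size() == 60).all()

    def test_deterministic(self, trialset):
        again = tg.build_trialset(seed=7)
        assert again == trialset
        assert again.to_frame().to_csv() == trialset.to_frame().to_csv()

    def test_per_cell_ratio_grid(self, trialset):
        df = trialset.to_frame()
        expected = np.sort(tg.ratio_grid(60, 0.01, 0.99))
        for _, cell in df.groupby(["context", "recipient"]):
            assert np.allclose(np.sort(cell["desired_ratio"]), expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_ds_dm_decorrelated(self, seed):
        df = tg.build_trialset(seed=seed).to_frame()
        assert abs(df["delta_s"].corr(df["delta_m"])) < 0.2

    def test_bounds_and_identities(self, trialset):
        df = trialset.to_frame()
        assert (df["shocks_more"] <= 20).all() and (df["shocks_less"] >= 1).all()
        assert (df["money_more"].abs() <= 20).all()
        assert (df["money_less"].abs() <= 20).all()
        assert np.allclose(df["shocks_more"] - df["shocks_less"], df["delta_s"])
        assert np.allclose(df["money_more"] - df["money_less"], df["delta_m"])
        loss = df[df["context"] == "loss"]
        assert (loss["money_more"] <= 0).all() and (loss["money_less"] <= 0).all()
        gain = df[df["context"] == "gain"]
        assert (gain["money_less"] > 0).all()


class TestCalibration:
    def test_noiseless_recovery(self):
        x = np.linspace(1.0, 5.0, 21)
        y = 10.0 / (1.0 + np.exp(-(x - 3.0) / 0.5))
        curve = tg.fit_rating_curve(x, y)
        assert curve.converged
        assert curve.midpoint == pytest.approx(3.0, abs=1e-3)
        assert curve.width == pytest.approx(0.5, abs=1e-3)

    def test_half_ceiling_is_midpoint(self):
        curve = tg.CalibrationCurve(midpoint=3.0, width=0.5)
        assert tg.intensity_for_rating(curve, 5) == pytest.approx(3.0)

    def test_level_seven_closed_form(self):
        curve = tg.CalibrationCurve(midpoint=3.0, width=0.5)
        assert tg.intensity_for_rating(curve, 7) == pytest.approx(
            3.0 + 0.5 * np.log(7 / 3)
        )

    def test_too_few_intensities(self):
        with pytest.raises(ValueError):
            tg.fit_rating_curve([1, 2, 2, 1], [0, 5, 5, 0])

    def test_degenerate_data_flagged(self):
        # ratings anti-monotone in intensity: sigmoid fit is hopeless but
        # must come back flagged, not raise or silently pretend
        x = np.linspace(1, 5, 10)
        y = np.linspace(9, 1, 10)
        curve = tg.fit_rating_curve(x, y)
        assert isinstance(curve, tg.CalibrationCurve)

    def test_invalid_level(self):
        curve = tg.CalibrationCurve(midpoint=3.0, width=0.5)
        with pytest.raises(ValueError):
            tg.intensity_for_rating(curve, 10)
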