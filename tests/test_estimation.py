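import numpy as np
import pandas as pd
import pytest

from spinedyn import estimation as est
from spinedyn.estimation import BinnedMoments


def _transitions(v_start, dv):
    v_start = np.asarray(v_start, float)
    dv = np.asarray(dv, float)
    return pd.DataFrame({
        "animal_id": "m", "dendrite_id": "d",
        "spine_id": [f"s{i}" for i in range(v_start.size)],
        "group": "WT", "session": 1,
        "v_start": v_start, "v_end": v_start + dv, "dv": dv,
    })


def _moments_on_line(volumes, slope, intercept, mu=0.0):
    volumes = np.asarray(volumes, float)
    sigma = slope * volumes ** (2 / 3) + intercept
    t = pd.DataFrame({
        "volume": volumes, "sigma": sigma, "mu": mu, "n": 32,
        "sigma_lo": sigma, "sigma_hi": sigma, "mu_sem": 0.0,
    })
    return BinnedMoments(table=t, bin_size=32)


class TestPairTransitions:
    def test_consecutive_pairs(self, tiny_table):
        trans, elim = est.pair_transitions(tiny_table)
        a = trans[trans.spine_id == "a"]
        assert len(a) == 2
        np.testing.assert_allclose(sorted(a["dv"]), [-0.01, 0.02])

    def test_elimination_split_off(self, tiny_table):
        trans, elim = est.pair_transitions(tiny_table)
        assert not (trans.spine_id == "b").any()
        assert len(elim) == 1 and elim.iloc[0]["v_start"] == 0.05

    def test_session_gap_respects_interval(self, tiny_table):
        trans1, _ = est.pair_transitions(tiny_table, interval=1)
        assert not (trans1.spine_id == "c").any()
        trans2, _ = est.pair_transitions(tiny_table, interval=2)
        c = trans2[trans2.spine_id == "c"]
        assert len(c) == 1 and c.iloc[0]["dv"] == pytest.approx(0.05)

    def test_count_matches_brute_force(self, small_cohort):
        """Independent enumeration over all (spine, session, session+1) rows."""
        trans, elim = est.pair_transitions(small_cohort)
        expected_trans = expected_elim = 0
        for _, d in small_cohort.groupby(["animal_id", "dendrite_id", "spine_id"]):
            sess = set(d["session"])
            by_s = d.set_index("session")
            for s in sorted(sess):
                if s + 1 not in sess or by_s.loc[s, "eliminated"]:
                    continue
                if by_s.loc[s + 1, "eliminated"]:
                    expected_elim += 1
                else:
                    expected_trans += 1
        assert len(trans) == expected_trans
        assert len(elim) == expected_elim

    def test_empty_table(self):
        empty = pd.DataFrame(columns=est.TRAJECTORY_COLUMNS)
        trans, elim = est.pair_transitions(empty)
        assert len(trans) == 0 and len(elim) == 0

    def test_min_session_filter(self, tiny_table):
        trans, _ = est.pair_transitions(tiny_table, min_session=2)
        assert set(trans.spine_id) == {"a"}
        assert len(trans) == 1   # only 2 -> 3 survives


class TestBinAndMoment:
    def test_constant_changes(self):
        m = est.bin_and_moment(_transitions(np.linspace(0.1, 0.5, 64), np.full(64, 0.01)), 32)
        assert len(m) == 2
        np.testing.assert_allclose(m.sigma, 0.0, atol=1e-15)
        np.testing.assert_allclose(m.mu, 0.01)

    def test_population_divisor_hand_example(self):
        """Two changes {0, 0.2}: mean 0.1 and SD 0.1 with divisor N."""
        m = est.bin_and_moment(_transitions([0.1, 0.2], [0.0, 0.2]), bin_size=2)
        assert m.mu[0] == pytest.approx(0.1)
        assert m.sigma[0] == pytest.approx(0.1)

    def test_remainder_merged_into_last_bin(self):
        # 70 = 2*32 + 6; 6 < 16 -> merged, giving bins of 32 and 38
        m = est.bin_and_moment(
            _transitions(np.linspace(0.1, 0.9, 70), np.zeros(70)), 32
        )
        assert list(m.table["n"]) == [32, 38]

    def test_large_remainder_kept(self):
        # 52 = 32 + 20; 20 >= 16 -> second bin kept
        m = est.bin_and_moment(
            _transitions(np.linspace(0.1, 0.9, 52), np.zeros(52)), 32
        )
        assert list(m.table["n"]) == [32, 20]

    def test_permutation_invariance(self, rng):
        v = rng.uniform(0.05, 0.8, 200)
        dv = rng.normal(0, 0.05, 200)
        m1 = est.bin_and_moment(_transitions(v, dv), 32)
        perm = rng.permutation(200)
        m2 = est.bin_and_moment(_transitions(v[perm], dv[perm]), 32)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_sd_interval_coverage(self, rng):
        """Volume-independent N(0, 0.05) changes: the chi-square interval
        should cover 0.05 in at least ~90% of bins over replicates."""
        hits = total = 0
        for _ in range(60):
            v = rng.uniform(0.05, 0.8, 320)
            dv = rng.normal(0.0, 0.05, 320)
            m = est.bin_and_moment(_transitions(v, dv), 32)
            t = m.table
            hits += ((t["sigma_lo"] <= 0.05) & (0.05 <= t["sigma_hi"])).sum()
            total += len(t)
        assert hits / total >= 0.90

    def test_too_few_transitions(self):
        with pytest.raises(ValueError):
            est.bin_and_moment(_transitions([0.1], [0.0]), 32)


class TestFits:
    def test_fast_fit_recovers_published_line(self):
        m = _moments_on_line(np.linspace(0.02, 0.6, 12), 0.115, 0.0051)
        slope, intercept = est.fit_fast(m)
        assert slope == pytest.approx(0.115, abs=1e-12)
        assert intercept == pytest.approx(0.0051, abs=1e-12)

    def test_fast_fit_flat_line(self):
        m = _moments_on_line(np.linspace(0.02, 0.6, 8), 0.0, 0.01)
        slope, intercept = est.fit_fast(m)
        assert slope == pytest.approx(0.0, abs=1e-14)
        assert intercept == pytest.approx(0.01)

    def test_decompose_pythagorean(self):
        m = _moments_on_line([0.2], 0.0, 0.05)
        slow = est.decompose_slow(m, (0.0, 0.03))
        assert slow.sigma[0] == pytest.approx(0.04)   # 3-4-5
        assert not slow.table["clipped"].iloc[0]

    def test_decompose_clips_and_flags(self):
        m = _moments_on_line([0.2], 0.0, 0.02)
        slow = est.decompose_slow(m, (0.0, 0.05))
        assert slow.sigma[0] == 0.0
        assert bool(slow.table["clipped"].iloc[0])

    def test_decompose_exact_when_equal(self):
        v = np.linspace(0.05, 0.5, 6)
        m = _moments_on_line(v, 0.115, 0.0051)
        slow = est.decompose_slow(m, (0.115, 0.0051))
        np.testing.assert_allclose(slow.sigma, 0.0, atol=1e-12)

    @pytest.mark.parametrize("slope", [0.198, 0.278])
    def test_anchored_fit_exact_on_line(self, slope):
        v = np.linspace(0.02, 0.8, 10)
        sigma = slope * (v ** (2 / 3) - 0.015 ** (2 / 3)) + 0.02
        t = pd.DataFrame({
            "volume": v, "sigma": sigma, "mu": 0.0, "n": 32,
            "sigma_lo": sigma, "sigma_hi": sigma, "mu_sem": 0.0,
        })
        fitted, ci = est.fit_anchored_slope(BinnedMoments(t, 32))
        assert fitted == pytest.approx(slope, abs=1e-12)
        assert ci[0] <= slope <= ci[1]

    def test_anchored_fit_horizontal_line(self):
        m = _moments_on_line(np.linspace(0.02, 0.8, 10), 0.0, 0.02)
        fitted, _ = est.fit_anchored_slope(m)
        assert fitted == pytest.approx(0.0, abs=1e-12)

    def test_drift_fit_exact(self):
        v = np.linspace(0.02, 0.8, 10)
        mu = -0.12 * v ** (2 / 3) + 0.029
        m = _moments_on_line(v, 0.1, 0.01, mu=mu)
        c, d = est.fit_drift(m)
        assert c == pytest.approx(-0.12, abs=1e-12)
        assert d == pytest.approx(0.029, abs=1e-12)

    def test_drift_fit_zero(self):
        m = _moments_on_line(np.linspace(0.02, 0.8, 10), 0.1, 0.01, mu=0.0)
        c, d = est.fit_drift(m)
        assert c == pytest.approx(0.0, abs=1e-14)
        assert d == pytest.approx(0.0, abs=1e-14)

    def test_zero_crossing_from_published_drift(self):
        assert est.drift_zero_crossing((-0.12, 0.029)) == pytest.approx(0.12, abs=5e-3)

    def test_fit_errors_on_single_bin(self):
        m = _moments_on_line([0.2], 0.1, 0.01)
        for fn in (est.fit_fast, est.fit_drift):
            with pytest.raises(ValueError):
                fn(m)
        with pytest.raises(ValueError):
            est.fit_anchored_slope(m)


class TestCompareSlopes:
    def test_identical_groups(self):
        m = _moments_on_line(np.linspace(0.02, 0.8, 10), 0.2, 0.008)
        t, p = est.compare_slopes(m, m)
        assert abs(t) < 1e-8
        assert p > 0.99

    def test_doubled_sigma_doubles_slope(self):
        """Fit linearity: scaling sigma (about the anchor) scales the slope."""
        v = np.linspace(0.02, 0.8, 10)
        s = 0.2 * (v ** (2 / 3) - 0.015 ** (2 / 3)) + 0.02
        def mom(sigma):
            t = pd.DataFrame({
                "volume": v, "sigma": sigma, "mu": 0.0, "n": 32,
                "sigma_lo": sigma, "sigma_hi": sigma, "mu_sem": 0.0,
            })
            return BinnedMoments(t, 32)
        a = mom(s)
        b = mom(2 * (s - 0.02) + 0.02)
        sa, _ = est.fit_anchored_slope(a)
        sb, _ = est.fit_anchored_slope(b)
        assert sb == pytest.approx(2 * sa)

    def test_distinct_slopes_detected(self, rng):
        v = np.linspace(0.02, 0.8, 30)
        def noisy(slope):
            s = slope * (v ** (2 / 3) - 0.015 ** (2 / 3)) + 0.02 + rng.normal(0, 0.003, v.size)
            t = pd.DataFrame({
                "volume": v, "sigma": np.clip(s, 0, None), "mu": 0.0, "n": 32,
                "sigma_lo": s, "sigma_hi": s, "mu_sem": 0.0,
            })
            return BinnedMoments(t.assign(sigma_lo=t.sigma, sigma_hi=t.sigma), 32)
        t, p = est.compare_slopes(noisy(0.198), noisy(0.278))
        assert p < 0.05


class TestTableValidation:
    def test_round_trip_csv(self, small_cohort, tmp_path):
        path = tmp_path / "traj.csv"
        small_cohort.to_csv(path, index=False)
        back = est.read_trajectories(path)
        assert len(back) == len(small_cohort)

    def test_rejects_nonmonotonic_sessions(self, tiny_table):
        bad = tiny_table.copy()
        bad.loc[bad.index[-1], "session"] = 1
        with pytest.raises(ValueError):
            est.validate_trajectories(bad)

    def test_rejects_observation_after_elimination(self, tiny_table):
        extra = tiny_table[tiny_table.spine_id == "b"].copy()
        extra["session"] = [1, 3]
        extra["eliminated"] = [True, False]
        bad = pd.concat([tiny_table[tiny_table.spine_id != "b"], extra])
        with pytest.raises(ValueError):
            est.validate_trajectories(bad)

    def test_elimination_by_dendrite(self, small_cohort):
        frac = est.elimination_by_dendrite(small_cohort)
        assert set(frac["group"]) == {"WT", "KO"}
        assert ((frac["fraction"] >= 0) & (frac["fraction"] <= 1)).all()
        assert (frac["n_pairs"] > 0).all()
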