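import numpy as np
import pandas as pd
import pytest

from spinedyn import fp
from spinedyn import estimation as est
from spinedyn.calibration import CalibrationError, PSFSphereModel, fit_sphere
from spinedyn.synthetic import CohortConfig, generate_cohort, generate_zstack


def _wt_only(wt_spec, **kw):
    base = dict(
        specs={"WT": wt_spec}, n_spines={"WT": 400}, n_dendrites={"WT": 8},
        n_animals={"WT": 4}, seed=3,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestCohorts:
    def test_fixed_sample_mode_is_static(self, wt_spec):
        tab = generate_cohort(_wt_only(wt_spec, mode="fixed", n_sessions=4))
        per_spine = tab.groupby("spine_id")["volume_um3"].nunique()
        assert (per_spine == 1).all()
        assert not tab["eliminated"].any()

    def test_deterministic_under_seed(self, wt_spec):
        cfg = _wt_only(wt_spec, n_sessions=4)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seeds_differ(self, wt_spec):
        a = generate_cohort(_wt_only(wt_spec, seed=1))
        b = generate_cohort(_wt_only(wt_spec, seed=2))
        assert not a["volume_um3"].equals(b["volume_um3"])

    def test_schema_and_structure(self, small_cohort):
        # generate_cohort validates internally; spot-check invariants here
        assert set(small_cohort["group"]) == {"WT", "KO"}
        gone = small_cohort[small_cohort["eliminated"]]
        assert (gone["volume_um3"] == 0).all()
        # eliminated record terminates its spine's series
        last = small_cohort.groupby("spine_id").tail(1)
        assert small_cohort[small_cohort["eliminated"]].index.isin(last.index).all()

    def test_first_interval_elimination_matches_model(self, wt_spec):
        """Stationary-initialized cohorts eliminate at the model's per-
        session rate over the first interval (3 binomial SEs)."""
        cfg = _wt_only(wt_spec, n_spines={"WT": 20000}, n_sessions=2, seed=17)
        tab = generate_cohort(cfg)
        n0 = (tab["session"] == 1).sum()
        gone = tab["eliminated"].sum()
        frac = 100.0 * gone / n0
        model = fp.session_elimination_rate(wt_spec)
        se = 100.0 * np.sqrt(model / 100 * (1 - model / 100) / n0)
        assert abs(frac - model) < 3 * se

    def test_fast_mode_recovers_fast_coefficients(self, wt_spec):
        """10-min imaging of frozen latents: binned SDs of observed
        differences scatter about the generating fast-SD line."""
        slopes, intercepts = [], []
        for seed in range(6):
            cfg = _wt_only(
                wt_spec, mode="fast", seed=100 + seed,
                n_spines={"WT": 600}, n_dendrites={"WT": 2}, n_animals={"WT": 2},
            )
            tab = generate_cohort(cfg)
            assert tab.groupby("spine_id")["session"].count().max() == 7
            trans, _ = est.pair_transitions(tab)
            m = est.bin_and_moment(trans, 30)
            s, i = est.fit_fast(m)
            slopes.append(s)
            intercepts.append(i)
        assert np.mean(slopes) == pytest.approx(0.115, rel=0.15)
        assert np.mean(intercepts) == pytest.approx(0.0051, abs=0.004)

    def test_end_to_end_slope_recovery(self, wt_spec):
        """Full estimation chain on generated cohorts lands near the
        generating slow slope (attenuation by observation noise and
        boundary effects is bounded)."""
        slopes = []
        for seed in range(4):
            cfg = _wt_only(wt_spec, n_spines={"WT": 754}, n_dendrites={"WT": 15},
                           n_animals={"WT": 5}, n_sessions=5, seed=seed)
            tab = generate_cohort(cfg)
            trans, _ = est.pair_transitions(tab)
            slow = est.decompose_slow(
                est.bin_and_moment(trans, 32), (0.115, 0.0051)
            )
            slopes.append(est.fit_anchored_slope(slow)[0])
        assert np.mean(slopes) == pytest.approx(0.198, rel=0.2)

    def test_top_up_keeps_counts(self, wt_spec):
        cfg = _wt_only(wt_spec, n_spines={"WT": 2000}, n_sessions=4, top_up=True)
        tab = generate_cohort(cfg)
        alive = tab[~tab["eliminated"]].groupby("session").size()
        assert (alive == 2000).all()

    def test_sde_latent_step_supported(self, wt_spec):
        cfg = _wt_only(wt_spec, n_spines={"WT": 200}, n_sessions=3,
                       latent_step="sde")
        tab = generate_cohort(cfg)
        assert tab["session"].max() == 3

    def test_single_session_has_no_transitions(self, wt_spec):
        tab = generate_cohort(_wt_only(wt_spec, n_sessions=1))
        trans, elim = est.pair_transitions(tab)
        assert len(trans) == 0 and len(elim) == 0

    def test_bad_config_rejected(self, wt_spec):
        with pytest.raises(ValueError):
            _wt_only(wt_spec, mode="warp")
        with pytest.raises(ValueError):
            _wt_only(wt_spec, n_spines={"WT": 0})


class TestZStacks:
    def test_round_trip_radius_recovery(self):
        stack = generate_zstack([(3.0, 3.0, 5.0, 0.4, 2.0)], shape=(48, 48, 25))
        zsum = stack.sum(axis=2) * 0.4
        iy, ix = np.unravel_index(np.argmax(zsum), zsum.shape)
        r = (np.arange(48) + 0.5) * 0.124 - 3.0
        fitted, _ = fit_sphere(np.column_stack([r, zsum[iy]]))
        assert fitted.radius == pytest.approx(0.4, abs=0.124)  # within 1 px
        assert fitted.amplitude == pytest.approx(2.0, rel=0.05)

    def test_total_flux_scales_with_radius_cubed(self):
        """Summed fluorescence vs R^3: linear through the origin."""
        radii = np.array([0.2, 0.3, 0.4, 0.5])
        sums = []
        for R in radii:
            st = generate_zstack([(3.0, 3.0, 5.0, R, 1.0)], shape=(48, 48, 25))
            sums.append(st.sum() * 0.124**2 * 0.4)
        sums = np.asarray(sums)
        x = radii**3
        beta = (x @ sums) / (x @ x)
        resid = sums - beta * x
        r2 = 1 - resid @ resid / ((sums - sums.mean()) @ (sums - sums.mean()))
        assert r2 > 0.999
        assert beta == pytest.approx(4 / 3 * np.pi, rel=1e-3)

    def test_noise_only_field_fails_fit(self, rng):
        stack = generate_zstack([], shape=(32, 32, 10), noise_sd=0.1, seed=4)
        zsum = stack.sum(axis=2) * 0.4
        r = (np.arange(32) + 0.5) * 0.124 - 2.0
        with pytest.raises((CalibrationError, ValueError)):
            fit_sphere(np.column_stack([r, zsum[16]]))

    def test_overlapping_spheres_warn(self):
        with pytest.warns(UserWarning):
            generate_zstack(
                [(2.0, 2.0, 3.0, 0.4, 1.0), (2.2, 2.0, 3.0, 0.4, 1.0)],
                shape=(32, 32, 15),
            )

    def test_sphere_outside_field_rejected(self):
        with pytest.raises(ValueError):
            generate_zstack([(50.0, 2.0, 3.0, 0.3, 1.0)], shape=(32, 32, 15))

    def test_deterministic_noise(self):
        a = generate_zstack([(2.0, 2.0, 3.0, 0.3, 1.0)], shape=(24, 24, 12),
                            noise_sd=0.05, seed=9)
        b = generate_zstack([(2.0, 2.0, 3.0, 0.3, 1.0)], shape=(24, 24, 12),
                            noise_sd=0.05, seed=9)
        assert np.array_equal(a, b)
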