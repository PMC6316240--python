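"""Simulator physics, sampling scheduler, observation model, failure injection."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from mbrkit.design import expand_design, load_design_table
from mbrkit.simulate import (
    ETHANOL_DETECTION_LIMIT,
    KineticParams,
    generate_campaign,
    inject_sensor_failure,
    sample_measurements,
    sampling_schedule,
    simulate_run,
)


def _plan_for(campaign, cid):
    return next(p for p in campaign.plans if p.condition.condition_id == cid)


def _traj_for(campaign, cid):
    return campaign.trajectories[_plan_for(campaign, cid).run_id]


class TestBatchPhysiology:
    def test_batch_regime_ordering(self, batch20):
        """Glucose falls monotonically; ethanol rises, then is consumed."""
        tb = batch20.t_batch_end
        in_batch = batch20.t <= tb
        S = batch20.S[in_batch]
        assert np.all(np.diff(S) <= 1e-9)
        iE = int(np.argmax(batch20.E))
        assert batch20.t[iE] == pytest.approx(tb, abs=0.5)
        after = batch20.t > tb + 1.0
        assert np.all(np.diff(batch20.E[after]) <= 1e-9)

    def test_no_overflow_when_capacity_exceeds_uptake(self, design_table):
        """Ethanol appears iff glucose uptake exceeds the respiratory bound."""
        plan = expand_design(design_table)[0]
        p_over = KineticParams().noiseless()
        p_resp = replace(p_over, qS_crit=5.0, Y_XS_ferm=0.01)  # capacity > qS_max
        t_over = simulate_run(plan, None, p_over, t_end=10.0)
        t_resp = simulate_run(plan, None, p_resp, t_end=10.0)
        assert t_over.E.max() > 1.0
        assert t_resp.E.max() == pytest.approx(0.0, abs=1e-12)

    def test_mass_balance_batch_and_fed(self, batch20, campaign, params):
        """S0*V0 + fed glucose = consumed + residual, within 0.5%.

        Checked without sample withdrawals (which remove glucose that is
        neither consumed nor residual)."""
        plan2 = _plan_for(campaign, 2)
        fed = simulate_run(plan2, campaign.schedules[plan2.run_id],
                           params.noiseless(), t_end=48.0)
        for tr in (batch20, fed):
            total_in = tr.S[0] * tr.V[0] + tr.fed_S[-1]
            out = tr.consumed_S[-1] + tr.S[-1] * tr.V[-1]
            assert out == pytest.approx(total_in, rel=5e-3)

    def test_volume_balance_exact(self, campaign):
        tr = _traj_for(campaign, 2)
        V0 = tr.V[0]
        recon = V0 + tr.cum_feed + tr.cum_base - tr.cum_evap - tr.cum_sample
        assert np.allclose(recon, tr.V, atol=1e-12)

    def test_dot_within_range_and_states_nonnegative(self, campaign):
        for tr in campaign.trajectories.values():
            assert np.all(tr.DOT >= 0) and np.all(tr.DOT <= 100)
            for arr in (tr.X, tr.S, tr.E, tr.V, tr.EAv):
                assert np.all(arr >= -1e-12)


class TestFedBatchRegimes:
    def test_low_rate_ethanol_below_detection(self, noiseless_campaign):
        """Condition 1 (exponential, 0.0875): ethanol cleared in fed-batch."""
        tr = _traj_for(noiseless_campaign, 1)
        late = tr.t >= tr.t_feed_start + 12
        assert tr.E[late].min() < ETHANOL_DETECTION_LIMIT

    def test_high_rate_exceeds_low_rate_everywhere(self, noiseless_campaign):
        """Condition 3 (0.35) accumulates more ethanol than condition 1 at
        every matched time from feed start on, and far more at the end."""
        t1 = _traj_for(noiseless_campaign, 1)
        t3 = _traj_for(noiseless_campaign, 3)
        grid = np.arange(max(t1.t_feed_start, t3.t_feed_start), 48.0, 0.25)
        e1 = t1.value("ethanol", grid)
        e3 = t3.value("ethanol", grid)
        assert np.all(e3 >= e1 - 5e-3)
        assert e3[-1] > 5.0 > e1[-1]

    def test_ethanol_monotone_in_feed_rate(self, noiseless_campaign):
        """Group-mean fed-batch ethanol is non-decreasing in the set rate."""
        fac = noiseless_campaign.design_factors()
        window = np.arange(24.0, 40.0, 0.5)
        means = {}
        for mu in (0.0875, 0.175, 0.35):
            runs = fac[fac.mu_set == mu].index
            vals = [noiseless_campaign.trajectories[r].value("ethanol", window).mean()
                    for r in runs]
            means[mu] = np.mean(vals)
        assert means[0.0875] <= means[0.175] <= means[0.35]

    def test_glucose_accumulates_at_high_rate_then_everywhere(self, noiseless_campaign):
        t3 = _traj_for(noiseless_campaign, 3)
        assert t3.value("glucose", 30.0) > 5.0
        # growth stagnation lets glucose appear even at the lowest rate late on
        t1 = _traj_for(noiseless_campaign, 1)
        assert t1.value("glucose", 46.0) > t1.value("glucose", 34.0)


class TestSamplingSchedule:
    def test_fedbatch_period_is_two_hours(self, design_table):
        plans = expand_design(design_table)
        times = sampling_schedule(plans, t_feed_start=20.0, t_end=48.0)
        for rid, tt in times.items():
            fed = tt[tt >= 20.0]
            assert np.allclose(np.diff(fed), 2.0, atol=1e-9)

    def test_column_offsets(self, design_table):
        plans = expand_design(design_table)
        times = sampling_schedule(plans, t_feed_start=20.0, t_end=48.0)
        by_col = {}
        for p in plans:
            by_col[p.plate_position[1]] = times[p.run_id]
        for c in range(1, 7):
            fed = by_col[c][by_col[c] >= 20.0]
            assert fed[0] == pytest.approx(20.0 + (c - 1) * 20.0 / 60.0)
        batch = by_col[2][by_col[2] < 20.0]
        assert np.allclose(batch - by_col[1][: len(batch)], 5.0 / 60.0)

    def test_total_count_matches_enumeration(self, design_table):
        """Closed-form check by brute-force enumeration of the round times."""
        plans = expand_design(design_table)
        t_fs, t_end = 20.0, 48.0
        times = sampling_schedule(plans, t_fs, t_end=t_end)
        total = sum(len(t) for t in times.values())
        expected = 0
        for p in plans:
            c = p.plate_position[1] - 1
            n_batch = sum(1 for k in range(1, 100)
                          if k * 2.0 + c * 5 / 60 < t_fs and k * 2.0 < t_fs)
            n_fed = sum(1 for k in range(0, 100)
                        if t_fs + c * 20 / 60 + k * 2.0 <= t_end)
            expected += n_batch + n_fed
        assert total == expected

    def test_single_column_degenerate(self, design_table):
        plans = expand_design(design_table[:2], replicates=2)  # 4 runs, col 1-4
        one_col = [p for p in plans if p.plate_position[1] == 1]
        times = sampling_schedule(one_col, t_feed_start=10.0, t_end=20.0)
        tt = times[one_col[0].run_id]
        fed = tt[tt >= 10.0]
        assert np.allclose(np.diff(fed), 20.0 / 60.0)


class TestObservationModel:
    def test_noiseless_identity(self, batch20, params):
        times = [4.0, 8.0, 12.0]
        tab = sample_measurements(batch20, times, params.noiseless(), seed=0)
        bio = tab[tab.variable == "biomass"]
        assert np.allclose(bio["value"], batch20.value("biomass", times))

    def test_seed_determinism(self, batch20, params):
        a = sample_measurements(batch20, [4.0, 8.0], params, seed=42)
        b = sample_measurements(batch20, [4.0, 8.0], params, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_level_monte_carlo(self, batch20, params):
        """10^4 draws of one biomass value: empirical rel sd within 5% of 5%."""
        draws = []
        rng = np.random.default_rng(7)
        tab = sample_measurements(batch20, [10.0] * 10000, params, seed=rng)
        vals = tab[tab.variable == "biomass"]["value"].to_numpy()
        rel_sd = vals.std() / vals.mean()
        assert rel_sd == pytest.approx(params.noise["biomass"], rel=0.05)

    def test_ethanol_censoring(self, batch20, params):
        tab = sample_measurements(batch20, [0.5, 1.0], params.noiseless(), seed=0)
        eth = tab[tab.variable == "ethanol"]
        assert (eth["value"] >= ETHANOL_DETECTION_LIMIT).all()
        assert eth["censored"].all()

    def test_out_of_span_times_listed(self, batch20, params):
        with pytest.raises(ValueError, match=r"99\.0"):
            sample_measurements(batch20, [4.0, 99.0], params, seed=0)

    def test_fedbatch_replication_scheme(self, campaign):
        tab = campaign.measurements
        tr = campaign.trajectories[1]
        fed = tab[(tab.run_id == 1) & (tab.time_h >= tr.t_feed_start)]
        reps = fed.groupby("variable")["replicate"].max()
        assert reps["biomass"] == 2 and reps["glucose"] == 2
        assert reps["EAv"] == 3
        assert reps["pH"] == 1


class TestFailureInjection:
    def test_unchanged_when_onset_beyond_end(self, batch20):
        out = inject_sensor_failure(batch20, onset=1e6, seed=0)
        assert out is batch20

    def test_unknown_mode_rejected(self, batch20):
        with pytest.raises(ValueError, match="unknown failure mode"):
            inject_sensor_failure(batch20, mode="teleport", onset=1.0, seed=0)

    def test_failure_degrades_culture_and_sensors(self, campaign, design_table):
        healthy = generate_campaign(design_table, seed=1, failure_run=None)
        bad = campaign.trajectories[46]
        good = healthy.trajectories[46]
        assert bad.value("biomass", 40.0) < 0.7 * good.value("biomass", 40.0)
        assert bad.value("pH", 26.0) > 6.5  # drifted sensor
        assert abs(np.diff(bad.DOT[bad.t > 1.0]).mean()) < 0.05  # flatlined


class TestGenerateCampaign:
    def test_default_campaign_shape(self, campaign):
        assert len(campaign.run_ids) == 48
        assert campaign.failure_run == 46
        assert campaign.trajectories[46].failure_mode == "pH_DOT_failure"
        n_failed = sum(tr.failure_mode is not None
                       for tr in campaign.trajectories.values())
        assert n_failed == 1
        assert set(campaign.measurements.run_id.unique()) == set(range(1, 49))

    def test_two_runs_minimal(self, design_table):
        camp = generate_campaign(design_table[:2], replicates=1, seed=0,
                                 failure_run=None)
        assert camp.run_ids == [1, 2]

    def test_seed_reproducibility_bytes(self, design_table):
        a = generate_campaign(design_table[:4], replicates=1, seed=5)
        b = generate_campaign(design_table[:4], replicates=1, seed=5)
        assert (a.measurements.to_csv(index=False)
                == b.measurements.to_csv(index=False))

    def test_x0_feedstart_filled_from_batch(self, campaign):
        for p in campaign.plans:
            assert 1.4 <= p.X0_feedstart <= 3.6
            assert p.t_batch_end > 15.0
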