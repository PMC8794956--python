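"""Generator tests: exposure timelines, Langevin dynamics (including the
Kramers-rate oracle), EEG/EMG synthesis and cohort assembly."""

import numpy as np
import pytest
from scipy import signal

from neuroinertia.synthetic_data import (
    ANALYSIS_SPANS,
    CohortConfig,
    ConcentrationSchedule,
    SimConfig,
    SpectralTemplateSet,
    StateTrajectory,
    adapted_concentration,
    first_passage_time,
    generate_cohort,
    inject_artifacts,
    kramers_rate,
    make_exposure_timeline,
    make_templates,
    noise_for_relaxation,
    occupancy,
    simulate_two_well,
    synthesize_eeg,
    synthesize_emg,
)

from conftest import mini_cohort_config


def _flat_traj(state: int, duration_s: float, dt: float = 0.01):
    n = int(duration_s / dt)
    x = np.full(n, 1.0 if state else -1.0)
    return StateTrajectory(dt=dt, x=x, s=np.full(n, state, dtype=np.uint8))


# ---------------------------------------------------------------------------
# exposure timelines
# ---------------------------------------------------------------------------

class TestExposureTimeline:
    def test_induction_schedule(self):
        sch = make_exposure_timeline("induction")
        assert sch.breakpoints == ((0.0, 0.0), (1800.0, 0.6))
        assert sch.duration_s == 270 * 60.0
        assert sch.conc_at(0.0) == 0.0
        # 0.6% for 240 min after the 30-min oxygen baseline
        assert sch.conc_at(1800.0) == 0.6
        assert sch.conc_at(sch.duration_s - 1) == 0.6

    def test_emergence_schedule(self):
        sch = make_exposure_timeline("emergence")
        assert sch.breakpoints == (
            (0.0, 0.0), (1800.0, 0.6), (5400.0, 1.2), (7200.0, 0.6))
        assert sch.duration_s == 360 * 60.0
        assert sch.conc_at(0.0) == 0.0
        assert sch.conc_at(6000.0) == 1.2
        assert sch.final_step_onset_s == 7200.0

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError, match="unknown exposure arm"):
            make_exposure_timeline("sideways")

    @pytest.mark.parametrize("breakpoints,duration", [
        (((10.0, 0.0),), 100.0),            # must start at 0
        (((0.0, 0.0), (0.0, 0.6)), 100.0),  # strictly increasing
        (((0.0, -0.1),), 100.0),            # non-negative concentration
        (((0.0, 0.0), (50.0, 0.6)), 50.0),  # duration beyond last breakpoint
    ])
    def test_invalid_schedules_rejected(self, breakpoints, duration):
        with pytest.raises(ValueError):
            ConcentrationSchedule(breakpoints, duration, "induction")

    def test_adapted_concentration_lags_steps(self):
        sch = make_exposure_timeline("emergence")
        t = np.arange(0.0, sch.duration_s, 1.0)
        lagged = adapted_concentration(sch, tau_s=2400.0, t_grid=t)
        inst = sch.conc_at(t)
        # continuous, bounded by the delivered range, and behind each step
        assert lagged.min() >= 0.0 and lagged.max() <= 1.2
        assert np.all(np.abs(np.diff(lagged)) < 1e-3)
        assert lagged[7300] > inst[7300]  # still remembers the 1.2% step
        # converges to the step level after many time constants
        assert lagged[-1] == pytest.approx(0.6, abs=0.02)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

class TestTwoWell:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(a=-1.0)
        with pytest.raises(ValueError):
            SimConfig(noise_amplitude=-0.1)
        with pytest.raises(ValueError):
            SimConfig(adaptation_tau_s=0.0)

    def test_unstable_dt_rejected(self):
        sch = make_exposure_timeline("induction")
        with pytest.raises(ValueError, match="stability"):
            simulate_two_well(SimConfig(dt=1.0), sch, seed=0, t_end=10.0)

    def test_zero_noise_stays_in_awake_well(self):
        cfg = SimConfig(noise_amplitude=0.0, tilt_gain=0.0)
        sch = ConcentrationSchedule(((0.0, 0.6),), 600.0, "induction")
        traj = simulate_two_well(cfg, sch, seed=0)
        assert np.all(traj.x < 0)
        assert not traj.s.any()

    def test_determinism(self):
        cfg = SimConfig()
        sch = make_exposure_timeline("induction")
        a = simulate_two_well(cfg, sch, seed=123, t_end=600.0)
        b = simulate_two_well(cfg, sch, seed=123, t_end=600.0)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.s, b.s)

    def test_symmetric_wells_half_occupancy(self):
        # symmetry forces equal occupancy in the long-run limit
        cfg = SimConfig(noise_amplitude=0.1, tilt_gain=0.0)
        sch = ConcentrationSchedule(((0.0, 0.6),), 100_000.0, "induction")
        traj = simulate_two_well(cfg, sch, seed=2)
        assert occupancy(traj, 0.0, 100_000.0) == pytest.approx(0.5, abs=0.06)

    def test_kramers_rate_agreement(self):
        # mean first-passage time vs the closed-form escape rate, >= 200
        # escapes; agreement within a factor of 1.5 in the small-noise limit
        cfg = SimConfig(noise_amplitude=0.05, tilt_gain=0.0)
        rate = kramers_rate(cfg)
        times = [first_passage_time(cfg, seed=s) for s in range(210)]
        ratio = np.mean(times) * rate
        assert 1 / 1.5 < ratio < 1.5

    def test_kramers_rate_zero_noise(self):
        assert kramers_rate(SimConfig(noise_amplitude=0.0)) == 0.0

    def test_noise_for_relaxation_inverts_kramers(self):
        d = noise_for_relaxation(2400.0)
        assert kramers_rate(SimConfig(noise_amplitude=d, tilt_gain=0.0)) \
            == pytest.approx(1.0 / (2 * 2400.0), rel=1e-9)


class TestOccupancy:
    def test_constant_state(self):
        assert occupancy(_flat_traj(1, 10.0), 0.0, 10.0) == 1.0
        assert occupancy(_flat_traj(0, 10.0), 0.0, 10.0) == 0.0

    def test_alternating_state(self):
        n = 1000
        s = (np.arange(n) % 2).astype(np.uint8)
        traj = StateTrajectory(dt=0.01, x=np.where(s, 1.0, -1.0), s=s)
        assert occupancy(traj, 0.0, 10.0) == pytest.approx(0.5, abs=1e-3)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            occupancy(_flat_traj(1, 10.0), 5.0, 5.0)
        with pytest.raises(ValueError):
            occupancy(_flat_traj(1, 10.0), 20.0, 30.0)

    def test_hysteresis_and_decay(self):
        """Emergence occupancy exceeds induction occupancy in minutes 30-50
        of the final 0.6% step, and the gap shrinks by minutes 110-130."""
        early_i, early_e, late_i, late_e = [], [], [], []
        for seed in range(6):
            cohort = generate_cohort(n_individuals=1, seed=seed)
            ti = cohort.individuals[0].induction.traj
            te = cohort.individuals[0].emergence.traj
            early_i.append(occupancy(ti, 3600.0, 4800.0))
            early_e.append(occupancy(te, 9000.0, 10200.0))
            late_i.append(occupancy(ti, 8400.0, 9600.0))
            late_e.append(occupancy(te, 13800.0, 15000.0))
        early_gap = np.mean(early_e) - np.mean(early_i)
        late_gap = np.mean(late_e) - np.mean(late_i)
        assert early_gap > 0.3
        assert late_gap < early_gap / 2


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

class TestEegSynthesis:
    def test_flat_template_gives_white_spectrum(self):
        freqs = np.arange(0, 125.1, 0.25)
        flat = SpectralTemplateSet(
            freqs_hz=freqs, power=np.full((1, 2, freqs.size), 10.0),
            channel_names=("M2",))
        segs, _ = synthesize_eeg(_flat_traj(0, 120.0), flat, seed=7,
                                 sigma_mod_db=0.0)
        f, p = signal.welch(segs[0][0].astype(float), fs=250, nperseg=512)
        band = p[(f > 2) & (f < 110)]
        assert band.mean() == pytest.approx(10.0, rel=0.05)
        assert band.std() < 0.3 * band.mean()

    def test_delta_power_ratio_matches_templates(self):
        tpl = make_templates(seed=3, n_aux=0, band_gain_sigma=0.0)
        segs_a, _ = synthesize_eeg(_flat_traj(1, 60.0), tpl, seed=5,
                                   sigma_mod_db=0.0)
        segs_w, _ = synthesize_eeg(_flat_traj(0, 60.0), tpl, seed=5,
                                   sigma_mod_db=0.0)
        f, pa = signal.welch(segs_a[0][0].astype(float), fs=250, nperseg=1024)
        _, pw = signal.welch(segs_w[0][0].astype(float), fs=250, nperseg=1024)
        delta = (f >= 0.5) & (f <= 4.0)
        tband = (tpl.freqs_hz >= 0.5) & (tpl.freqs_hz <= 4.0)
        expected = tpl.power[0, 1][tband].mean() / tpl.power[0, 0][tband].mean()
        assert pa[delta].mean() / pw[delta].mean() == pytest.approx(
            expected, rel=0.2)

    def test_same_seed_bit_identical(self):
        tpl = make_templates(seed=1, n_aux=1)
        traj = _flat_traj(0, 20.0)
        a, _ = synthesize_eeg(traj, tpl, seed=9)
        b, _ = synthesize_eeg(traj, tpl, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_rapid_switching_handled_by_crossfade(self):
        # state bouts shorter than a synthesis block blend, never drop
        n = int(20.0 / 0.01)
        s = ((np.arange(n) // 150) % 2).astype(np.uint8)  # 1.5-s bouts
        traj = StateTrajectory(dt=0.01, x=np.where(s, 1.0, -1.0), s=s)
        tpl = make_templates(seed=2, n_aux=0)
        segs, _ = synthesize_eeg(traj, tpl, seed=3)
        assert segs[0].shape == (2, 20 * 250)
        assert np.all(np.isfinite(segs[0]))

    def test_span_shorter_than_block_rejected(self):
        tpl = make_templates(seed=2, n_aux=0)
        with pytest.raises(ValueError, match="span shorter"):
            synthesize_eeg(_flat_traj(0, 20.0), tpl, seed=3,
                           spans=((0.0, 1.0),))


# ---------------------------------------------------------------------------
# EMG synthesis and artifacts
# ---------------------------------------------------------------------------

class TestEmgSynthesis:
    def test_awake_burst_count_poisson(self):
        # 10 awake minutes at 2 bursts/min: count within the Poisson(20)
        # central 99% interval [9, 33]
        segs, _, bursts = synthesize_emg(_flat_traj(0, 600.0), seed=21)
        x = segs[0]
        rms = np.sqrt((x[: 600 * 250] ** 2).reshape(600, 250).mean(axis=1))
        detected = np.flatnonzero(np.diff((rms > 10.0).astype(int)) == 1).size
        assert 8 <= len(bursts) <= 33
        assert 8 <= detected <= 33

    def test_anesthetized_is_quiet_and_unimodal(self):
        segs, _, bursts = synthesize_emg(_flat_traj(1, 600.0), seed=4)
        assert bursts == []
        x = segs[0]
        rms = np.sqrt((x ** 2).reshape(600, 250).mean(axis=1))
        assert rms.max() < 2.0 * np.median(rms)

    def test_burst_mode_ratio(self):
        segs, _, bursts = synthesize_emg(_flat_traj(0, 600.0), seed=5,
                                         burst_amp_ratio=8.0)
        x = segs[0]
        rms = np.sqrt((x[: 600 * 250] ** 2).reshape(600, 250).mean(axis=1))
        # estimate the high mode from seconds fully inside a burst (partially
        # covered seconds dilute the RMS and sit between the two modes)
        full_sec = np.zeros(600, dtype=bool)
        any_sec = np.zeros(600, dtype=bool)
        for onset, dur in bursts:
            full_sec[int(np.ceil(onset + 0.2)): int(onset + dur - 0.2)] = True
            any_sec[int(onset): int(np.ceil(onset + dur))] = True
        assert full_sec.sum() >= 5
        ratio = np.median(rms[full_sec]) / np.median(rms[~any_sec])
        assert ratio == pytest.approx(8.0, rel=0.25)

    def test_determinism(self):
        traj = _flat_traj(0, 120.0)
        a, _, ba = synthesize_emg(traj, seed=6)
        b, _, bb = synthesize_emg(traj, seed=6)
        assert np.array_equal(a[0], b[0]) and ba == bb


class TestInjectArtifacts:
    def test_zero_rate_identity(self, mini_pair):
        rec = mini_pair.induction
        out = inject_artifacts(rec, rate_per_min=0.0, seed=3)
        assert all(np.array_equal(s1.eeg, s2.eeg)
                   for s1, s2 in zip(rec.segments, out.segments))

    def test_amplitude_exceeds_hard_limit(self, mini_pair):
        rec = mini_pair.induction
        out = inject_artifacts(rec, rate_per_min=2.0, amplitude_uv=1500.0,
                               seed=3)
        n_new = len(out.artifact_times) - len(rec.artifact_times)
        assert n_new > 0
        peak = max(np.abs(s.eeg).max() for s in out.segments)
        assert peak > 700.0

    def test_negative_amplitude_rejected(self, mini_pair):
        with pytest.raises(ValueError):
            inject_artifacts(mini_pair.induction, 1.0, amplitude_uv=-5.0)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

class TestCohort:
    def test_cardinality_and_shared_templates(self):
        cfg = mini_cohort_config(n_individuals=2)
        cohort = generate_cohort(config=cfg, seed=5)
        assert len(cohort.recordings) == 4
        assert len(cohort.individuals) == 2
        for ind in cohort.individuals:
            assert ind.induction.channel_names == ind.emergence.channel_names
            assert ind.induction.individual_id == ind.emergence.individual_id

    def test_same_seed_identical(self):
        cfg = mini_cohort_config()
        a = generate_cohort(config=cfg, seed=9)
        b = generate_cohort(config=cfg, seed=9)
        sa = a.individuals[0].emergence.segments
        sb = b.individuals[0].emergence.segments
        assert all(np.array_equal(x.eeg, y.eeg) and np.array_equal(x.emg, y.emg)
                   for x, y in zip(sa, sb))

    def test_needs_at_least_one_individual(self):
        with pytest.raises(ValueError):
            generate_cohort(n_individuals=0)

    def test_analysis_spans_cover_training_and_test(self):
        for arm, spans in ANALYSIS_SPANS.items():
            onset = 1800.0 if arm == "induction" else 7200.0
            covered = [(t0, t1) for t0, t1 in spans]
            # training minutes 10-30 and test minutes 30-130 of final step
            assert any(t0 <= onset + 600 and t1 >= onset + 1800
                       for t0, t1 in covered)
            assert any(t0 <= onset + 1800 and t1 >= onset + 7800
                       for t0, t1 in covered)

    def test_exchangeable_cohort_has_no_tilt(self):
        cfg = mini_cohort_config(exchangeable=True)
        cohort = generate_cohort(config=cfg, seed=3)
        assert cohort.individuals[0].sim_config.tilt_gain == 0.0
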