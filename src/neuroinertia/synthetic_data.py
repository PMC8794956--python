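"""Synthetic EEG/EMG cohorts driven by a two-well stochastic model of
anesthetic state switching.

The latent arousal state of an individual held near the hypnotic EC50 is
modelled as overdamped Brownian motion of a particle in a double-well
potential

    V(x) = (a/4) x^4 - (b/2) x^2 + c(t) x,      c(t) = -k (conc(t) - c_ref)

where ``x < 0`` is the awake well, ``x > 0`` the anesthetized well, and the
anesthetic concentration tilts the landscape: concentrations above the
reference (EC50-like) concentration deepen the anesthetized well.  The well
depths set state occupancy; the noise amplitude ``D`` sets how often the
particle hops the barrier (height ``b^2/(4a)`` when symmetric).  With slow
hopping the initial condition — approaching the final concentration from
wakefulness (induction) or from deep anesthesia (emergence) — leaves a
memory that decays with the barrier-crossing relaxation time.  That memory
is neural inertia, and it is the quantity the downstream classifiers probe.

On top of the latent trajectory the module synthesizes:

* two-channel (M2, V1) EEG plus optional context channels, by shaping white
  noise in the frequency domain with state-dependent spectral templates,
  per-individual band gains and slow per-window spectral modulation;
* an EMG channel with Poisson movement bursts restricted to awake bouts,
  giving the bimodal log-RMS distribution the movement classifier expects;
* optional large-amplitude artifact transients for exercising the
  preprocessing stage.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.fft import irfft

__all__ = [
    "ConcentrationSchedule",
    "SimConfig",
    "StateTrajectory",
    "SpectralTemplateSet",
    "RecordingSegment",
    "SyntheticRecording",
    "IndividualRecordings",
    "Cohort",
    "make_exposure_timeline",
    "adapted_concentration",
    "simulate_two_well",
    "occupancy",
    "kramers_rate",
    "noise_for_relaxation",
    "make_templates",
    "synthesize_eeg",
    "synthesize_emg",
    "inject_artifacts",
    "generate_individual",
    "generate_cohort",
    "ANALYSIS_SPANS",
    "FS_OUT",
]

FS_OUT = 250.0  #: sample rate of every synthesized channel, Hz

# Spans (seconds from recording start) that the analysis actually consumes:
# the oxygen baseline, the 10-30 min training windows of each 0.6% step and
# the 30-130 min test window of the final step.  Synthesizing only these
# spans keeps a six-individual cohort tractable; the latent trajectory is
# always integrated over the full exposure so state memory is preserved.
ANALYSIS_SPANS = {
    "induction": ((0.0, 1800.0), (2400.0, 9600.0)),
    "emergence": ((0.0, 1800.0), (2400.0, 3600.0), (7800.0, 15000.0)),
}


# ---------------------------------------------------------------------------
# exposure timelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcentrationSchedule:
    """Piecewise-constant isoflurane timeline (% atm) for one exposure arm."""

    breakpoints: tuple  # ((time_s, percent), ...)
    duration_s: float
    arm: str

    def __post_init__(self):
        times = [t for t, _ in self.breakpoints]
        concs = [c for _, c in self.breakpoints]
        if not times or times[0] != 0.0:
            raise ValueError("schedule must start at t = 0")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be non-negative")
        if self.duration_s <= times[-1]:
            raise ValueError("duration must exceed the last breakpoint")

    def conc_at(self, t):
        """Concentration (%) at time(s) ``t`` seconds (piecewise constant)."""
        t = np.asarray(t, dtype=float)
        times = np.array([bp[0] for bp in self.breakpoints])
        concs = np.array([bp[1] for bp in self.breakpoints])
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(concs) - 1)
        return concs[idx]

    @property
    def final_step_onset_s(self) -> float:
        """Start time of the last (steady-state 0.6%) concentration step."""
        return self.breakpoints[-1][0]


def make_exposure_timeline(arm: str) -> ConcentrationSchedule:
    """Return the standard exposure timeline for ``arm``.

    induction: 30 min 100% O2, then 0.6% isoflurane for 240 min (270 min).
    emergence: 30 min O2, 60 min 0.6%, 30 min 1.2%, then 0.6% for 240 min
    (360 min).  Both arms end on the same extended 0.6% step, so the only
    difference between them is the history of the initial condition.
    """
    if arm == "induction":
        return ConcentrationSchedule(
            breakpoints=((0.0, 0.0), (1800.0, 0.6)),
            duration_s=270 * 60.0,
            arm="induction",
        )
    if arm == "emergence":
        return ConcentrationSchedule(
            breakpoints=((0.0, 0.0), (1800.0, 0.6), (5400.0, 1.2), (7200.0, 0.6)),
            duration_s=360 * 60.0,
            arm="emergence",
        )
    raise ValueError(f"unknown exposure arm: {arm!r} (expected 'induction' or 'emergence')")


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the double-well Langevin model.

    ``a``/``b`` are the quartic/quadratic well coefficients (unitless;
    barrier height b^2/(4a)), ``tilt_gain`` couples concentration (%) to the
    linear tilt, ``reference_conc`` is the concentration at which the
    potential is symmetric, ``noise_amplitude`` is the diffusion constant D
    and ``dt`` the Euler-Maruyama step (s).
    """

    a: float = 1.0
    b: float = 1.0
    tilt_gain: float = 1.0
    reference_conc: float = 0.6
    noise_amplitude: float = 0.0358
    dt: float = 0.01
    adaptation_tau_s: float | None = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("well coefficients a, b must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude D must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.adaptation_tau_s is not None and self.adaptation_tau_s <= 0:
            raise ValueError("adaptation time constant must be positive")

    def tilt(self, conc):
        """Linear tilt c = -k (conc - reference); negative tilt favors x>0."""
        return -self.tilt_gain * (np.asarray(conc, dtype=float) - self.reference_conc)

    @property
    def barrier_height(self) -> float:
        return self.b ** 2 / (4.0 * self.a)


@dataclass
class StateTrajectory:
    """Latent position and binarized state sampled at the integrator step."""

    dt: float
    x: np.ndarray       # position, unitless
    s: np.ndarray       # uint8; 1 = anesthetized (x > 0), ties keep previous
    t0: float = 0.0

    def __post_init__(self):
        if len(self.x) != len(self.s):
            raise ValueError("position and state series must have equal length")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.x))

    @property
    def duration_s(self) -> float:
        return self.dt * len(self.x)

    def state_slice(self, t_start: float, t_stop: float) -> np.ndarray:
        i0 = int(math.ceil((t_start - self.t0) / self.dt))
        i1 = int(math.floor((t_stop - self.t0) / self.dt))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.s))
        return self.s[i0:i1]


def _drift_roots(a: float, b: float, c: float) -> np.ndarray:
    """Real roots of V'(x) = a x^3 - b x + c (stationary points)."""
    roots = np.roots([a, 0.0, -b, c])
    return np.sort(roots[np.abs(roots.imag) < 1e-9].real)


def awake_minimum(config: SimConfig, conc: float) -> float:
    """Position of the awake-side potential minimum at concentration ``conc``.

    Falls back to the single remaining minimum when the tilt has removed the
    awake well (strong tilt regime).
    """
    c = float(config.tilt(conc))
    roots = _drift_roots(config.a, config.b, c)
    minima = [r for r in roots if 3 * config.a * r * r - config.b > 0]
    if not minima:  # pragma: no cover - valid configs always have a minimum
        raise ValueError("potential has no minimum; invalid configuration")
    return float(min(minima))


def _check_stability(config: SimConfig):
    # Explicit Euler on the cubic drift diverges if dt * V'' gets large over
    # the visited range; bound the range by ~2x the well separation.
    x_span = 2.0 * math.sqrt(config.b / config.a) + 1.0
    max_curv = 3.0 * config.a * x_span ** 2 + config.b
    if config.dt * max_curv > 0.5:
        raise ValueError(
            f"dt = {config.dt} too large for stability "
            f"(dt * max|V''| = {config.dt * max_curv:.2f} > 0.5)"
        )


def _integrate_numpy(x0, a, b, c_of_step, dt, noise):
    x = np.empty(noise.size + 1)
    x[0] = x0
    xi = x0
    for i in range(noise.size):
        xi = xi - (a * xi ** 3 - b * xi + c_of_step[i]) * dt + noise[i]
        x[i + 1] = xi
    return x


try:  # jit the hot loop; the numpy fallback is ~100x slower but identical
    from numba import njit

    _integrate_jit = njit(cache=False)(_integrate_numpy)

    def _integrate(x0, a, b, c_of_step, dt, noise):
        return _integrate_jit(float(x0), float(a), float(b), c_of_step, float(dt), noise)

except ImportError:  # pragma: no cover
    _integrate = _integrate_numpy


def adapted_concentration(schedule: ConcentrationSchedule, tau_s: float,
                          t_grid: np.ndarray) -> np.ndarray:
    """Concentration as felt through a slow first-order adaptation.

    The neural drive lags the delivered concentration with time constant
    ``tau_s`` (exact exponential solution per constant-concentration
    segment, initialized adapted to the baseline).  This slow variable is
    the generator's memory mechanism: it is what makes occupancy at the
    shared final step depend on the arm's history and decay toward the
    symmetric condition with the chosen relaxation time.
    """
    out = np.empty_like(np.asarray(t_grid, dtype=float))
    bps = list(schedule.breakpoints) + [(schedule.duration_s + 1.0, None)]
    level = float(schedule.breakpoints[0][1])
    for (t0, conc), (t1, _) in zip(bps[:-1], bps[1:]):
        sel = (t_grid >= t0) & (t_grid < t1)
        out[sel] = conc + (level - conc) * np.exp(-(t_grid[sel] - t0) / tau_s)
        level = conc + (level - conc) * math.exp(-(t1 - t0) / tau_s)
    return out


def simulate_two_well(
    config: SimConfig,
    schedule: ConcentrationSchedule,
    seed: int,
    t_end: float | None = None,
    initial_state: str = "awake",
) -> StateTrajectory:
    """Integrate the Langevin equation over ``schedule`` (Euler-Maruyama).

    With the default ``adaptation_tau_s = None`` the tilt follows the
    delivered concentration instantaneously (the textbook two-well model);
    when an adaptation time constant is set, the tilt follows the slowly
    adapted concentration instead, decoupling the state-switching timescale
    (set by the noise) from the memory timescale (set by the adaptation).

    ``initial_state`` is ``"awake"`` (start at the awake-well minimum, the
    physical condition for both arms, which begin in oxygen) or ``"random"``
    (start in either well with equal probability — used to build
    arm-exchangeable null cohorts).
    """
    _check_stability(config)
    if t_end is None:
        t_end = schedule.duration_s
    if not 0 < t_end <= schedule.duration_s:
        raise ValueError("t_end must lie within the schedule")
    n_steps = int(round(t_end / config.dt))

    rng = np.random.default_rng(seed)
    t_grid = config.dt * np.arange(n_steps)
    if config.adaptation_tau_s is None:
        conc = schedule.conc_at(t_grid)
    else:
        conc = adapted_concentration(schedule, config.adaptation_tau_s, t_grid)
    c_of_step = np.ascontiguousarray(config.tilt(conc))

    x0 = awake_minimum(config, schedule.conc_at(0.0))
    if initial_state == "random":
        if rng.random() < 0.5:
            x0 = -x0
    elif initial_state != "awake":
        raise ValueError("initial_state must be 'awake' or 'random'")

    sigma = math.sqrt(2.0 * config.noise_amplitude * config.dt)
    noise = sigma * rng.standard_normal(n_steps) if sigma > 0 else np.zeros(n_steps)
    x = _integrate(x0, config.a, config.b, c_of_step, config.dt, noise)

    s = (x > 0).astype(np.uint8)
    ties = np.flatnonzero(x == 0.0)
    for i in ties:  # exact zeros keep the previous state
        s[i] = s[i - 1] if i > 0 else np.uint8(0)
    return StateTrajectory(dt=config.dt, x=x, s=s)


def occupancy(traj: StateTrajectory, t_start: float, t_stop: float) -> float:
    """Fraction of time in the anesthetized state over [t_start, t_stop)."""
    if t_stop <= t_start:
        raise ValueError("empty interval")
    s = traj.state_slice(t_start, t_stop)
    if s.size == 0:
        raise ValueError("interval lies outside the trajectory")
    return float(s.mean())


def kramers_rate(config: SimConfig) -> float:
    """Closed-form escape rate over a symmetric barrier (small-noise limit).

    rate = sqrt(V''(min) |V''(barrier)|) / (2 pi) * exp(-dV / D)
    with V''(min) = 2b, |V''(0)| = b and dV = b^2/(4a).
    """
    if config.noise_amplitude <= 0:
        return 0.0
    prefactor = math.sqrt(2.0 * config.b * config.b) / (2.0 * math.pi)
    return prefactor * math.exp(-config.barrier_height / config.noise_amplitude)


def noise_for_relaxation(relaxation_s: float, a: float = 1.0, b: float = 1.0) -> float:
    """Noise amplitude D giving initial-condition memory time ``relaxation_s``.

    At the symmetric concentration the occupancy difference between arms
    decays at twice the single-well escape rate; inverting the Kramers
    formula for tau = 1/(2 r) gives D.
    """
    if relaxation_s <= 0:
        raise ValueError("relaxation time must be positive")
    prefactor = math.sqrt(2.0) * b / (2.0 * math.pi)
    arg = 2.0 * relaxation_s * prefactor
    if arg <= 1.0:
        raise ValueError("relaxation time too short for this barrier")
    return (b ** 2 / (4.0 * a)) / math.log(arg)


def first_passage_time(config: SimConfig, seed: int, max_t: float = 1e5) -> float:
    """Time to first reach the opposite well minimum, starting awake.

    Monte-Carlo oracle for the Kramers rate: the mean first-passage time from
    one well bottom to the other approximates 1/rate for small D.
    """
    _check_stability(config)
    rng = np.random.default_rng(seed)
    x_min = math.sqrt(config.b / config.a)
    sigma = math.sqrt(2.0 * config.noise_amplitude * config.dt)
    chunk = 200_000
    x0 = -x_min
    t_elapsed = 0.0
    while t_elapsed < max_t:
        noise = sigma * rng.standard_normal(chunk)
        x = _integrate(x0, config.a, config.b, np.zeros(chunk), config.dt, noise)
        hits = np.flatnonzero(x >= x_min)
        if hits.size:
            return t_elapsed + hits[0] * config.dt
        x0 = x[-1]
        t_elapsed += chunk * config.dt
    return math.nan


# ---------------------------------------------------------------------------
# spectral templates and EEG synthesis
# ---------------------------------------------------------------------------

_BAND_CENTERS = np.array([2.0, 7.0, 20.0, 55.0, 100.0])  # Hz, for gain jitter
_MOD_CENTERS = np.geomspace(1.5, 90.0, 8)                # Hz, per-window bumps
_MOD_WIDTH_DEX = 0.22                                    # bump width in log10(f)


@dataclass
class SpectralTemplateSet:
    """State- and channel-dependent EEG power templates (one individual).

    ``power[ch, state, :]`` is a one-sided PSD in uV^2/Hz on ``freqs_hz``;
    state 0 = awake, 1 = anesthetized.  Channel 0/1 are the analyzed M2/V1
    leads; further channels are context leads that only participate in
    re-referencing.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    channel_names: tuple
    band_gains: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.power.shape[0] != len(self.channel_names):
            raise ValueError("one template row per channel required")
        if self.power.shape[1] != 2:
            raise ValueError("templates needed for both states")
        if np.any(self.power <= 0):
            raise ValueError("template powers must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]


def _awake_psd(f):
    f = np.asarray(f, dtype=float)
    bg = 300.0 / (1.0 + (f / 8.0) ** 2.5)
    theta = 100.0 * np.exp(-0.5 * ((f - 7.5) / 1.5) ** 2)
    gamma = 8.0 / (1.0 + np.exp(-(f - 30.0) / 4.0)) / (1.0 + np.exp((f - 80.0) / 6.0))
    return bg + theta + gamma + 0.8


def _anesthetized_psd(f):
    f = np.asarray(f, dtype=float)
    delta = 900.0 * np.exp(-0.5 * ((f - 1.5) / 2.0) ** 2)
    bg = 250.0 / (1.0 + (f / 6.0) ** 3.0)
    return delta + bg + 0.8


def _smooth_gain_curve(f, centers, log_gains):
    """Interpolate per-band log gains to a smooth curve over frequency."""
    logf = np.log10(np.maximum(np.asarray(f, dtype=float), 0.25))
    return np.interp(logf, np.log10(centers), log_gains)


def make_templates(
    seed: int,
    n_aux: int = 2,
    band_gain_sigma: float = 0.2,
    f_max: float = 125.0,
    df: float = 0.25,
) -> SpectralTemplateSet:
    """Build per-individual templates: canonical awake/anesthetized spectra
    (1/f background + theta and 30-80 Hz elevation awake; boosted 0.5-4 Hz
    delta, attenuated high frequencies anesthetized) times log-normal
    per-band gains that differ between individuals and channels."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(0.0, f_max + df / 2, df)
    names = ("M2", "V1") + tuple(f"CTX{i + 1}" for i in range(n_aux))
    power = np.empty((len(names), 2, freqs.size))
    gains = rng.normal(0.0, band_gain_sigma, size=(len(names), _BAND_CENTERS.size))
    base = np.stack([_awake_psd(freqs), _anesthetized_psd(freqs)])
    for ch in range(len(names)):
        g = np.exp(_smooth_gain_curve(freqs, _BAND_CENTERS, gains[ch]))
        power[ch] = base * g
    # keep signal content inside the 1-120 Hz analysis band
    power[:, :, freqs > 120.0] = 1e-4
    return SpectralTemplateSet(freqs_hz=freqs, power=power, channel_names=names,
                               band_gains=gains)


def _mod_basis(freqs):
    logf = np.log10(np.maximum(freqs, 0.25))
    return np.exp(-0.5 * ((logf[None, :] - np.log10(_MOD_CENTERS)[:, None])
                          / _MOD_WIDTH_DEX) ** 2)


def _block_weights(traj, t_start, n_blocks, block_s):
    """Per-block anesthetized fraction used to blend the two templates."""
    w = np.empty(n_blocks)
    for k in range(n_blocks):
        s = traj.state_slice(t_start + k * block_s, t_start + (k + 1) * block_s)
        w[k] = s.mean() if s.size else w[k - 1] if k else 0.0
    return w


def synthesize_eeg(
    traj: StateTrajectory,
    templates: SpectralTemplateSet,
    seed: int,
    spans=None,
    fs: float = FS_OUT,
    block_s: float = 4.0,
    fade_s: float = 0.256,
    sigma_mod_db: float = 2.0,
):
    """Synthesize EEG for every requested span by frequency-domain shaping.

    Each 4-s block gets a random-phase spectrum whose amplitude follows the
    geometric blend of the awake/anesthetized templates at the block's
    latent-state fraction, times a slowly varying per-window modulation
    (``sigma_mod_db`` dB over smooth log-frequency bumps, shared across
    channels).  Consecutive blocks are joined with power-complementary
    raised-cosine cross-fades so short bouts are blended, never dropped.

    Returns ``(segments, starts)``: a list of float32 arrays of shape
    (n_channels, n_samples) and their span start times.
    """
    if spans is None:
        spans = ((0.0, traj.duration_s),)
    rng = np.random.default_rng(seed)
    hop = int(round(block_s * fs))
    n_fade = int(round(fade_s * fs))
    n_block = hop + n_fade
    n_freq = n_block // 2 + 1
    f_block = np.fft.rfftfreq(n_block, 1.0 / fs)
    basis = _mod_basis(f_block)                      # (n_bumps, n_freq)
    ramp_up = np.sin(0.5 * np.pi * (np.arange(n_fade) + 0.5) / n_fade)
    # log-interpolate templates onto the block grid once
    log_tpl = np.empty((templates.n_channels, 2, n_freq))
    for ch in range(templates.n_channels):
        for st in (0, 1):
            log_tpl[ch, st] = np.interp(
                f_block, templates.freqs_hz, np.log(templates.power[ch, st])
            )

    segments = []
    starts = []
    for t0, t1 in spans:
        n_blocks = int(round((t1 - t0) / block_s))
        if n_blocks < 1:
            raise ValueError("span shorter than one synthesis block")
        n_samples = n_blocks * hop
        w = _block_weights(traj, t0, n_blocks, block_s)
        g = rng.normal(0.0, sigma_mod_db, size=(n_blocks, len(_MOD_CENTERS)))
        mod_ln = (g @ basis) * (math.log(10.0) / 10.0)   # dB -> ln power
        out = np.zeros((templates.n_channels, n_samples + n_fade), dtype=np.float32)
        for ch in range(templates.n_channels):
            ln_p = (1.0 - w[:, None]) * log_tpl[ch, 0] + w[:, None] * log_tpl[ch, 1]
            amp = np.sqrt(np.exp(ln_p + mod_ln) * fs * n_block / 2.0)
            z = rng.standard_normal((n_blocks, n_freq, 2))
            spec = amp * (z[..., 0] + 1j * z[..., 1]) / math.sqrt(2.0)
            spec[:, 0] = 0.0
            spec[:, -1] = spec[:, -1].real
            blocks = irfft(spec, n=n_block, axis=1).astype(np.float32)
            blocks[1:, :n_fade] *= ramp_up
            blocks[:, hop:] *= ramp_up[::-1]
            idx = np.arange(n_block)[None, :] + hop * np.arange(n_blocks)[:, None]
            np.add.at(out[ch], idx.ravel(), blocks.ravel())
        segments.append(out[:, :n_samples])
        starts.append(t0)
    return segments, starts


# ---------------------------------------------------------------------------
# EMG synthesis and artifacts
# ---------------------------------------------------------------------------

def synthesize_emg(
    traj: StateTrajectory,
    seed: int,
    spans=None,
    fs: float = FS_OUT,
    base_sigma: float = 3.0,
    burst_rate_per_min: float = 2.0,
    burst_amp_ratio: float = 8.0,
    mean_burst_s: float = 2.0,
):
    """Synthesize an EMG channel: white baseline noise everywhere, plus
    Poisson movement bursts (rate per awake minute) whose RMS is
    ``burst_amp_ratio`` times baseline.  Returns (segments, starts,
    burst_times): segments are float32 arrays, burst_times the ground-truth
    (onset, duration) pairs actually placed."""
    if spans is None:
        spans = ((0.0, traj.duration_s),)
    rng = np.random.default_rng(seed)
    sigma_burst = base_sigma * math.sqrt(max(burst_amp_ratio ** 2 - 1.0, 0.0))
    n_ramp = int(round(0.1 * fs))
    segments, starts, burst_times = [], [], []
    for t0, t1 in spans:
        n = int(round((t1 - t0) * fs))
        sig = rng.normal(0.0, base_sigma, n).astype(np.float32)
        n_cand = rng.poisson(burst_rate_per_min * (t1 - t0) / 60.0)
        onsets = np.sort(rng.uniform(t0, t1, n_cand))
        durations = np.clip(rng.exponential(mean_burst_s, n_cand), 0.5, 8.0)
        for onset, dur in zip(onsets, durations):
            i_state = int((onset - traj.t0) / traj.dt)
            if i_state >= len(traj.s) or traj.s[i_state] == 1:
                continue  # movement only while awake
            i0 = int(round((onset - t0) * fs))
            i1 = min(int(round((onset + dur - t0) * fs)), n)
            if i1 <= i0:
                continue
            env = np.ones(i1 - i0)
            m = min(n_ramp, env.size // 2)
            if m:
                ramp = np.sin(0.5 * np.pi * (np.arange(m) + 0.5) / m)
                env[:m] *= ramp
                env[-m:] *= ramp[::-1]
            sig[i0:i1] += (sigma_burst * env * rng.standard_normal(i1 - i0)).astype(np.float32)
            burst_times.append((float(onset), float(min(dur, (t1 - onset)))))
        segments.append(sig)
        starts.append(t0)
    return segments, starts, burst_times


@dataclass
class RecordingSegment:
    """One contiguous synthesized stretch of a recording."""

    t_start_s: float
    eeg: np.ndarray  # (n_channels, n_samples) float32, uV
    emg: np.ndarray  # (n_samples,) float32, uV

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass
class SyntheticRecording:
    """Paired EEG/EMG signals plus ground truth for one exposure arm."""

    individual_id: int
    arm: str
    schedule: ConcentrationSchedule
    fs: float
    channel_names: tuple
    segments: list
    traj: StateTrajectory
    seed: int
    artifact_times: list = field(default_factory=list)   # (time_s, channel)
    emg_burst_times: list = field(default_factory=list)  # (onset_s, duration_s)

    def __post_init__(self):
        for seg in self.segments:
            if seg.eeg.shape[1] != seg.emg.shape[0]:
                raise ValueError("EEG and EMG segment lengths must match")

    @property
    def duration_synthesized_s(self) -> float:
        return sum(seg.n_samples for seg in self.segments) / self.fs


def inject_artifacts(
    rec: SyntheticRecording,
    rate_per_min: float,
    amplitude_uv: float = 1500.0,
    seed: int = 0,
    duration_s: float = 0.15,
) -> SyntheticRecording:
    """Add sparse large transients (damped 8 Hz oscillations peaking at
    ``amplitude_uv``) to random EEG channels; returns a new recording whose
    ``artifact_times`` lists every injected (time, channel)."""
    if amplitude_uv <= 0:
        raise ValueError("artifact amplitude must be positive")
    rng = np.random.default_rng(seed)
    new_segments = []
    artifact_times = list(rec.artifact_times)
    n_shape = int(round(duration_s * rec.fs))
    t_shape = np.arange(n_shape) / rec.fs
    shape = np.sin(2 * np.pi * 8.0 * t_shape) * np.hanning(n_shape)
    shape = (amplitude_uv / np.abs(shape).max()) * shape
    for seg in rec.segments:
        eeg = seg.eeg.copy()
        span_min = seg.n_samples / rec.fs / 60.0
        n_art = rng.poisson(rate_per_min * span_min) if rate_per_min > 0 else 0
        for _ in range(n_art):
            i0 = int(rng.integers(0, max(seg.n_samples - n_shape, 1)))
            ch = int(rng.integers(0, eeg.shape[0]))
            eeg[ch, i0:i0 + n_shape] += shape[: eeg.shape[1] - i0].astype(np.float32)
            artifact_times.append((seg.t_start_s + i0 / rec.fs, rec.channel_names[ch]))
        new_segments.append(RecordingSegment(seg.t_start_s, eeg, seg.emg))
    return replace(rec, segments=new_segments, artifact_times=artifact_times)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study; defaults reproduce the collapsing-
    inertia condition (relaxation ~= 40 min at the symmetric 0.6% step)."""

    n_individuals: int = 6
    relaxation_target_min: float = 40.0
    a: float = 1.0
    b: float = 1.0
    tilt_gain: float = 0.45
    reference_conc: float = 0.6
    noise_amplitude: float = 0.0676   # barrier hopping every few minutes
    dt: float = 0.01
    n_aux_channels: int = 2
    band_gain_sigma: float = 0.2
    noise_jitter: float = 0.2           # +-20% uniform jitter on D
    sigma_mod_db: float = 2.0
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_uv: float = 1500.0
    emg_burst_rate_per_min: float = 2.0
    emg_burst_amp_ratio: float = 8.0
    exchangeable: bool = False          # no tilt, random initial wells
    spans: object = "analysis"          # "analysis" | "full" | dict arm->spans


@dataclass
class IndividualRecordings:
    individual_id: int
    induction: SyntheticRecording
    emergence: SyntheticRecording
    templates: SpectralTemplateSet
    sim_config: SimConfig


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    individuals: list

    @property
    def recordings(self) -> list:
        out = []
        for ind in self.individuals:
            out.extend([ind.induction, ind.emergence])
        return out


def _spans_for(config: CohortConfig, arm: str, schedule: ConcentrationSchedule):
    if config.spans == "full":
        return ((0.0, schedule.duration_s),)
    if config.spans == "analysis":
        return ANALYSIS_SPANS[arm]
    return tuple(config.spans[arm])


def generate_individual(
    individual_id: int,
    config: CohortConfig,
    seed: int,
) -> IndividualRecordings:
    """Generate one individual's paired induction/emergence recordings.

    Both recordings share the individual's templates and Langevin
    parameters, mirroring two exposures of the same animal; seeds for every
    stochastic stage are spawned deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    templates = make_templates(
        seeds[0], n_aux=config.n_aux_channels, band_gain_sigma=config.band_gain_sigma
    )
    rng = np.random.default_rng(seeds[1])
    d_ind = config.noise_amplitude * (
        1.0 + config.noise_jitter * (2.0 * rng.random() - 1.0))
    sim_config = SimConfig(
        a=config.a, b=config.b,
        tilt_gain=0.0 if config.exchangeable else config.tilt_gain,
        reference_conc=config.reference_conc,
        noise_amplitude=d_ind, dt=config.dt,
        adaptation_tau_s=config.relaxation_target_min * 60.0,
    )
    initial = "random" if config.exchangeable else "awake"

    recs = {}
    for i, arm in enumerate(("induction", "emergence")):
        schedule = make_exposure_timeline(arm)
        spans = _spans_for(config, arm, schedule)
        t_end = max(t1 for _, t1 in spans)
        traj = simulate_two_well(sim_config, schedule, seeds[2 + 3 * i],
                                 t_end=t_end, initial_state=initial)
        eeg_segs, starts = synthesize_eeg(
            traj, templates, seeds[3 + 3 * i], spans=spans,
            sigma_mod_db=config.sigma_mod_db,
        )
        emg_segs, _, bursts = synthesize_emg(
            traj, seeds[4 + 3 * i], spans=spans,
            burst_rate_per_min=config.emg_burst_rate_per_min,
            burst_amp_ratio=config.emg_burst_amp_ratio,
        )
        segments = [
            RecordingSegment(t0, eeg, emg)
            for t0, eeg, emg in zip(starts, eeg_segs, emg_segs)
        ]
        rec = SyntheticRecording(
            individual_id=individual_id, arm=arm, schedule=schedule, fs=FS_OUT,
            channel_names=templates.channel_names, segments=segments, traj=traj,
            seed=seed, emg_burst_times=bursts,
        )
        if config.artifact_rate_per_min > 0:
            rec = inject_artifacts(
                rec, config.artifact_rate_per_min, config.artifact_amplitude_uv,
                seed=seeds[2 + 3 * i] + 7,
            )
        recs[arm] = rec
    return IndividualRecordings(
        individual_id=individual_id, induction=recs["induction"],
        emergence=recs["emergence"], templates=templates, sim_config=sim_config,
    )


def generate_cohort(
    n_individuals: int = 6,
    relaxation_target_min: float = 40.0,
    seed: int = 0,
    config: CohortConfig | None = None,
    **overrides,
) -> Cohort:
    """Generate a cohort of paired recordings with controlled neural inertia.

    The relaxation target sets how fast arm memory (the induction/emergence
    occupancy gap at the final 0.6% step) decays; 40 min produces inertia
    that is strong in test minutes 30-50 and largely collapsed by minutes
    110-130.  Identical (arguments, seed) give identical cohorts.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if config is None:
        config = CohortConfig(
            n_individuals=n_individuals,
            relaxation_target_min=relaxation_target_min,
            **overrides,
        )
    elif overrides:
        config = replace(config, **overrides)
    ind_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in np.random.SeedSequence(seed).spawn(config.n_individuals)
    ]
    individuals = [
        generate_individual(i + 1, config, ind_seeds[i])
        for i in range(config.n_individuals)
    ]
    return Cohort(config=config, seed=seed, individuals=individuals)
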