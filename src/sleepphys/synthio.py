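"""Synthetic multimodal recording sessions with known ground truth.

Everything downstream (staging, state-conditioned calcium metrics, Markov
dynamics, impedance analysis) is exercised on data from this module, so each
generator returns its latent truth alongside the signals:

* :func:`simulate_state_sequence` — a bout-level first-order Markov chain over
  {WAKE, NREM, REM} with geometric dwell times, expanded to a per-window
  hypnogram.
* :func:`synthesize_signals` — EEG shaped as 1/f background plus
  state-conditioned delta/theta band noise, EMG and accelerometer as white
  noise with state-dependent RMS tone.
* :func:`synthesize_calcium` — state-modulated Poisson events convolved with
  an exponential indicator kernel, plus polynomial drift and Gaussian noise.
* :func:`simulate_membrane` / :func:`analytic_impedance` — a two-variable
  linearized resonant membrane (leak + slow negative-feedback branch, the
  standard linear surrogate for an h-current) and its closed-form impedance.

All randomness flows through an explicit integer seed; fixed seed means
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq
from scipy import signal as sps

WAKE, NREM, REM = 0, 1, 2
STATE_NAMES = ("WAKE", "NREM", "REM")
N_STATES = 3


# ---------------------------------------------------------------------------
# state sequences
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """Per-window vigilance labels on a fixed window grid."""

    labels: np.ndarray          # int codes in {0, 1, 2}, one per window
    window_s: float             # seconds per window
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        if not np.isin(self.labels, [WAKE, NREM, REM]).all():
            raise ValueError("labels must be drawn from {WAKE, NREM, REM}")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    @property
    def n_windows(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_windows * self.window_s

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """State code at time(s) ``t`` (seconds); clipped to the last window."""
        idx = np.clip((np.asarray(t) / self.window_s).astype(np.intp),
                      0, self.n_windows - 1)
        return self.labels[idx]


def _validate_stochastic(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (N_STATES, N_STATES):
        raise ValueError("transition matrix must be 3x3")
    if (m < 0).any():
        raise ValueError("transition probabilities must be nonnegative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1 (within 1e-9)")
    return m


def simulate_state_sequence(
    transition_matrix: np.ndarray,
    dwell_windows: np.ndarray | list[float],
    n_windows: int,
    seed: int,
    window_s: float = 2.5,
    start_state: int | None = None,
) -> StateSequence:
    """Simulate a bout-level Markov hypnogram.

    The chain operates at the level of *bouts*: the next state is drawn from
    ``transition_matrix`` (row-stochastic; the diagonal is honoured, so an
    absorbing state stays put), and the bout length in windows is geometric
    with mean ``dwell_windows[state]`` (support >= 1, memoryless — the
    discrete-time analogue of exponential dwell in a first-order Markov
    process).

    Parameters
    ----------
    transition_matrix
        3x3 row-stochastic matrix over (WAKE, NREM, REM).
    dwell_windows
        Mean bout duration per state, in windows (each >= 1).
    n_windows
        Total hypnogram length; the final bout is truncated to fit.
    seed
        RNG seed; fixed seed reproduces the sequence exactly.
    """
    m = _validate_stochastic(transition_matrix)
    dwell = np.asarray(dwell_windows, dtype=float)
    if dwell.shape != (N_STATES,) or (dwell < 1).any():
        raise ValueError("dwell_windows must be 3 means, each >= 1")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")

    rng = np.random.default_rng(seed)
    state = int(rng.integers(N_STATES)) if start_state is None else int(start_state)
    labels = np.empty(n_windows, dtype=np.intp)
    filled = 0
    while filled < n_windows:
        # geometric on {1, 2, ...} with mean = dwell[state]
        p = 1.0 / dwell[state]
        run = int(rng.geometric(p))
        run = min(run, n_windows - filled)
        labels[filled:filled + run] = state
        filled += run
        state = int(rng.choice(N_STATES, p=m[state]))
    return StateSequence(labels=labels, window_s=window_s, seed=seed)


# ---------------------------------------------------------------------------
# EEG / EMG / accelerometer
# ---------------------------------------------------------------------------

@dataclass
class SpectralProfile:
    """State-conditioned spectral/tone targets for signal synthesis.

    Band powers are per-state variances (µV²) of band-limited EEG noise in
    the named band; ``one_over_f_scale`` sets the RMS of the 1/f background
    common to all states. ``emg_tone`` / ``accel_tone`` are per-state RMS of
    the white EMG (µV) and accelerometer (g) channels.
    """

    delta_power: dict[int, float]               # µV², band 0.5-4 Hz
    theta_power: dict[int, float]               # µV², band 5-9 Hz
    emg_tone: dict[int, float]                  # µV RMS
    accel_tone: dict[int, float]                # g RMS
    one_over_f_scale: float = 10.0              # µV RMS of broadband background
    one_over_f_exponent: float = 1.0
    delta_band: tuple[float, float] = (0.5, 4.0)
    theta_band: tuple[float, float] = (5.0, 9.0)

    def __post_init__(self) -> None:
        for d in (self.delta_power, self.theta_power, self.emg_tone, self.accel_tone):
            if any(v < 0 for v in d.values()):
                raise ValueError("powers and tones must be nonnegative")
        if self.delta_band[1] > self.theta_band[0]:
            raise ValueError("delta and theta bands must not overlap")


def default_profile(
    nrem_delta_factor: float = 10.0,
    rem_theta_factor: float = 5.0,
    wake_emg_factor: float = 5.0,
) -> SpectralProfile:
    """Study-condition spectral profile.

    NREM delta power is ``nrem_delta_factor`` x wake delta, REM theta power is
    ``rem_theta_factor`` x wake theta, and wake EMG RMS is
    ``wake_emg_factor`` x sleep EMG; wake also carries the highest
    accelerometer tone (movement).
    """
    return SpectralProfile(
        delta_power={WAKE: 25.0, NREM: 25.0 * nrem_delta_factor, REM: 25.0},
        theta_power={WAKE: 16.0, NREM: 16.0, REM: 16.0 * rem_theta_factor},
        emg_tone={WAKE: 25.0, NREM: 5.0, REM: 5.0},
        accel_tone={WAKE: 0.05, NREM: 0.005, REM: 0.005},
    )


def _one_over_f_noise(n: int, fs: float, exponent: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with |amplitude| ∝ f^(-exponent/2), scaled to target RMS."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0                      # no DC
    x = irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via hard spectral masking."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    x = irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class SyntheticSession:
    """One synthetic subject: raw channels plus all latent ground truth."""

    eeg: np.ndarray                 # (2, n) µV
    emg: np.ndarray                 # (2, n) µV
    accel: np.ndarray               # (3, n) g
    fs: float                       # Hz, shared by all channels
    states: StateSequence           # latent hypnogram
    subject_id: str = "s0"
    seed: int | None = None
    calcium: np.ndarray | None = None       # (cells, n_ca) ΔF/F source traces
    calcium_fs: float | None = None
    true_event_times: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.eeg.shape[-1]
        if self.emg.shape[-1] != n or self.accel.shape[-1] != n:
            raise ValueError("all channels must share duration")


def synthesize_signals(
    states: StateSequence,
    profile: SpectralProfile,
    fs: float = 1000.0,
    seed: int = 0,
) -> SyntheticSession:
    """Render EEG/EMG/accelerometer channels for a hypnogram.

    EEG (2 channels) = common 1/f background + state-gated delta and theta
    band noise + small per-channel white noise so the channels are not
    identical under mean re-referencing. EMG (2 channels, differential pair)
    and accelerometer (3 axes) are white noise with per-sample RMS set by the
    state. Gains are applied per sample from the hypnogram, so window-level
    spectral content follows the state within estimation error.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(states.duration_s * fs))
    t = np.arange(n) / fs
    state_per_sample = states.state_at(t)

    delta_gain = np.sqrt(np.array([profile.delta_power[s] for s in range(N_STATES)]))
    theta_gain = np.sqrt(np.array([profile.theta_power[s] for s in range(N_STATES)]))
    emg_gain = np.array([profile.emg_tone[s] for s in range(N_STATES)])
    acc_gain = np.array([profile.accel_tone[s] for s in range(N_STATES)])

    # each electrode sees its own cortical signal; a shared common-mode term
    # (e.g. reference drift) is what mean re-referencing removes downstream
    def one_channel() -> np.ndarray:
        if profile.one_over_f_scale > 0:
            base = _one_over_f_noise(n, fs, profile.one_over_f_exponent,
                                     profile.one_over_f_scale, rng)
        else:
            base = np.zeros(n)
        delta = (_band_noise(n, fs, profile.delta_band, rng)
                 * delta_gain[state_per_sample])
        theta = (_band_noise(n, fs, profile.theta_band, rng)
                 * theta_gain[state_per_sample])
        return base + delta + theta

    common_mode = (0.5 * profile.one_over_f_scale
                   * _one_over_f_noise(n, fs, 2.0, 1.0, rng)
                   if profile.one_over_f_scale > 0 else np.zeros(n))
    eeg = np.stack([one_channel() + common_mode for _ in range(2)])

    emg_amp = emg_gain[state_per_sample]
    # differential pair: common-mode term cancels, the difference carries tone
    emg_common = 0.5 * emg_amp * rng.standard_normal(n)
    emg = np.stack([
        emg_common + emg_amp * rng.standard_normal(n) / np.sqrt(2),
        emg_common - emg_amp * rng.standard_normal(n) / np.sqrt(2),
    ])
    acc_amp = acc_gain[state_per_sample]
    accel = np.stack([acc_amp * rng.standard_normal(n) for _ in range(3)])

    return SyntheticSession(eeg=eeg, emg=emg, accel=accel, fs=fs,
                            states=states, seed=seed)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def synthesize_calcium(
    states: StateSequence,
    rates_per_min: dict[int, float] | np.ndarray,
    tau_decay_s: float = 1.0,
    fs: float = 4.0,
    noise_sd: float = 0.1,
    drift_poly: np.ndarray | list[float] = (0.0,),
    amplitude_range: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a ΔF/F trace with state-modulated Poisson transients.

    Events arrive as an inhomogeneous Poisson process whose rate is
    ``rates_per_min[state]`` while the hypnogram is in that state. Each event
    adds an amplitude drawn uniformly from ``amplitude_range`` (default
    [1.5, 3.0] ΔF/F, comfortably above the 1.0/0.8 detection thresholds) that
    decays exponentially with ``tau_decay_s``. Polynomial drift
    (``drift_poly``, highest power first, argument = time in s) and white
    Gaussian noise of SD ``noise_sd`` are added.

    Returns
    -------
    trace : ndarray
        ΔF/F samples at ``fs``.
    true_event_times : ndarray
        Ground-truth event times in seconds, sorted.
    """
    if tau_decay_s <= 0:
        raise ValueError("tau_decay_s must be positive")
    if isinstance(rates_per_min, dict):
        rates = np.array([rates_per_min.get(s, 0.0) for s in range(N_STATES)])
    else:
        rates = np.asarray(rates_per_min, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be nonnegative")

    rng = np.random.default_rng(seed)
    n = int(round(states.duration_s * fs))
    t = np.arange(n) / fs

    # thinning over the window grid: per window, Poisson count at that state's rate
    event_times: list[float] = []
    for w in range(states.n_windows):
        lam = rates[states.labels[w]] / 60.0 * states.window_s
        k = rng.poisson(lam)
        if k:
            event_times.extend(w * states.window_s
                               + rng.uniform(0, states.window_s, size=k))
    event_times_arr = np.sort(np.array(event_times))

    trace = np.polyval(np.asarray(drift_poly, dtype=float), t)
    if noise_sd > 0:
        trace = trace + noise_sd * rng.standard_normal(n)
    for et in event_times_arr:
        amp = rng.uniform(*amplitude_range)
        onset = int(np.ceil(et * fs))
        if onset >= n:
            continue
        tail = t[onset:] - et
        trace[onset:] += amp * np.exp(-tail / tau_decay_s)
    return trace, event_times_arr


# ---------------------------------------------------------------------------
# linear resonant membrane
# ---------------------------------------------------------------------------

@dataclass
class MembraneParams:
    """Linearized membrane: leak + slow feedback branch.

    ``g_l`` (nS) and ``c`` (pF) set the passive RC; the slow branch with gain
    ``g_1`` (nS) and time constant ``tau_w`` (ms) produces a high-pass
    contribution that, for sufficient ``g_1``, yields an impedance peak at a
    nonzero frequency — the linear surrogate of h-current resonance.
    """

    g_l: float          # nS
    c: float            # pF
    g_1: float = 0.0    # nS
    tau_w: float = 50.0  # ms

    def __post_init__(self) -> None:
        if self.g_l <= 0 or self.c <= 0:
            raise ValueError("g_l and c must be positive")
        if self.g_1 < 0:
            raise ValueError("g_1 must be nonnegative")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")


def analytic_impedance(params: MembraneParams, freqs_hz: np.ndarray) -> np.ndarray:
    """Closed-form |Z|(f) in MΩ.

    Z(ω) = 1 / (g_L + iωC + g_1/(1 + iωτ_w)); with conductances in nS the
    admittance is in nS so |Z| converts to MΩ by a factor 1000. The DC limit
    is 1/(g_L + g_1).
    """
    f = np.asarray(freqs_hz, dtype=float)
    omega = 2 * np.pi * f
    y = (params.g_l
         + 1j * omega * params.c * 1e-3            # pF·rad/s -> nS (ms units)
         + params.g_1 / (1 + 1j * omega * params.tau_w * 1e-3))
    return 1000.0 / np.abs(y)                       # 1/nS = GΩ -> MΩ


def simulate_membrane(params: MembraneParams, stimulus_pa: np.ndarray,
                      dt_ms: float) -> np.ndarray:
    """Integrate the two-variable linear membrane; returns voltage in mV.

    System (time in ms):  C dv/dt = -g_L v - w + i(t),  τ_w dw/dt = g_1 v - w,
    from rest (v = w = 0). Exact matrix-exponential stepping with
    zero-order-hold input, so accuracy is limited only by the stimulus sample
    rate. ``dt_ms`` must resolve both time constants (dt < τ_w/10 and
    dt < C/g_L/10).
    """
    tau_m = params.c / params.g_l
    if dt_ms >= tau_m / 10 or dt_ms >= params.tau_w / 10:
        raise ValueError(
            f"dt={dt_ms} ms too coarse for tau_m={tau_m:.3g} ms, "
            f"tau_w={params.tau_w:.3g} ms")
    a = np.array([[-params.g_l / params.c, -1.0 / params.c],
                  [params.g_1 / params.tau_w, -1.0 / params.tau_w]])
    b = np.array([[1.0 / params.c], [0.0]])
    c = np.array([[1.0, 0.0]])
    d = np.zeros((1, 1))
    ad, bd, cd, dd, _ = sps.cont2discrete((a, b, c, d), dt_ms, method="zoh")
    num, den = sps.ss2tf(ad, bd, cd, dd)
    i = np.asarray(stimulus_pa, dtype=float)
    return sps.lfilter(num[0], den, i)
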