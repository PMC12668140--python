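"""Deterministic signal conditioning and spectral estimation.

The conditioning chain mirrors standard rodent polysomnography practice:
EEG decimated to 125 Hz, zero-phase 4th-order Butterworth high-pass at
0.5 Hz, mean re-referenced; EMG differentially referenced and high-passed at
300 Hz; multitaper spectrograms (35 Slepian tapers, 5 s window, 2.5 s step)
with EMG/accelerometer RMS on the identical window grid so that per-window
feature vectors line up across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class TimeSeries:
    """Multichannel uniformly sampled signal."""

    samples: np.ndarray     # (channels, time)
    fs: float               # Hz
    units: str = ""
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Spectrogram:
    """Time × frequency power with the window grid that produced it."""

    power: np.ndarray           # (windows, freqs), >= 0
    frequencies: np.ndarray     # Hz, strictly increasing
    window_centers: np.ndarray  # s
    window_s: float
    step_s: float
    n_tapers: int = 1

    def __post_init__(self) -> None:
        if (np.asarray(self.power) < 0).any():
            raise ValueError("power must be nonnegative")
        if (np.diff(self.frequencies) <= 0).any():
            raise ValueError("frequencies must be strictly increasing")


def _zero_phase_highpass(x: np.ndarray, fs: float, cutoff_hz: float,
                         order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def preprocess_eeg(raw: TimeSeries, target_fs: float = 125.0,
                   highpass_hz: float = 0.5) -> TimeSeries:
    """Decimate 1 kHz EEG to 125 Hz, high-pass, and mean re-reference.

    Decimation is ×8 with an anti-aliasing FIR (polyphase resampling); the
    high-pass is a 4th-order Butterworth applied forward-backward (zero
    phase); re-referencing subtracts the per-sample mean across channels.
    """
    if not np.isclose(raw.fs, 1000.0):
        raise ValueError(f"expected 1 kHz input, got {raw.fs} Hz")
    if raw.n_channels < 2:
        raise ValueError("mean re-referencing needs >= 2 channels")
    factor = int(round(raw.fs / target_fs))
    if not np.isclose(raw.fs / factor, target_fs):
        raise ValueError("target_fs must divide fs")
    x = sps.resample_poly(raw.samples, up=1, down=factor, axis=-1,
                          padtype="line")
    x = _zero_phase_highpass(x, target_fs, highpass_hz)
    x = x - x.mean(axis=0, keepdims=True)
    return TimeSeries(x, fs=target_fs, units=raw.units, start_s=raw.start_s)


def preprocess_emg(raw: TimeSeries, pair: tuple[int, int] = (0, 1),
                   highpass_hz: float = 300.0) -> TimeSeries:
    """Differential EMG: channel difference, zero-phase high-pass at 300 Hz."""
    if not np.isclose(raw.fs, 1000.0):
        raise ValueError(f"expected 1 kHz input, got {raw.fs} Hz")
    if raw.n_channels < 2:
        raise ValueError("differential referencing needs two channels")
    diff = raw.samples[pair[0]] - raw.samples[pair[1]]
    x = _zero_phase_highpass(diff[None, :], raw.fs, highpass_hz)
    return TimeSeries(x, fs=raw.fs, units=raw.units, start_s=raw.start_s)


def _window_starts(n_samples: int, fs: float, window_s: float,
                   step_s: float) -> np.ndarray:
    """Start indices of full windows; partial trailing windows are dropped.

    Starts are ``round(k * step_s * fs)`` so the grid stays on the nominal
    step even when ``step_s * fs`` is not an integer (e.g. 2.5 s at 125 Hz);
    this keeps window centers aligned across modalities sampled at
    different rates.
    """
    nper = int(round(window_s * fs))
    if n_samples < nper:
        raise ValueError("signal shorter than one window")
    n_win = int(np.floor((n_samples - nper) / (step_s * fs) + 1e-9)) + 1
    return np.round(np.arange(n_win) * step_s * fs).astype(np.intp)


def multitaper_spectrogram(ts: TimeSeries, window_s: float = 5.0,
                           step_s: float = 2.5, n_tapers: int = 35,
                           channel: int = 0) -> Spectrogram:
    """Sliding-window multitaper power spectral estimate.

    Each window is multiplied by ``n_tapers`` Slepian (DPSS) tapers with
    time-bandwidth NW = (K+1)/2 and the taper periodograms are averaged.
    35 tapers in a 5 s window implies NW = 18, i.e. ±3.6 Hz spectral
    smoothing. Power is normalized so that summing over frequencies
    recovers the windowed signal variance (one-sided density × df).
    """
    nper = int(round(window_s * ts.fs))
    if nper < 2 * n_tapers:
        raise ValueError("window too short for the requested taper count")
    starts = _window_starts(ts.n_samples, ts.fs, window_s, step_s)
    nw = (n_tapers + 1) / 2.0
    tapers = sps.windows.dpss(nper, NW=nw, Kmax=n_tapers)  # (K, nper)

    x = ts.samples[channel]
    frames = np.lib.stride_tricks.sliding_window_view(x, nper)[starts]  # (W, nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / ts.fs)
    power = np.empty((starts.size, freqs.size))
    chunk = 512                      # bound transient memory at (chunk*K*nper)
    for lo in range(0, starts.size, chunk):
        seg = frames[lo:lo + chunk, None, :] * tapers[None, :, :]
        spec = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
        # one-sided scaling: double interior bins, per-taper average
        spec[..., 1:-1 if nper % 2 == 0 else None] *= 2.0
        power[lo:lo + chunk] = spec.mean(axis=1) / nper
    # nominal centers: identical grid across modalities regardless of fs
    centers = np.arange(starts.size) * step_s + window_s / 2.0
    return Spectrogram(power=power, frequencies=freqs, window_centers=centers,
                       window_s=window_s, step_s=step_s, n_tapers=n_tapers)


def windowed_rms(ts: TimeSeries, window_s: float = 5.0, step_s: float = 2.5,
                 channel: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-window RMS on the spectrogram grid; returns (centers_s, rms)."""
    nper = int(round(window_s * ts.fs))
    starts = _window_starts(ts.n_samples, ts.fs, window_s, step_s)
    x = ts.samples[channel]
    frames = np.lib.stride_tricks.sliding_window_view(x, nper)[starts]
    rms = np.sqrt((frames ** 2).mean(axis=1))
    centers = np.arange(starts.size) * step_s + window_s / 2.0
    return centers, rms


def band_fraction(spec: Spectrogram, band: tuple[float, float] = (0.5, 4.0),
                  total_band: tuple[float, float] = (0.5, 62.5)) -> np.ndarray:
    """Per-window fraction of power in ``band`` relative to ``total_band``.

    With the default bands this is slow-wave activity (SWA): delta-band
    (0.5–4 Hz) power as a fraction of all retained power. Always in [0, 1].
    """
    f = spec.frequencies
    if not (total_band[0] <= band[0] < band[1] <= total_band[1]):
        raise ValueError("band must be non-empty and inside total_band")
    in_band = (f >= band[0]) & (f <= band[1])
    in_total = (f >= total_band[0]) & (f <= total_band[1])
    if not in_band.any():
        raise ValueError("band contains no frequency bins")
    num = spec.power[:, in_band].sum(axis=1)
    den = spec.power[:, in_total].sum(axis=1)
    out = np.zeros(num.shape)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def power_ratio(spec_post: Spectrogram, spec_pre: Spectrogram) -> np.ndarray:
    """Mean-over-windows power ratio post/pre, per frequency.

    Frequencies where the pre spectrum has zero mean power are returned as
    NaN rather than raising.
    """
    if not np.array_equal(spec_post.frequencies, spec_pre.frequencies):
        raise ValueError("frequency grids must match")
    pre = spec_pre.power.mean(axis=0)
    post = spec_post.power.mean(axis=0)
    out = np.full(pre.shape, np.nan)
    nz = pre > 0
    out[nz] = post[nz] / pre[nz]
    return out


def thermal_trace(frames: np.ndarray, frame_rate_hz: float = 0.1,
                  hot_fraction: float = 0.01, smooth_s: float = 300.0,
                  baseline: tuple[float, float] | None = None) -> np.ndarray:
    """Body-temperature time course from a thermal frame stack.

    Per frame the subject is taken as the hottest ``hot_fraction`` of pixels
    and summarized by their median; the series is then smoothed with a moving
    median of ``smooth_s`` seconds (robust to single-frame flat-field
    artifacts). If ``baseline=(t0, t1)`` is given (seconds), the mean over
    that interval is subtracted (normalization to a reference hour).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (frame, y, x) stack")
    npix = frames.shape[1] * frames.shape[2]
    k = max(1, int(round(hot_fraction * npix)))
    flat = frames.reshape(frames.shape[0], npix)
    hottest = np.partition(flat, npix - k, axis=1)[:, npix - k:]
    temp = np.median(hottest, axis=1)

    win = int(round(smooth_s * frame_rate_hz))
    if win > 1:
        win += (win % 2 == 0)        # odd length, centered
        pad = win // 2
        padded = np.pad(temp, pad, mode="edge")
        temp = np.median(np.lib.stride_tricks.sliding_window_view(padded, win),
                         axis=1)
    if baseline is not None:
        t = np.arange(temp.size) / frame_rate_hz
        sel = (t >= baseline[0]) & (t < baseline[1])
        if not sel.any():
            raise ValueError("baseline interval not covered by trace")
        temp = temp - temp[sel].mean()
    return temp
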