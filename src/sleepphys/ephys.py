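"""Intrinsic-property extraction from patch-clamp sweep sets.

Three protocols are analyzed:

1. **Chirp (ZAP)** — an exponentially swept sinusoidal current (0.2 → 40 Hz
   over 20 s). The impedance amplitude profile |Z|(f) is the ratio of the
   Fourier transforms of voltage and current; the frequency of maximal
   impedance is the resonant frequency fR, resonance strength is
   |Z|max/|Z|(0.5 Hz), and the 3 dB cutoff is the first frequency above fR
   where |Z| falls to √0.5·|Z|max. Cells with fR > 2 Hz are flagged as
   ET-like (extratelencephalic-type) physiology.
2. **Subthreshold steps** — 11 one-second square steps, −150 → +50 pA in
   20 pA increments: maximum and steady-state input resistance from the
   linear (hyperpolarizing) portion of the I–V relation, sag ratio
   (Rin_max/Rin_steady), and rebound slope (post-offset rebound amplitude
   regressed on steady-state potential).
3. **Suprathreshold steps** — +50 pA increments to 0.95 nA: rheobase, spike
   threshold (first crossing of dV/dt = 20 V/s), max/min dV/dt, half-width,
   first ISI, and spike-frequency accommodation (2nd ISI / last ISI from the
   first train with >= 10 spikes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SweepSet:
    """Paired stimulus/response sweeps for one protocol."""

    stimulus_pa: np.ndarray     # (sweeps, samples) or (samples,)
    voltage_mv: np.ndarray      # same shape
    dt_ms: float
    protocol: str = "chirp"     # chirp | sub-steps | supra-steps

    def __post_init__(self) -> None:
        self.stimulus_pa = np.atleast_2d(np.asarray(self.stimulus_pa, float))
        self.voltage_mv = np.atleast_2d(np.asarray(self.voltage_mv, float))
        if self.stimulus_pa.shape != self.voltage_mv.shape:
            raise ValueError("stimulus and response must share shape")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")


@dataclass
class ImpedanceProfile:
    """|Z|(f) over the stimulated band with resonance metrics."""

    frequencies: np.ndarray     # Hz
    z_mohm: np.ndarray          # MΩ, >= 0

    def __post_init__(self) -> None:
        if (self.z_mohm < 0).any():
            raise ValueError("|Z| must be nonnegative")


def make_chirp(f0: float = 0.2, f1: float = 40.0, duration_s: float = 20.0,
               amplitude_pa: float = 20.0, dt_ms: float = 0.1) -> np.ndarray:
    """Exponential (log-frequency) chirp current.

    Phase φ(t) = 2π·f0·T/ln(f1/f0)·(e^{t·ln(f1/f0)/T} − 1), so the
    instantaneous frequency sweeps from f0 at t = 0 to f1 at t = T, passing
    the geometric mean √(f0·f1) at T/2.
    """
    if not f1 > f0 > 0:
        raise ValueError("need f1 > f0 > 0")
    t = np.arange(0, duration_s, dt_ms / 1000.0)
    k = np.log(f1 / f0) / duration_s
    phase = 2 * np.pi * f0 / k * (np.exp(k * t) - 1.0)
    return amplitude_pa * np.sin(phase)


def chirp_instantaneous_frequency(t_s: np.ndarray | float, f0: float = 0.2,
                                  f1: float = 40.0,
                                  duration_s: float = 20.0) -> np.ndarray:
    """Instantaneous frequency of the exponential chirp at time ``t_s``."""
    k = np.log(f1 / f0) / duration_s
    return f0 * np.exp(k * np.asarray(t_s, dtype=float))


def impedance_profile(sweep: SweepSet, band: tuple[float, float] = (0.2, 40.0),
                      smooth: bool = False) -> ImpedanceProfile:
    """|FFT(V)| / |FFT(I)| on the stimulated band, in MΩ.

    With voltage in mV and current in pA the raw ratio is in GΩ, converted
    to MΩ. Multiple sweeps are averaged in the spectral domain. Optional
    3-point median smoothing of the profile (off by default).
    """
    if sweep.protocol != "chirp":
        raise ValueError("impedance_profile expects a chirp sweep")
    n = sweep.stimulus_pa.shape[1]
    freqs = np.fft.rfftfreq(n, d=sweep.dt_ms / 1000.0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    v = np.abs(np.fft.rfft(sweep.voltage_mv, axis=1)).mean(axis=0)
    i = np.abs(np.fft.rfft(sweep.stimulus_pa, axis=1)).mean(axis=0)
    if (i[sel] == 0).any():
        raise ValueError("stimulus spectrum vanishes inside the band")
    z = 1000.0 * v[sel] / i[sel]          # mV/pA = GΩ -> MΩ
    if smooth:
        z = np.concatenate([[z[0]],
                            np.median(np.lib.stride_tricks.sliding_window_view(z, 3),
                                      axis=1),
                            [z[-1]]])
    return ImpedanceProfile(frequencies=freqs[sel], z_mohm=z)


def resonance_metrics(z: ImpedanceProfile,
                      ref_hz: float = 0.5) -> tuple[float, float, float]:
    """(fR, resonance strength, 3 dB cutoff) from an impedance profile.

    fR = argmax |Z|; strength = |Z|max / |Z|(ref_hz) with linear
    interpolation at the reference frequency; f_3dB = first frequency above
    fR where |Z| <= √0.5·|Z|max (band edge if no crossing). All three are
    invariant under positive rescaling of |Z|.
    """
    f, zz = z.frequencies, z.z_mohm
    if ref_hz < f[0] or ref_hz > f[-1]:
        raise ValueError("profile must cover the reference frequency")
    imax = int(np.argmax(zz))
    fr = float(f[imax])
    zmax = zz[imax]
    zref = float(np.interp(ref_hz, f, zz))
    strength = float(zmax / zref)
    target = np.sqrt(0.5) * zmax
    above = zz[imax:]
    cross = np.flatnonzero(above <= target)
    f3db = float(f[imax + cross[0]]) if cross.size else float(f[-1])
    return fr, strength, f3db


def classify_et(fr_hz: float, threshold_hz: float = 2.0) -> bool:
    """ET-like physiology flag: resonant frequency strictly above 2 Hz."""
    return fr_hz > threshold_hz


def _detect_spikes(v: np.ndarray, dt_ms: float,
                   dvdt_thresh_v_per_s: float = 20.0,
                   v_thresh_mv: float = -20.0) -> np.ndarray:
    """Spike peak indices: local maxima above ``v_thresh_mv`` preceded by a
    dV/dt crossing of the threshold."""
    dvdt = np.gradient(v) / dt_ms          # mV/ms = V/s
    fast = dvdt > dvdt_thresh_v_per_s
    high = v > v_thresh_mv
    candidates = np.flatnonzero(high[1:-1] & (v[1:-1] >= v[:-2])
                                & (v[1:-1] > v[2:])) + 1
    peaks = []
    for p in candidates:
        lo = max(0, p - int(5.0 / dt_ms))
        if fast[lo:p + 1].any():
            if peaks and (p - peaks[-1]) * dt_ms < 1.0:
                continue
            peaks.append(p)
    return np.array(peaks, dtype=int)


def subthreshold_step_metrics(
    sweeps: SweepSet,
    step_window: tuple[float, float],
    steady_window_ms: float = 200.0,
    baseline_ms: float = 100.0,
    linear_max_pa: float = -10.0,
) -> dict[str, float]:
    """Input resistance, sag ratio, and rebound slope from square steps.

    ``step_window`` gives (onset_s, offset_s) of the current step. Peak
    deflection and the mean over the final ``steady_window_ms`` of the step
    are each regressed on injected current over the linear (hyperpolarizing,
    I <= ``linear_max_pa``) portion; sag = Rin_max / Rin_steady. Rebound
    amplitude (post-offset extremum relative to pre-step baseline) is
    regressed on steady-state potential. Sweeps containing spikes during the
    step are excluded.
    """
    dt = sweeps.dt_ms
    on = int(round(step_window[0] * 1000.0 / dt))
    off = int(round(step_window[1] * 1000.0 / dt))
    nb = int(round(baseline_ms / dt))
    nsteady = int(round(steady_window_ms / dt))

    amps, peaks, steadies, rebounds = [], [], [], []
    for i_tr, v_tr in zip(sweeps.stimulus_pa, sweeps.voltage_mv):
        amp = i_tr[on:off].mean()
        if _detect_spikes(v_tr[on:off], dt).size:
            continue
        base = v_tr[max(0, on - nb):on].mean()
        dv = v_tr[on:off] - base
        peak = dv[np.argmax(np.abs(dv))]
        steady = dv[-nsteady:].mean()
        post = v_tr[off:] - base
        # rebound = overshoot beyond baseline opposite the step polarity
        # (zero for a passive membrane, positive after hyperpolarization
        # with an h-current-like slow branch)
        if post.size == 0:
            rebound = np.nan
        elif amp < 0:
            rebound = max(post.max(), 0.0)
        else:
            rebound = min(post.min(), 0.0)
        amps.append(amp)
        peaks.append(peak)
        steadies.append(steady)
        rebounds.append(rebound)
    amps_arr = np.array(amps)
    lin = amps_arr <= linear_max_pa
    if lin.sum() < 2:
        raise ValueError("too few hyperpolarizing sweeps for the I-V fit")
    # slope in mV/pA = GΩ -> MΩ
    rin_max = 1000.0 * np.polyfit(amps_arr[lin], np.array(peaks)[lin], 1)[0]
    rin_steady = 1000.0 * np.polyfit(amps_arr[lin], np.array(steadies)[lin], 1)[0]
    vsteady = np.array(steadies)[lin]
    reb = np.array(rebounds)[lin]
    rebound_slope = (np.polyfit(vsteady, reb, 1)[0]
                     if np.ptp(vsteady) > 0 else 0.0)
    return {
        "rin_max_mohm": float(rin_max),
        "rin_steady_mohm": float(rin_steady),
        "sag_ratio": float(rin_max / rin_steady),
        "rebound_slope": float(rebound_slope),
    }


def suprathreshold_metrics(
    sweeps: SweepSet,
    step_window: tuple[float, float],
    dvdt_thresh_v_per_s: float = 20.0,
) -> dict[str, float]:
    """Rheobase and single-spike / train metrics from depolarizing steps.

    Sweeps must be ordered by increasing current. Rheobase is the smallest
    step current evoking >= 1 spike; threshold, max/min dV/dt and half-width
    come from the first spike at rheobase; the first ISI from the minimal
    current evoking >= 2 spikes; SFA (2nd ISI / last ISI) from the first
    train with >= 10 spikes. Undefined quantities are returned as NaN.
    """
    dt = sweeps.dt_ms
    on = int(round(step_window[0] * 1000.0 / dt))
    off = int(round(step_window[1] * 1000.0 / dt))
    out = {k: float("nan") for k in
           ("rheobase_pa", "ap_threshold_mv", "max_dvdt_v_per_s",
            "min_dvdt_v_per_s", "half_width_ms", "first_isi_ms", "sfa")}
    rheo_done = isi_done = sfa_done = False
    for i_tr, v_tr in zip(sweeps.stimulus_pa, sweeps.voltage_mv):
        seg = v_tr[on:off]
        peaks = _detect_spikes(seg, dt, dvdt_thresh_v_per_s)
        if peaks.size == 0:
            continue
        amp = i_tr[on:off].mean()
        if not rheo_done:
            out["rheobase_pa"] = float(amp)
            p = peaks[0]
            dvdt = np.gradient(seg) / dt
            # walk back from the peak to the threshold crossing
            pre = np.flatnonzero(dvdt[:p + 1] <= dvdt_thresh_v_per_s)
            t_idx = pre[-1] + 1 if pre.size and pre[-1] + 1 <= p else 0
            vth = seg[t_idx]
            out["ap_threshold_mv"] = float(vth)
            stop = peaks[1] if peaks.size > 1 else seg.size
            out["max_dvdt_v_per_s"] = float(dvdt[t_idx:stop].max())
            out["min_dvdt_v_per_s"] = float(dvdt[t_idx:stop].min())
            half = vth + 0.5 * (seg[p] - vth)
            up = np.flatnonzero(seg[t_idx:p + 1] >= half)
            down = np.flatnonzero(seg[p:stop] <= half)
            if up.size and down.size:
                out["half_width_ms"] = float((p - t_idx - up[0] + down[0]) * dt)
            rheo_done = True
        if peaks.size >= 2 and not isi_done:
            out["first_isi_ms"] = float((peaks[1] - peaks[0]) * dt)
            isi_done = True
        if peaks.size >= 10 and not sfa_done:
            isis = np.diff(peaks) * dt
            out["sfa"] = float(isis[1] / isis[-1])
            sfa_done = True
    return out
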