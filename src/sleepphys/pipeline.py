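"""Session container, file I/O, configuration, and end-to-end study drivers.

A recording session lives in one HDF5 file: raw channels under ``/raw``,
derived arrays under ``/derived``, and generator ground truth under
``/truth``. EDF is supported read-only through MNE for external EEG; a
minimal 16-bit EDF writer is included so round-trip fixtures can be built
without binary assets. Delimited-text tables go through pandas.

:func:`run_pipeline` chains the stages (simulate → preprocess → stage →
metrics/calcium) into a machine-readable JSON report, deterministic for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import metrics as mx
from . import sigproc as sp
from . import staging as stg
from . import synthio as syn


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline tunables with their default (printed) settings."""

    seed: int = 0
    n_subjects: int = 6
    duration_s: float = 7200.0
    fs: float = 1000.0
    window_s: float = 5.0
    step_s: float = 2.5
    n_tapers: int = 35
    nmf_rank: int = 6
    min_run_windows: int = 15
    state_window_s: float = 2.5
    dwell_windows: tuple[float, float, float] = (60.0, 60.0, 60.0)
    transition_matrix: tuple = ((0.0, 0.95, 0.05),
                               (0.60, 0.0, 0.40),
                               (0.80, 0.20, 0.0))
    nrem_delta_factor: float = 10.0
    rem_theta_factor: float = 5.0
    wake_emg_factor: float = 5.0
    calcium_rates_per_min: tuple[float, float, float] = (0.2, 2.0, 1.0)
    calcium_noise_sd: float = 0.1
    calcium_fs: float = 4.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("dwell_windows", "calcium_rates_per_min"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "transition_matrix" in raw:
            raw["transition_matrix"] = tuple(tuple(r) for r in raw["transition_matrix"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

def write_session(path: str | Path, session: syn.SyntheticSession) -> None:
    """Persist a synthetic session with its ground truth to HDF5."""
    with h5py.File(path, "w") as f:
        raw = f.create_group("raw")
        for name, arr in (("eeg", session.eeg), ("emg", session.emg),
                          ("accel", session.accel)):
            raw.create_dataset(name, data=arr)
        raw.attrs["fs"] = session.fs
        raw.attrs["subject_id"] = session.subject_id
        if session.seed is not None:
            raw.attrs["seed"] = session.seed
        truth = f.create_group("truth")
        truth.create_dataset("state_labels", data=session.states.labels)
        truth.attrs["window_s"] = session.states.window_s
        if session.calcium is not None:
            truth.create_dataset("calcium", data=session.calcium)
            truth.attrs["calcium_fs"] = session.calcium_fs
            ev = truth.create_group("events")
            for i, times in enumerate(session.true_event_times):
                ev.create_dataset(f"cell{i}", data=times)


def read_session(path: str | Path) -> syn.SyntheticSession:
    """Read back a session written by :func:`write_session` (lossless)."""
    with h5py.File(path, "r") as f:
        raw = f["raw"]
        states = syn.StateSequence(
            labels=f["truth/state_labels"][()],
            window_s=float(f["truth"].attrs["window_s"]),
            seed=int(raw.attrs["seed"]) if "seed" in raw.attrs else None)
        calcium = None
        calcium_fs = None
        events: list[np.ndarray] = []
        if "calcium" in f["truth"]:
            calcium = f["truth/calcium"][()]
            calcium_fs = float(f["truth"].attrs["calcium_fs"])
            ev = f["truth/events"]
            events = [ev[f"cell{i}"][()] for i in range(len(ev))]
        return syn.SyntheticSession(
            eeg=raw["eeg"][()], emg=raw["emg"][()], accel=raw["accel"][()],
            fs=float(raw.attrs["fs"]), states=states,
            subject_id=str(raw.attrs["subject_id"]),
            seed=int(raw.attrs["seed"]) if "seed" in raw.attrs else None,
            calcium=calcium, calcium_fs=calcium_fs, true_event_times=events)


# ---------------------------------------------------------------------------
# EDF I/O and delimited tables
# ---------------------------------------------------------------------------

def write_edf(path: str | Path, samples: np.ndarray, fs: float,
              channel_labels: list[str] | None = None,
              physical_unit: str = "uV") -> None:
    """Write a minimal EDF file (16-bit, one data record per second).

    Covers what the round-trip tests and external viewers need: standard
    256-byte header, per-channel physical/digital scaling, integer-second
    records. Samples are truncated to whole seconds.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch = x.shape[0]
    spr = int(round(fs))
    n_rec = x.shape[1] // spr
    if n_rec < 1:
        raise ValueError("need at least one second of data")
    x = x[:, :n_rec * spr]
    labels = channel_labels or [f"ch{i}" for i in range(n_ch)]

    phys_min = np.minimum(x.min(axis=1), -1.0)
    phys_max = np.maximum(x.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("EDF", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(physical_unit, 8) for _ in labels),
        b"".join(pad(f"{phys_min[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(pad(f"{phys_max[i]:.6g}", 8) for i in range(n_ch)),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(spr), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ])
    with open(path, "wb") as f:
        f.write(hdr + sig)
        for r in range(n_rec):
            for i in range(n_ch):
                seg = x[i, r * spr:(r + 1) * spr]
                dig = np.round((seg - phys_min[i]) * scale[i] + dig_min)
                f.write(dig.astype("<i2").tobytes())


def read_edf(path: str | Path) -> sp.TimeSeries:
    """Read an EDF file into a TimeSeries (requires mne)."""
    import mne

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such EDF file: {p}")
    raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    return sp.TimeSeries(samples=raw.get_data(units="uV"),
                         fs=float(raw.info["sfreq"]), units="uV")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such table: {p}")
    return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

def simulate_subject(cfg: RunConfig, subject: int) -> syn.SyntheticSession:
    """One synthetic subject under the study conditions in ``cfg``."""
    seed = cfg.seed + 1009 * (subject + 1)
    n_windows = int(round(cfg.duration_s / cfg.state_window_s))
    states = syn.simulate_state_sequence(
        np.array(cfg.transition_matrix), np.array(cfg.dwell_windows),
        n_windows, seed=seed, window_s=cfg.state_window_s)
    profile = syn.default_profile(cfg.nrem_delta_factor, cfg.rem_theta_factor,
                                  cfg.wake_emg_factor)
    session = syn.synthesize_signals(states, profile, fs=cfg.fs, seed=seed + 1)
    session.subject_id = f"s{subject}"
    return session


def session_features(session: syn.SyntheticSession, cfg: RunConfig | None = None
                     ) -> tuple[sp.Spectrogram, np.ndarray, np.ndarray, stg.Hypnogram]:
    """Preprocess one session into staging inputs.

    Returns the EEG multitaper spectrogram (decimated signal), EMG RMS and
    accelerometer-magnitude RMS on the same window grid, and the ground-truth
    hypnogram sampled at the spectrogram window centers.
    """
    cfg = cfg or RunConfig()
    eeg = sp.preprocess_eeg(sp.TimeSeries(session.eeg, fs=session.fs, units="uV"))
    emg = sp.preprocess_emg(sp.TimeSeries(session.emg, fs=session.fs, units="uV"))
    spec = sp.multitaper_spectrogram(eeg, cfg.window_s, cfg.step_s, cfg.n_tapers)
    _, emg_rms = sp.windowed_rms(emg, cfg.window_s, cfg.step_s)
    accel_mag = np.linalg.norm(session.accel, axis=0)
    _, acc_rms = sp.windowed_rms(sp.TimeSeries(accel_mag, fs=session.fs),
                                 cfg.window_s, cfg.step_s)
    n = min(spec.power.shape[0], emg_rms.size, acc_rms.size)
    spec = sp.Spectrogram(power=spec.power[:n], frequencies=spec.frequencies,
                          window_centers=spec.window_centers[:n],
                          window_s=spec.window_s, step_s=spec.step_s,
                          n_tapers=spec.n_tapers)
    truth = stg.Hypnogram(labels=session.states.state_at(spec.window_centers),
                          window_centers=spec.window_centers,
                          provenance="manual")
    return spec, emg_rms[:n], acc_rms[:n], truth


def run_staging_study(cfg: RunConfig | None = None) -> stg.CVReport:
    """Generate the synthetic cohort and run leave-one-subject-out staging.

    Sessions are synthesized one at a time and reduced to windowed features
    immediately, so memory stays bounded at one subject's raw signals.
    """
    cfg = cfg or RunConfig()
    specs, emgs, accs, truths = [], [], [], []
    for s in range(cfg.n_subjects):
        session = simulate_subject(cfg, s)
        spec, emg_rms, acc_rms, truth = session_features(session, cfg)
        specs.append(spec)
        emgs.append(emg_rms)
        accs.append(acc_rms)
        truths.append(truth)
        del session
    return stg.loso_cv(spectrograms=specs, emg_rms=emgs, accel_rms=accs,
                       labels=truths, seed=cfg.seed,
                       min_run=cfg.min_run_windows,
                       subject_ids=[f"s{i}" for i in range(cfg.n_subjects)])


def run_pipeline(cfg: RunConfig | None = None,
                 out_path: str | Path | None = None) -> dict:
    """End-to-end study: staging CV, Markov recovery, calcium preferences.

    Returns (and optionally writes) a JSON-serializable report; identical
    config and seed give an identical report.
    """
    cfg = cfg or RunConfig()
    report: dict = {"config": dataclasses.asdict(cfg)}

    cv = run_staging_study(cfg)
    report["staging"] = {
        "overall_accuracy": cv.overall_accuracy,
        "fold_accuracies": cv.fold_accuracies,
        "confusion": cv.confusion.tolist(),
    }

    # Markov transition recovery on a long bout sequence
    tm = np.array(cfg.transition_matrix)
    states = syn.simulate_state_sequence(tm, np.array(cfg.dwell_windows),
                                         n_windows=200_000, seed=cfg.seed + 7,
                                         window_s=cfg.state_window_s)
    h = stg.Hypnogram(labels=states.labels,
                      window_centers=(np.arange(states.n_windows) + 0.5)
                      * cfg.state_window_s)
    bouts = mx.bout_table(h, cfg.state_window_s)
    est = mx.transition_matrix(bouts)
    report["markov"] = {
        "generating": tm.tolist(),
        "estimated": np.nan_to_num(est.probabilities).tolist(),
        "sup_norm_error": float(np.nanmax(np.abs(est.probabilities - tm))),
        "n_bouts": int(len(bouts.table)),
    }

    # calcium: one synthetic cohort of cells, detection + state preference
    rates = dict(enumerate(cfg.calcium_rates_per_min))
    ca_states = syn.simulate_state_sequence(
        tm, np.array(cfg.dwell_windows), n_windows=int(3600 / cfg.state_window_s),
        seed=cfg.seed + 11, window_s=cfg.state_window_s)
    truth_h = stg.Hypnogram(labels=ca_states.labels,
                            window_centers=(np.arange(ca_states.n_windows) + 0.5)
                            * cfg.state_window_s)
    s_rows, prefs = [], []
    for cell in range(20):
        trace, _ = syn.synthesize_calcium(ca_states, rates, fs=cfg.calcium_fs,
                                          noise_sd=cfg.calcium_noise_sd,
                                          seed=cfg.seed + 100 + cell)
        train = ca.detect_transients(trace, fs=cfg.calcium_fs,
                                     cell_id=f"c{cell}")
        r, counts, minutes = ca.state_rates(train, truth_h, cfg.state_window_s)
        pref = ca.state_preference(r, counts, minutes)
        prefs.append(pref)
        if pref.included:
            s_rows.append(pref.s)
    _, proportions = ca.simplex_coordinates(np.array(s_rows))
    report["calcium"] = {
        "n_cells": len(prefs),
        "n_included": int(sum(p.included for p in prefs)),
        "preferred_proportions": dict(zip(syn.STATE_NAMES, proportions.tolist())),
    }

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return report
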