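"""Calcium-trace conditioning, transient detection, and state preference.

Miniscope traces are detrended with a cubic polynomial and normalized to the
raw-trace mean to yield ΔF/F; transients are local maxima exceeding 100%
ΔF/F with >= 80% prominence and >= 1 s separation. The two-photon variant
thresholds a baseline-normalized trace at mean + 3 SD. Per-state transient
rates feed the state-preference index S_i = F_i / Σ_j F_j, summarized as
survivor curves and barycentric (simplex) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .staging import Hypnogram
from .synthio import N_STATES, STATE_NAMES


@dataclass
class TransientTrain:
    """Detected event times for one cell."""

    event_times_s: np.ndarray
    fs: float
    cell_id: str = "c0"

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        if t.size > 1 and (np.diff(t) <= 0).any():
            raise ValueError("event times must be strictly increasing")
        self.event_times_s = t

    @property
    def n_events(self) -> int:
        return self.event_times_s.size


@dataclass
class StatePreference:
    """Per-state preference index S for one cell.

    ``s`` holds S_i per recorded state (NaN for unrecorded states); included
    cells have Σ S_i = 1. Cells with no transients in any state are excluded.
    """

    s: np.ndarray                   # (3,) with NaN for unrecorded states
    preferred_state: int | None     # argmax of transient count; None if excluded
    included: bool
    counts: np.ndarray | None = None


def detrend_normalize(raw: np.ndarray, fs: float | None = None,
                      order: int = 3) -> np.ndarray:
    """Cubic-detrended, mean-normalized ΔF/F.

    Subtracts the least-squares polynomial of the given order and divides by
    the mean of the raw trace, so a transient that doubles fluorescence reads
    as 1.0 (100% ΔF/F).
    """
    y = np.asarray(raw, dtype=float)
    if y.size <= order + 1:
        raise ValueError("trace too short for polynomial detrending")
    mu = y.mean()
    if abs(mu) < 1e-9 * max(np.ptp(y), 1e-30):
        raise ValueError("raw trace has (near-)zero mean; ΔF/F undefined")
    x = np.arange(y.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(x, y, order)
    trend = np.polynomial.polynomial.polyval(x, coef)
    _ = fs
    return (y - trend) / mu


def detect_transients(dff: np.ndarray, fs: float, min_height: float = 1.0,
                      min_prominence: float = 0.8,
                      min_separation_s: float = 1.0,
                      cell_id: str = "c0") -> TransientTrain:
    """Detect calcium transients as constrained local maxima.

    Peaks must exceed ``min_height`` ΔF/F, have prominence of at least
    ``min_prominence`` ΔF/F, and be separated by at least
    ``min_separation_s``; of two close candidates the higher survives
    (scipy's distance pruning keeps the larger peak).
    """
    x = np.asarray(dff, dtype=float)
    distance = max(1, int(round(min_separation_s * fs)))
    idx, _ = sps.find_peaks(x, height=min_height, prominence=min_prominence,
                            distance=distance)
    return TransientTrain(event_times_s=idx / fs, fs=fs, cell_id=cell_id)


def detect_transients_2p(trace: np.ndarray, fs: float,
                         background: np.ndarray | float = 0.0,
                         n_sd: float = 3.0,
                         baseline_min_s: float = 2.0) -> np.ndarray:
    """Two-photon event mask: threshold at mean + ``n_sd``·SD.

    The background (scalar or per-frame) is subtracted, the trace is
    normalized by a baseline F0 estimated from an inactive period — the
    longest stretch of at least ``baseline_min_s`` below the trace's median —
    and contiguous samples above mean + ``n_sd``·SD are marked as events.
    Returns a boolean mask over samples.
    """
    y = np.asarray(trace, dtype=float) - background
    if y.size < int(np.ceil(baseline_min_s * fs)):
        raise ValueError("trace shorter than the minimum baseline window")
    below = y <= np.median(y)
    # longest run of below-median samples
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(int))
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    min_len = int(np.ceil(baseline_min_s * fs))
    spans = [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]
    if spans:
        s0, e0 = max(spans, key=lambda se: se[1] - se[0])
        f0 = y[s0:e0].mean()
    else:
        f0 = y[below].mean() if below.any() else y.mean()
    if f0 == 0:
        f0 = 1.0
    norm = (y - f0) / abs(f0)
    thr = norm.mean() + n_sd * norm.std()
    return norm > thr


def mask_to_periods(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Contiguous True spans of an event mask as (start_s, end_s) pairs."""
    padded = np.concatenate([[False], np.asarray(mask, bool), [False]])
    d = np.diff(padded.astype(int))
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def state_rates(events: TransientTrain, h: Hypnogram,
                window_step_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state transient rates (events/min), counts, and exposure minutes.

    Each hypnogram window contributes ``window_step_s`` seconds of exposure
    to its state; events are assigned to the state of the window containing
    them. States with zero exposure get NaN rates.
    """
    exposure_s = np.array([(h.labels == s).sum() * window_step_s
                           for s in range(N_STATES)])
    counts = np.zeros(N_STATES, dtype=int)
    if events.n_events:
        idx = np.clip((events.event_times_s / window_step_s).astype(np.intp),
                      0, h.n_windows - 1)
        np.add.at(counts, h.labels[idx], 1)
    minutes = exposure_s / 60.0
    rates = np.full(N_STATES, np.nan)
    nz = minutes > 0
    rates[nz] = counts[nz] / minutes[nz]
    return rates, counts, minutes


def state_preference(rates: np.ndarray, counts: np.ndarray | None = None,
                     exposure_min: np.ndarray | None = None) -> StatePreference:
    """State-preference index S_i = F_i / Σ_j F_j over recorded states.

    ``rates`` may contain NaN for unrecorded states (excluded from the sum).
    The preferred state is the state with the most transients (falling back
    to the rate argmax when counts are unavailable); ties break toward the
    state with greater exposure, then toward the fixed order W < N < R.
    Cells with no transients in any recorded state are flagged excluded.
    """
    f = np.asarray(rates, dtype=float)
    recorded = ~np.isnan(f)
    if recorded.sum() < 2:
        raise ValueError("need >= 2 recorded states")
    total = np.nansum(f)
    if total == 0:
        return StatePreference(s=np.full(N_STATES, np.nan),
                               preferred_state=None, included=False,
                               counts=counts)
    s = np.full(N_STATES, np.nan)
    s[recorded] = f[recorded] / total
    key = counts if counts is not None else f
    key = np.where(recorded, key, -np.inf)
    best = np.nanmax(key)
    tied = np.flatnonzero(key == best)
    if tied.size > 1 and exposure_min is not None:
        expo = np.asarray(exposure_min, dtype=float)[tied]
        tied = tied[expo == expo.max()]
    return StatePreference(s=s, preferred_state=int(tied[0]), included=True,
                           counts=counts)


def survivor_curve(s_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Survivor function P(s) = fraction of cells with S >= s.

    Returns (s_grid, p) where ``s_grid`` is the sorted unique values padded
    with 0; the curve is right-continuous. Evaluate elsewhere with
    :func:`survivor_at`.
    """
    v = np.asarray(s_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no included cells")
    grid = np.unique(np.concatenate([[0.0], v]))
    p = np.array([(v >= g).mean() for g in grid])
    return grid, p


def survivor_at(s_values: np.ndarray, threshold: float = 0.5,
                strict: bool = False) -> float:
    """Fraction of cells with S >= threshold (or > if ``strict``)."""
    v = np.asarray(s_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no included cells")
    return float((v > threshold).mean() if strict else (v >= threshold).mean())


# vertices of the unit equilateral triangle for (WAKE, NREM, REM)
_SIMPLEX_VERTICES = np.array([[0.0, 0.0],
                              [1.0, 0.0],
                              [0.5, np.sqrt(3) / 2]])


def simplex_coordinates(s_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric embedding of 3-state preference vectors.

    ``s_matrix`` is (cells, 3) with rows summing to 1; returns the 2-D
    coordinates in an equilateral triangle (vertices = pure W, N, R) and the
    per-state proportions of cells by argmax.
    """
    s = np.asarray(s_matrix, dtype=float)
    if s.ndim != 2 or s.shape[1] != N_STATES:
        raise ValueError("s_matrix must be (cells, 3)")
    if not np.allclose(s.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1")
    xy = s @ _SIMPLEX_VERTICES
    pref = s.argmax(axis=1)
    proportions = np.array([(pref == k).mean() for k in range(N_STATES)])
    return xy, proportions


def preference_table(prefs: list[StatePreference]) -> dict[str, float]:
    """Proportion of included cells preferring each state."""
    included = [p for p in prefs if p.included]
    n = len(included)
    if n == 0:
        return {name: float("nan") for name in STATE_NAMES}
    return {STATE_NAMES[k]: sum(p.preferred_state == k for p in included) / n
            for k in range(N_STATES)}
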