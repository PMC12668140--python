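"""State-dynamics and physiology metrics over hypnograms and derived series.

Covers the quantities reported per-cohort in sleep chemogenetics
experiments: time-in-state fractions per epoch, bout tables and durations
(with percent-of-baseline normalization), bout-level Markov transition
matrices and their baseline-normalized ratios, jackknife confidence
intervals across subjects, sliding-window righting-reflex probabilities with
exact binomial bounds, and windowed temperature deltas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .staging import Hypnogram
from .synthio import N_STATES, STATE_NAMES


@dataclass
class BoutTable:
    """Contiguous same-state runs: (state, start_s, duration_s) per bout."""

    table: pd.DataFrame     # columns: state (int), state_name, start_s, duration_s

    def __post_init__(self) -> None:
        s = self.table["state"].to_numpy()
        if s.size > 1 and (s[1:] == s[:-1]).any():
            raise ValueError("consecutive bouts must alternate in state")

    @property
    def states(self) -> np.ndarray:
        return self.table["state"].to_numpy()

    def durations(self, state: int | None = None) -> np.ndarray:
        if state is None:
            return self.table["duration_s"].to_numpy()
        return self.table.loc[self.table["state"] == state, "duration_s"].to_numpy()


@dataclass
class TransitionMatrix:
    """Bout-level transition counts and row-normalized probabilities.

    The diagonal is structurally zero (a bout cannot be followed by a bout of
    the same state). Rows with no outgoing transitions are flagged undefined
    (NaN probabilities).
    """

    counts: np.ndarray          # (3, 3) int
    probabilities: np.ndarray   # (3, 3) float, NaN rows where undefined
    row_defined: np.ndarray     # (3,) bool


def time_in_state(h: Hypnogram, window_step_s: float,
                  epoch_s: float = 3600.0) -> pd.DataFrame:
    """Fraction of time per state in consecutive epochs.

    Windows are assigned to epochs by their center time; epochs with no
    windows are excluded. Fractions sum to 1 within each epoch.
    """
    t = np.asarray(h.window_centers, dtype=float)
    epoch_idx = (t // epoch_s).astype(int)
    rows = []
    for e in np.unique(epoch_idx):
        sel = epoch_idx == e
        n = sel.sum()
        fracs = [(h.labels[sel] == s).sum() / n for s in range(N_STATES)]
        rows.append({"epoch": int(e), "epoch_start_s": e * epoch_s,
                     **{STATE_NAMES[s]: fracs[s] for s in range(N_STATES)}})
    _ = window_step_s  # grid metadata; fractions are per-window counts
    return pd.DataFrame(rows)


def bout_table(h: Hypnogram, window_step_s: float) -> BoutTable:
    """Run-length encode a hypnogram into contiguous bouts."""
    y = h.labels
    bounds = np.flatnonzero(np.diff(y)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [y.size]])
    df = pd.DataFrame({
        "state": y[starts],
        "state_name": [STATE_NAMES[s] for s in y[starts]],
        "start_s": starts * window_step_s,
        "duration_s": (ends - starts) * window_step_s,
    })
    return BoutTable(table=df)


def summarize_bouts(bouts: BoutTable) -> pd.DataFrame:
    """Mean/median bout duration and bout count per state."""
    rows = []
    for s in range(N_STATES):
        d = bouts.durations(s)
        rows.append({"state": STATE_NAMES[s], "n_bouts": d.size,
                     "mean_s": d.mean() if d.size else np.nan,
                     "median_s": np.median(d) if d.size else np.nan})
    return pd.DataFrame(rows)


def normalize_to_baseline(stat: float, baseline_stat: float) -> float:
    """Express a statistic as percent of its baseline value (100·stat/baseline)."""
    if baseline_stat == 0:
        raise ValueError("baseline statistic is zero")
    return 100.0 * stat / baseline_stat


def transition_matrix(bouts: BoutTable) -> TransitionMatrix:
    """Count ordered bout pairs and row-normalize by outgoing totals."""
    s = bouts.states
    if s.size < 2:
        raise ValueError("need at least one transition (>= 2 bouts)")
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    np.add.at(counts, (s[:-1], s[1:]), 1)
    row_sums = counts.sum(axis=1)
    probs = np.full((N_STATES, N_STATES), np.nan)
    defined = row_sums > 0
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(counts=counts, probabilities=probs,
                            row_defined=defined)


def transition_ratio(post: TransitionMatrix,
                     baseline: TransitionMatrix) -> np.ndarray:
    """Elementwise probability ratio post/baseline; undefined cells are NaN."""
    ratio = np.full((N_STATES, N_STATES), np.nan)
    ok = (post.row_defined[:, None] & baseline.row_defined[:, None]
          & (baseline.probabilities > 0))
    ratio[ok] = post.probabilities[ok] / baseline.probabilities[ok]
    return ratio


def jackknife_ci(values: np.ndarray | None = None, *,
                 statistic=None, subjects: list | None = None,
                 conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Leave-one-subject-out jackknife mean and t-based confidence interval.

    Either pass per-subject ``values`` (the statistic is their mean) or a
    ``statistic`` callable applied to any subset of ``subjects``. Pseudovalue
    form: θ̃_i = n·θ̂ − (n−1)·θ̂_(−i); CI = mean(θ̃) ± t_{1−α/2, n−1}·SE(θ̃).
    For the sample mean this reproduces the classical t-interval exactly.
    """
    if values is not None:
        data = list(np.asarray(values, dtype=float))
        statistic = lambda subset: float(np.mean(subset))  # noqa: E731
    elif statistic is not None and subjects is not None:
        data = list(subjects)
    else:
        raise ValueError("pass values, or statistic with subjects")
    n = len(data)
    if n < 2:
        raise ValueError("jackknife needs >= 2 subjects")
    theta_full = statistic(data)
    pseudo = np.array([
        n * theta_full - (n - 1) * statistic(data[:i] + data[i + 1:])
        for i in range(n)
    ])
    mean = pseudo.mean()
    se = pseudo.std(ddof=1) / np.sqrt(n)
    tcrit = st.t.ppf(0.5 + conf / 2, df=n - 1)
    return float(mean), (float(mean - tcrit * se), float(mean + tcrit * se))


def righting_probability(outcomes: np.ndarray, window: int = 10, step: int = 1,
                         conf: float = 0.95) -> pd.DataFrame:
    """Sliding-window righting probability with exact binomial bounds.

    Fraction of successes in windows of ``window`` trials (step ``step``),
    with Clopper–Pearson ``conf`` confidence limits per window. Trials are
    binary (1 = righted).
    """
    y = np.asarray(outcomes)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcomes must be binary")
    if y.size < window:
        raise ValueError("fewer trials than one window")
    rows = []
    alpha = 1 - conf
    for start in range(0, y.size - window + 1, step):
        k = int(y[start:start + window].sum())
        lo = st.beta.ppf(alpha / 2, k, window - k + 1) if k > 0 else 0.0
        hi = st.beta.ppf(1 - alpha / 2, k + 1, window - k) if k < window else 1.0
        rows.append({"window_start_trial": start, "k": k, "n": window,
                     "p": k / window, "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def temperature_delta(trace: np.ndarray, frame_rate_hz: float,
                      injection_s: float, control_s: float | None = None,
                      window_s: float = 50 * 60.0,
                      center_offset_s: float = 90 * 60.0) -> float:
    """Windowed post-injection temperature change relative to a control period.

    Mean over a ``window_s`` window centered ``center_offset_s`` after
    injection, minus the mean over the matching window around
    ``control_s + center_offset_s`` (default control: 24 h after injection,
    same zeitgeber time). Positive values mean warmer after injection.
    """
    trace = np.asarray(trace, dtype=float)
    if control_s is None:
        control_s = injection_s + 24 * 3600.0
    t = np.arange(trace.size) / frame_rate_hz

    def window_mean(center: float) -> float:
        lo, hi = center - window_s / 2, center + window_s / 2
        sel = (t >= lo) & (t < hi)
        if not sel.any() or lo < t[0] or hi > t[-1] + 1.0 / frame_rate_hz:
            raise ValueError("trace does not cover the requested window")
        return float(trace[sel].mean())

    return (window_mean(injection_s + center_offset_s)
            - window_mean(control_s + center_offset_s))
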