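"""Calcium-transient detection and state preference on synthetic cells.

Synthesizes a cohort of cells with NREM-biased Poisson transient rates over
a Markov hypnogram, detects transients with the height/prominence/separation
rules, computes per-state rates and the preference index S, and summarizes
survivor fractions, simplex proportions, and fold-changes of median rates.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from sleepphys import calcium as ca
from sleepphys import pipeline as pl
from sleepphys import stats as ss
from sleepphys import synthio as syn
from sleepphys.staging import Hypnogram
from sleepphys.synthio import STATE_NAMES

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_CELLS = 40
HOURS = 2.0


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = pl.RunConfig(seed=seed)
    states = syn.simulate_state_sequence(
        np.array(cfg.transition_matrix), np.array(cfg.dwell_windows),
        n_windows=int(HOURS * 3600 / 2.5), seed=seed + 3)
    h = Hypnogram(labels=states.labels,
                  window_centers=(np.arange(states.n_windows) + 0.5) * 2.5)
    rates_gen = dict(enumerate(cfg.calcium_rates_per_min))

    rows, s_rows, prefs = [], [], []
    rates_by_state = {name: [] for name in STATE_NAMES}
    for cell in range(N_CELLS):
        trace, _ = syn.synthesize_calcium(states, rates_gen,
                                          noise_sd=cfg.calcium_noise_sd,
                                          seed=seed + 200 + cell)
        train = ca.detect_transients(trace, fs=cfg.calcium_fs,
                                     cell_id=f"c{cell}")
        rates, counts, minutes = ca.state_rates(train, h, 2.5)
        pref = ca.state_preference(rates, counts, minutes)
        prefs.append(pref)
        if pref.included:
            s_rows.append(pref.s)
        for k, name in enumerate(STATE_NAMES):
            rates_by_state[name].append(rates[k])
        rows.append({"cell": f"c{cell}", "n_events": train.n_events,
                     **{f"rate_{n}": rates[k]
                        for k, n in enumerate(STATE_NAMES)},
                     **{f"S_{n}": pref.s[k] for k, n in enumerate(STATE_NAMES)},
                     "preferred": STATE_NAMES[pref.preferred_state]
                     if pref.included else "excluded"})
    df = pd.DataFrame(rows)
    pl.write_table(RESULTS / "calcium_cells.tsv", df)

    _, proportions = ca.simplex_coordinates(np.array(s_rows))
    p_nrem_half = ca.survivor_at(np.array(s_rows)[:, syn.NREM], 0.5)
    fc = ss.fold_change_of_medians(
        {k: np.array(v) for k, v in rates_by_state.items()})
    summary = {
        "n_cells": N_CELLS,
        "n_included": int(sum(p.included for p in prefs)),
        "preferred_proportions": dict(zip(STATE_NAMES, proportions.tolist())),
        "survivor_P05_nrem": p_nrem_half,
        "median_rate_fold_changes": fc,
    }
    (RESULTS / "calcium_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"{summary['n_included']}/{N_CELLS} cells included; "
          f"preferred proportions: "
          + ", ".join(f"{k} {v:.2f}"
                      for k, v in summary["preferred_proportions"].items()))
    print(f"fraction with S_NREM >= 0.5: {p_nrem_half:.2f}")
    print("median-rate fold changes: "
          + ", ".join(f"{k} {v:.1f}" for k, v in fc.items()))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
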