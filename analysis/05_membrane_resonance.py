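"""ZAP impedance, resonance metrics, and intrinsic properties of simulated
membranes.

Builds a cohort of linear membranes (resonant h-current-like and passive),
runs the chirp protocol, extracts fR / resonance strength / 3 dB cutoff,
applies the fR > 2 Hz ET-like rule, and extracts subthreshold step metrics.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from sleepphys import ephys as ep
from sleepphys import pipeline as pl
from sleepphys import synthio as syn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def step_sweeps(params, dt=0.1):
    amps = np.arange(-150, 51, 20)
    n_pre, n_dur, n_post = int(200 / dt), int(1000 / dt), int(500 / dt)
    stims, volts = [], []
    for a in amps:
        i = np.concatenate([np.zeros(n_pre), np.full(n_dur, float(a)),
                            np.zeros(n_post)])
        stims.append(i)
        volts.append(syn.simulate_membrane(params, i, dt_ms=dt))
    return ep.SweepSet(np.array(stims), np.array(volts), dt, "sub-steps")


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    stim = ep.make_chirp(amplitude_pa=20.0, dt_ms=0.1)
    rows = []
    # 10 resonant (g_1 > 0, tau_w slow) and 8 passive membranes with jitter
    cohort = ([("resonant", syn.MembraneParams(5.0 * g, 150.0 * g, 10.36 * g,
                                               150.0))
               for g in rng.uniform(0.8, 1.2, 10)]
              + [("passive", syn.MembraneParams(5.0 * g, 150.0 * g, 0.0))
                 for g in rng.uniform(0.8, 1.2, 8)])
    for kind, params in cohort:
        v = syn.simulate_membrane(params, stim, dt_ms=0.1)
        prof = ep.impedance_profile(ep.SweepSet(stim, v, 0.1, "chirp"))
        fr, strength, f3 = ep.resonance_metrics(prof)
        sub = ep.subthreshold_step_metrics(step_sweeps(params), (0.2, 1.2))
        rows.append({"kind": kind, "fR_hz": fr, "strength": strength,
                     "f3db_hz": f3, "et_like": ep.classify_et(fr),
                     "sag_ratio": sub["sag_ratio"],
                     "rin_steady_mohm": sub["rin_steady_mohm"]})
    df = pd.DataFrame(rows)
    pl.write_table(RESULTS / "membrane_cohort.tsv", df)
    for kind in ("resonant", "passive"):
        sub = df[df["kind"] == kind]
        print(f"{kind}: n={len(sub)}, ET-like {int(sub.et_like.sum())}/{len(sub)}, "
              f"median fR {sub.fR_hz.median():.2f} Hz, "
              f"median sag {sub.sag_ratio.median():.2f}")
    table = np.array([
        [int(df[df.kind == "resonant"].et_like.sum()),
         int((~df[df.kind == "resonant"].et_like).sum())],
        [int(df[df.kind == "passive"].et_like.sum()),
         int((~df[df.kind == "passive"].et_like).sum())],
    ])
    from sleepphys import stats as ss
    p = ss.fisher_exact(table)
    print(f"ET-like split resonant vs passive: {table.tolist()}, "
          f"Fisher exact p = {p:.2e}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
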