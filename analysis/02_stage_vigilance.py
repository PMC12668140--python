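"""Leave-one-subject-out vigilance staging on the synthetic cohort.

The full pipeline per fold: multitaper spectrogram of decimated EEG ->
rank-6 NMF loadings + EMG RMS + accelerometer RMS -> standardized 8-vector
-> feedforward network -> 15-window persistence filter. Prints per-fold and
overall held-out accuracy and writes the confusion matrix.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

from sleepphys import pipeline as pl
from sleepphys.synthio import STATE_NAMES

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    warnings.filterwarnings("ignore")
    RESULTS.mkdir(exist_ok=True)
    cfg = pl.RunConfig(seed=seed)
    cv = pl.run_staging_study(cfg)
    for sub, acc in zip(cv.subjects, cv.fold_accuracies):
        print(f"  fold {sub}: held-out accuracy {acc:.3f}")
    print(f"overall held-out accuracy: {cv.overall_accuracy:.3f} "
          f"({int(cv.confusion.trace())}/{int(cv.confusion.sum())} windows)")
    conf = pd.DataFrame(cv.confusion, index=STATE_NAMES, columns=STATE_NAMES)
    conf.insert(0, "true_state", STATE_NAMES)
    pl.write_table(RESULTS / "staging_confusion.tsv", conf)
    (RESULTS / "staging_cv.json").write_text(json.dumps({
        "seed": seed,
        "fold_accuracies": cv.fold_accuracies,
        "overall_accuracy": cv.overall_accuracy,
    }, indent=2))
    print(f"report -> {RESULTS}/staging_cv.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
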