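"""Exact statistics on contingency tables rebuilt from published summaries.

Reconstructs the three isoflurane/state-preference contingency tables from
group sizes and percentages, runs the uncorrected Pearson chi-square, the
pairwise two-sided Fisher exact tests with Bonferroni correction, the
binomial subclass-enrichment probability, and the fold-changes of median
transient rates.
"""

import json
import sys
from pathlib import Path

import numpy as np

from sleepphys import stats as ss

RESULTS = Path(__file__).resolve().parents[1] / "results"

# fraction of neurons preferentially active under isoflurane, per population:
# activity-tagged PFC cohort 44/83, S1 0/215, PFC layer-5 16/119
ISO_PREFERENCE = np.array([[44, 39], [0, 215], [16, 103]])
# ET-like physiology in tagged (23/37) vs unlabeled (3/26) neurons
ET_PHYSIOLOGY = np.array([[23, 14], [3, 23]])
# molecular subtypes preferring isoflurane: 22.9% of 170, 21.4% of 192,
# 84.2% of 190
SUBTYPE_PREFERENCE = np.array([[39, 131], [41, 151], [160, 30]])


def main(seed: int = 1) -> None:
    del seed                      # exact statistics, nothing stochastic
    RESULTS.mkdir(exist_ok=True)
    out = {}
    for name, table in (("iso_preference_3x2", ISO_PREFERENCE),
                        ("subtype_preference_3x2", SUBTYPE_PREFERENCE),
                        ("et_physiology_2x2", ET_PHYSIOLOGY)):
        stat, df, p = ss.chi_square(table)
        out[name] = {"chi2": round(stat, 2), "df": df, "p": p}
        print(f"{name}: chi2({df}) = {stat:.2f}, p = {p:.3g}")

    pairs = [(0, 1), (0, 2), (1, 2)]
    raw = [ss.fisher_exact(ISO_PREFERENCE[[i, j]]) for i, j in pairs]
    adj = ss.bonferroni(raw, m=len(pairs))
    out["iso_preference_posthoc"] = {
        f"rows{i}{j}": {"p_raw": pr, "p_bonferroni": pa}
        for (i, j), pr, pa in zip(pairs, raw, adj)}
    print("pairwise Fisher (Bonferroni): "
          + ", ".join(f"rows {i}-{j}: {pa:.2e}"
                      for (i, j), pa in zip(pairs, adj)))

    out["subclass_enrichment_pmf"] = ss.binomial_pmf(11, 16, 0.35)
    print(f"P(X = 11 | n = 16, p = 0.35) = {out['subclass_enrichment_pmf']:.4f}")

    fc = ss.fold_change_of_medians({"NREM": np.array([0.5076]),
                                    "REM": np.array([0.2437]),
                                    "Wake": np.array([0.0677])})
    out["median_rate_fold_changes"] = {k: round(v, 1) for k, v in fc.items()}
    print("median-rate fold changes: "
          + ", ".join(f"{k} {v:.1f}" for k, v in fc.items()))

    (RESULTS / "printed_statistics.json").write_text(json.dumps(out, indent=2))
    print(f"-> {RESULTS}/printed_statistics.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
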