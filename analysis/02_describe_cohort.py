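#!/usr/bin/env python
"""Descriptive statistics, stability correlations and twin correlations.

Reads results/cohort.csv (run 01 first), square-root transforms the scores
and writes per-wave descriptives, the wave-by-wave longitudinal correlation
matrix (one twin per pair) and cross-twin correlations by zygosity.
"""

from pathlib import Path

from twinstab.data import (
    crosstwin_correlations,
    descriptives,
    load_csv,
    longitudinal_correlations,
    sqrt_transform,
)

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = load_csv(OUT / "cohort.csv")
    descriptives(data).to_csv(OUT / "descriptives.csv", index=False)
    tdata = sqrt_transform(data)
    longitudinal_correlations(tdata, one_per_pair=True, seed=1).to_csv(
        OUT / "stability_correlations.csv", index=False
    )
    crosstwin_correlations(tdata).to_csv(
        OUT / "crosstwin_correlations.csv", index=False
    )
    print(f"descriptive tables written to {OUT}")
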