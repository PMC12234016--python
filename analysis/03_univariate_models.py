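#!/usr/bin/env python
"""Univariate twin models at every wave.

Fits ACE, ADE and AE by FIML to each wave of the transformed cohort,
selects by AIC and tabulates the comparison plus the selected model's
standardised variance shares.
"""

from pathlib import Path

import pandas as pd

from twinstab import models, selection
from twinstab.biometric import build_univariate, standardize
from twinstab.data import load_csv, sqrt_transform

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    data = sqrt_transform(load_csv(OUT / "cohort.csv"))
    groups = data.group_arrays()
    W = data.n_waves
    comparison_rows, share_rows = [], []
    for w in range(W):
        wg = [models.drop_empty_rows(g[:, [w, W + w]]) for g in groups]
        fits = [
            models.fit(build_univariate(f, data=wg), wg, n_starts=2,
                       standard_errors=False)
            for f in ("ACE", "ADE", "AE")
        ]
        table = selection.compare(fits)
        table.insert(0, "wave", w + 1)
        comparison_rows.append(table)
        best = selection.best_model(table)
        est = standardize(next(f for f in fits if f.model == best))
        share_rows.append({
            "wave": w + 1, "best": best,
            **{f"{c}_share": float(est.total_shares[c][0])
               for c in est.components},
        })
    pd.concat(comparison_rows).to_csv(OUT / "univariate_comparison.csv",
                                      index=False)
    pd.DataFrame(share_rows).to_csv(OUT / "univariate_shares.csv", index=False)
    print(pd.DataFrame(share_rows).to_string(index=False))
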