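#!/usr/bin/env python
"""Correlated-factor model of the two symptom dimensions.

Simulates bivariate twin data at the generating dimension heritabilities
with genetic correlation 0.90 and non-shared environmental correlation
0.62, fits the AE correlated-factor model by FIML and writes the recovered
shares and component correlations.
"""

import json
from pathlib import Path

from twinstab import models
from twinstab.biometric import build_correlated_factors, standardize
from twinstab.data import sqrt_transform
from twinstab.recovery import correlated_factors_truth
from twinstab.simulate import simulate

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    data, truth = simulate(correlated_factors_truth(seed=7))
    groups = sqrt_transform(data).group_arrays()
    res = models.fit(build_correlated_factors(2, data=groups), groups,
                     n_starts=2, standard_errors=False)
    est = standardize(res)
    payload = est.to_dict()
    payload["truth_shares"] = {c: v.tolist() for c, v in truth.shares.items()}
    (OUT / "correlated_factors.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    print(f"A shares: {est.variance_shares['A'].round(3).tolist()}")
    print(f"rG = {est.correlations['A'][0, 1]:.3f}, "
          f"rE = {est.correlations['E'][0, 1]:.3f}")
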