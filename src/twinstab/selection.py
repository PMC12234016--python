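"""Model fit comparison: AIC ranking and likelihood-ratio tests.

AIC is the selection criterion; exact ties are broken toward the model with
fewer free parameters.  Chi-square LRT p-values are reported for declared
nestings; when the true value of a variance component lies on the boundary
of its parameter space the usual chi-square reference distribution is
conservative, and the p-values are reported as-is (no mixture correction).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import FitResult


def compare(
    fits: Sequence[FitResult],
    nesting: Sequence[tuple[str, str]] | None = None,
    check_data: bool = True,
) -> pd.DataFrame:
    """Comparison table over fitted models.

    ``nesting`` lists ``(restricted, general)`` model-name pairs for which a
    likelihood-ratio test is computed.  All fits must come from the same data
    (verified through the stored data fingerprint unless ``check_data`` is
    off).  The returned frame keeps the input row order; the ``best`` column
    marks the minimum-AIC model.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    if check_data:
        fps = {f.data_fingerprint for f in fits if f.data_fingerprint}
        if len(fps) > 1:
            raise ValueError(
                "fits were computed on different data (mismatched fingerprints)"
            )
    by_name = {f.model: f for f in fits}
    rows = []
    # ties below 1e-9 in AIC resolved toward fewer parameters
    best_name = min(fits, key=lambda f: (round(f.aic, 9), f.k)).model
    best_aic = by_name[best_name].aic
    for f in fits:
        row = {
            "model": f.model,
            "minus2ll": f.minus2ll,
            "df": f.df,
            "k": f.k,
            "aic": f.aic,
            "delta_aic": f.aic - best_aic,
            "best": f.model == best_name,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if nesting:
        table["lrt_vs"] = None
        table["lrt_chi2"] = np.nan
        table["lrt_df"] = np.nan
        table["lrt_p"] = np.nan
        for restricted, general in nesting:
            if restricted not in by_name or general not in by_name:
                raise ValueError(f"nesting refers to unknown model "
                                 f"'{restricted}' or '{general}'")
            r, g = by_name[restricted], by_name[general]
            chi2 = r.minus2ll - g.minus2ll
            ddf = g.k - r.k
            if ddf <= 0:
                raise ValueError(
                    f"'{restricted}' is not nested in '{general}' "
                    f"(no reduction in parameters)"
                )
            p = float(sps.chi2.sf(max(chi2, 0.0), ddf))
            i = table.index[table["model"] == restricted][0]
            table.loc[i, ["lrt_vs", "lrt_chi2", "lrt_df", "lrt_p"]] = (
                general, chi2, ddf, p,
            )
    return table


def best_model(table: pd.DataFrame) -> str:
    return str(table.loc[table["best"], "model"].iloc[0])
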