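"""Twin dataset container, CSV I/O, transforms and descriptive statistics.

The canonical layout is wide, one row per twin pair:

``pair_id, zygosity, [sex, age,] score_w{w}_t{t}, ...``

with ``w`` the wave (1..W) and ``t`` the twin (1 or 2).  Multi-variable data
(e.g. two symptom dimensions) use ``score_v{v}_w{w}_t{t}``; item-level data
use ``item_w{w}_i{i}_t{t}``.  Missing cells are empty / NaN.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ZYGOSITY_CODES = ("MZ", "DZ")


@dataclass
class TwinDataset:
    """Wide per-pair twin data with W waves, V variables and optional items."""

    df: pd.DataFrame
    n_waves: int
    n_vars: int = 1
    n_items: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.df["zygosity"].isna().any():
            raise ValueError("zygosity must be non-missing for every pair")
        bad = ~self.df["zygosity"].isin(ZYGOSITY_CODES)
        if bad.any():
            rows = self.df.index[bad].tolist()[:5]
            codes = self.df.loc[bad, "zygosity"].unique().tolist()
            raise ValueError(f"unknown zygosity codes {codes} in rows {rows}")

    # -- column bookkeeping -------------------------------------------------

    def score_column(self, wave: int, twin: int, var: int = 1) -> str:
        if self.n_vars == 1:
            return f"score_w{wave}_t{twin}"
        return f"score_v{var}_w{wave}_t{twin}"

    def item_column(self, wave: int, item: int, twin: int) -> str:
        return f"item_w{wave}_i{item}_t{twin}"

    def phenotype_columns(self, twin: int) -> list[str]:
        """Score columns of one twin, variable-major then wave order."""
        return [
            self.score_column(w, twin, v)
            for v in range(1, self.n_vars + 1)
            for w in range(1, self.n_waves + 1)
        ]

    def item_columns(self, twin: int, wave: int) -> list[str]:
        return [self.item_column(wave, i, twin) for i in range(1, self.n_items + 1)]

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    # -- conversion ---------------------------------------------------------

    def group_arrays(self) -> list[np.ndarray]:
        """[MZ, DZ] arrays with columns [twin1 phenotypes, twin2 phenotypes],
        the layout expected by the model-fitting layer."""
        cols = self.phenotype_columns(1) + self.phenotype_columns(2)
        out = []
        for z in ZYGOSITY_CODES:
            sub = self.df.loc[self.df["zygosity"] == z, cols]
            out.append(sub.to_numpy(dtype=float))
        return out

    def copy(self) -> "TwinDataset":
        return TwinDataset(self.df.copy(), self.n_waves, self.n_vars,
                           self.n_items, dict(self.meta))

    # -- I/O ------------------------------------------------------------------

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


_SCORE_RE = re.compile(r"^score_(?:v(\d+)_)?w(\d+)_t([12])$")
_ITEM_RE = re.compile(r"^item_w(\d+)_i(\d+)_t([12])$")


def load_csv(path, column_map: dict[str, str] | None = None) -> TwinDataset:
    """Read a canonical wide CSV into a :class:`TwinDataset`.

    Waves, variables and items are inferred from the column names.  Rows in
    which neither twin has any observed phenotype are dropped (with a logged
    count); duplicated pair ids or unknown zygosity codes are rejected with
    the offending rows named.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "pair_id" not in df.columns or "zygosity" not in df.columns:
        raise ValueError("CSV must contain 'pair_id' and 'zygosity' columns")
    dup = df["pair_id"].duplicated(keep=False)
    if dup.any():
        raise ValueError(f"duplicated pair_id in rows {df.index[dup].tolist()}")
    bad = ~df["zygosity"].isin(ZYGOSITY_CODES)
    if bad.any():
        raise ValueError(
            f"unknown zygosity code(s) {df.loc[bad, 'zygosity'].unique().tolist()} "
            f"in rows {df.index[bad].tolist()}"
        )
    waves, variables, items = set(), set(), set()
    score_cols, item_cols = [], []
    for c in df.columns:
        m = _SCORE_RE.match(c)
        if m:
            if m.group(1):
                variables.add(int(m.group(1)))
            waves.add(int(m.group(2)))
            score_cols.append(c)
            continue
        m = _ITEM_RE.match(c)
        if m:
            waves.add(int(m.group(1)))
            items.add(int(m.group(2)))
            item_cols.append(c)
    if not score_cols and not item_cols:
        raise ValueError("no score or item columns found")
    data_cols = score_cols + item_cols
    empty = df[data_cols].isna().all(axis=1)
    if empty.any():
        logger.warning("dropping %d pair(s) with no observed data", int(empty.sum()))
        df = df.loc[~empty].reset_index(drop=True)
    return TwinDataset(
        df=df,
        n_waves=max(waves) if waves else 1,
        n_vars=max(variables) if variables else 1,
        n_items=max(items) if items else 0,
    )


# ---------------------------------------------------------------------------
# transforms


def sqrt_transform(data: TwinDataset) -> TwinDataset:
    """Square-root transform all phenotype scores (for right-skewed scales);
    missing values are preserved, negative scores rejected."""
    out = data.copy()
    cols = out.phenotype_columns(1) + out.phenotype_columns(2)
    vals = out.df[cols].to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("negative scores cannot be square-root transformed")
    out.df[cols] = np.sqrt(vals)
    return out


# ---------------------------------------------------------------------------
# correlations


def _fisher_ci(r: float, n: int, level: float = 0.95):
    if n <= 3 or abs(r) >= 1.0:
        return np.nan, np.nan
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_with_ci(x: np.ndarray, y: np.ndarray):
    """Pearson r on pairwise-complete observations with a Fisher-z 95% CI.

    Returns ``(r, lo, hi, n)``; fewer than 3 complete pairs yields NaNs.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, np.nan, n
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    lo, hi = _fisher_ci(r, n)
    return r, lo, hi, n


def select_one_twin(data: TwinDataset, seed: int = 0) -> pd.DataFrame:
    """One randomly selected co-twin per pair (breaks the non-independence of
    twins for purely phenotypic analyses).  Returns a frame with columns
    named like twin 1's columns."""
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=data.n_pairs)
    cols1 = data.phenotype_columns(1)
    cols2 = data.phenotype_columns(2)
    a1 = data.df[cols1].to_numpy(dtype=float)
    a2 = data.df[cols2].to_numpy(dtype=float)
    chosen = np.where((pick == 1)[:, None], a1, a2)
    out = pd.DataFrame(chosen, columns=cols1)
    out.insert(0, "pair_id", data.df["pair_id"].to_numpy())
    return out


def longitudinal_correlations(
    data: TwinDataset, one_per_pair: bool = True, seed: int = 0, var: int = 1
) -> pd.DataFrame:
    """Pairwise wave-by-wave Pearson correlations with Fisher 95% CIs.

    With ``one_per_pair`` (default), a single randomly selected twin per pair
    enters, so observations are independent; otherwise both twins are used
    as separate rows.
    """
    if data.n_waves < 2:
        raise ValueError("need at least 2 waves for longitudinal correlations")
    if one_per_pair:
        frame = select_one_twin(data, seed=seed)
        series = {
            w: frame[data.score_column(w, 1, var)].to_numpy()
            for w in range(1, data.n_waves + 1)
        }
    else:
        series = {
            w: np.concatenate(
                [
                    data.df[data.score_column(w, 1, var)].to_numpy(dtype=float),
                    data.df[data.score_column(w, 2, var)].to_numpy(dtype=float),
                ]
            )
            for w in range(1, data.n_waves + 1)
        }
    rows = []
    for i in range(1, data.n_waves + 1):
        for j in range(i + 1, data.n_waves + 1):
            r, lo, hi, n = pearson_with_ci(series[i], series[j])
            rows.append(
                {"wave_i": i, "wave_j": j, "r": r, "ci_lower": lo,
                 "ci_upper": hi, "n": n, "defined": n >= 3}
            )
    return pd.DataFrame(rows)


def crosstwin_correlations(data: TwinDataset, var: int = 1) -> pd.DataFrame:
    """Within-pair (twin1 vs twin2) correlations per zygosity and wave,
    computed on double-entered pairs so the result is invariant to twin
    labelling."""
    rows = []
    for z in ZYGOSITY_CODES:
        sub = data.df[data.df["zygosity"] == z]
        for w in range(1, data.n_waves + 1):
            a = sub[data.score_column(w, 1, var)].to_numpy(dtype=float)
            b = sub[data.score_column(w, 2, var)].to_numpy(dtype=float)
            x = np.concatenate([a, b])
            y = np.concatenate([b, a])
            ok = ~(np.isnan(x) | np.isnan(y))
            n_pairs = int(ok.sum()) // 2
            if n_pairs < 3:
                rows.append({"zygosity": z, "wave": w, "r": np.nan,
                             "n_pairs": n_pairs, "defined": False})
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"zygosity": z, "wave": w, "r": r,
                         "n_pairs": n_pairs, "defined": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal consistency


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an (n respondents x k items) matrix on complete
    cases: alpha = k/(k-1) * (1 - sum(var_i) / var_total)."""
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 items")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 complete respondents")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return np.nan
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def cronbach_alpha_per_wave(data: TwinDataset) -> dict[int, float]:
    """Alpha of the item set at each wave, pooling twins as respondents."""
    if data.n_items < 2:
        raise ValueError("dataset has no item-level data")
    out = {}
    for w in range(1, data.n_waves + 1):
        mats = []
        for t in (1, 2):
            cols = data.item_columns(t, w)
            if all(c in data.df.columns for c in cols):
                mats.append(data.df[cols].to_numpy(dtype=float))
        out[w] = cronbach_alpha(np.vstack(mats))
    return out


def descriptives(data: TwinDataset, var: int = 1) -> pd.DataFrame:
    """Per-wave summary: n pairs with data for both twins (split by
    zygosity), mean and SD of the scores pooled over twins."""
    rows = []
    for w in range(1, data.n_waves + 1):
        c1, c2 = data.score_column(w, 1, var), data.score_column(w, 2, var)
        both = data.df[[c1, c2]].notna().all(axis=1)
        pooled = pd.concat([data.df[c1], data.df[c2]]).dropna()
        rows.append(
            {
                "wave": w,
                "n_pairs_complete": int(both.sum()),
                "n_mz": int((both & (data.df["zygosity"] == "MZ")).sum()),
                "n_dz": int((both & (data.df["zygosity"] == "DZ")).sum()),
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "skewness": float(sps.skew(pooled, bias=False)),
            }
        )
    return pd.DataFrame(rows)
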