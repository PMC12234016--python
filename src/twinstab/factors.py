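"""Exploratory and confirmatory factor analysis of item-level data.

EFA uses minimum-residual (minres) extraction with an oblique quartimin
rotation (the oblimin family with gamma = 0) and chooses the factor count by
parallel analysis, corroborated by the residual fit across the candidate
range.  Items are assigned to the factor on which they load above 0.3 and
strictly higher than on any other factor; otherwise they stay unassigned.

CFA models are fitted with the package's FIML core (single group, factor
variances fixed to 1, factor correlations free) and reported with the usual
incremental and absolute fit indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as opt
from statsmodels.multivariate.factor_rotation import rotate_factors

from .models import ModelSpec, fit, fit_saturated

ASSIGN_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# sample splitting


def split_sample(df: pd.DataFrame, fraction: float = 0.7, seed: int = 0):
    """Random, disjoint, exhaustive split into exploration and confirmation
    subsets (default 70/30); reproducible under ``seed``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(df)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_explore = int(round(n * fraction))
    explore = df.iloc[np.sort(perm[:n_explore])]
    confirm = df.iloc[np.sort(perm[n_explore:])]
    return explore, confirm


# ---------------------------------------------------------------------------
# correlation input


def pairwise_corr(items: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix on pairwise-complete observations."""
    arr = np.asarray(items, dtype=float)
    masked = np.ma.masked_invalid(arr)
    corr = np.ma.corrcoef(masked, rowvar=False, allow_masked=True).filled(np.nan)
    return np.asarray(corr)


# ---------------------------------------------------------------------------
# minres extraction


def _minres_loadings(corr: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    reduced = corr - np.diag(psi)
    w, v = np.linalg.eigh(reduced)
    idx = np.argsort(w)[::-1][:m]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def minres(corr: np.ndarray, n_factors: int):
    """Minimum-residual factor extraction.

    Minimises the sum of squared off-diagonal residuals of
    ``corr - L L'`` over the uniquenesses; returns (loadings, uniquenesses,
    objective at the optimum).
    """
    p = corr.shape[0]
    off = ~np.eye(p, dtype=bool)

    def objective(psi):
        lam = _minres_loadings(corr, psi, n_factors)
        resid = corr - lam @ lam.T
        return float((resid[off] ** 2).sum())

    # start: uniqueness = 1 - squared multiple correlation
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    x0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = opt.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(1e-3, 1.0 - 1e-4)] * p,
        options={"maxiter": 500},
    )
    lam = _minres_loadings(corr, res.x, n_factors)
    return lam, res.x, float(res.fun)


def parallel_analysis(
    n_obs: int, n_items: int, n_sim: int = 50, seed: int = 0
) -> np.ndarray:
    """Mean eigenvalues of correlation matrices of uncorrelated normal data
    with the same dimensions; the comparison baseline for factor retention."""
    rng = np.random.default_rng(seed)
    eigs = np.zeros((n_sim, n_items))
    for s in range(n_sim):
        x = rng.standard_normal((n_obs, n_items))
        eigs[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    return eigs.mean(axis=0)


def assign_items(loadings: np.ndarray, threshold: float = ASSIGN_THRESHOLD):
    """Factor assignment: an item belongs to the factor on which its absolute
    loading exceeds ``threshold`` AND is strictly greater than on every other
    factor.  Exact ties or all-below-threshold items are unassigned (-1)."""
    a = np.abs(loadings)
    out = np.full(a.shape[0], -1, dtype=int)
    for i in range(a.shape[0]):
        top = int(np.argmax(a[i]))
        if a[i, top] <= threshold:
            continue
        if np.any(np.delete(a[i], top) >= a[i, top]):
            continue  # tie or non-strict dominance
        out[i] = top
    return out


@dataclass
class EfaResult:
    n_factors: int
    loadings: np.ndarray
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    assignment: np.ndarray           # factor index per item, -1 unassigned
    eigenvalues: np.ndarray
    pa_eigenvalues: np.ndarray
    fit_by_factors: dict[int, float]  # minres objective per candidate count
    rotation_converged: bool = True

    def to_dict(self):
        return {
            "n_factors": int(self.n_factors),
            "loadings": self.loadings.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "assignment": self.assignment.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "pa_eigenvalues": self.pa_eigenvalues.tolist(),
            "fit_by_factors": {str(k): v for k, v in self.fit_by_factors.items()},
            "rotation_converged": self.rotation_converged,
        }


def efa(
    items: np.ndarray,
    n_factors_range=(1, 2, 3),
    n_factors: int | None = None,
    seed: int = 0,
    rotation: str = "quartimin",
) -> EfaResult:
    """Exploratory factor analysis of an (n x p) item matrix.

    The factor count is chosen by parallel analysis (restricted to the
    candidate range) unless given explicitly; the minres objective for every
    candidate count is recorded as corroborating fit information.
    """
    arr = np.asarray(items, dtype=float)
    n_obs = int((~np.isnan(arr).any(axis=1)).sum()) or arr.shape[0]
    corr = pairwise_corr(arr)
    if np.isnan(corr).any():
        raise ValueError("correlation matrix undefined (all-missing item pair)")
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]
    pa = parallel_analysis(n_obs, corr.shape[0], seed=seed)
    suggested = int((eigenvalues > pa).sum())
    fit_by = {}
    for m in n_factors_range:
        _, _, f = minres(corr, m)
        fit_by[m] = f
    if n_factors is None:
        n_factors = int(np.clip(suggested, min(n_factors_range), max(n_factors_range)))
    lam, psi, _ = minres(corr, n_factors)
    phi = np.eye(n_factors)
    converged = True
    if n_factors > 1:
        try:
            lam_rot, T = rotate_factors(lam, rotation)
            phi = T.T @ T
            lam = lam_rot
        except Exception:  # non-convergent rotation: keep unrotated, flag
            converged = False
    # orient factors positively (sign indeterminacy)
    flip = np.sign(lam.sum(axis=0))
    flip[flip == 0] = 1.0
    lam = lam * flip
    phi = phi * np.outer(flip, flip)
    return EfaResult(
        n_factors=n_factors,
        loadings=lam,
        factor_corr=phi,
        uniquenesses=psi,
        assignment=assign_items(lam),
        eigenvalues=eigenvalues,
        pa_eigenvalues=pa,
        fit_by_factors=fit_by,
        rotation_converged=converged,
    )


# ---------------------------------------------------------------------------
# confirmatory factor analysis


@dataclass
class CfaFit:
    loadings: np.ndarray
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    minus2ll: float
    k: int
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_obs: int
    converged: bool
    meta: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "loadings": self.loadings.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "minus2ll": float(self.minus2ll),
            "k": int(self.k),
            "chi2": float(self.chi2),
            "df": int(self.df),
            "cfi": float(self.cfi),
            "tli": float(self.tli),
            "rmsea": float(self.rmsea),
            "srmr": float(self.srmr),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }


def cfa_spec(p: int, pattern: np.ndarray, start_corr: float = 0.4) -> ModelSpec:
    """FIML model spec for a CFA with the given (p x m) boolean loading
    pattern; factor variances fixed to 1, factor correlations free."""
    pattern = np.asarray(pattern, dtype=bool)
    m = pattern.shape[1]
    counts = pattern.sum(axis=0)
    if m > 1 and np.any(counts < 2):
        raise ValueError(
            "empirically underidentified pattern: every factor needs at "
            "least 2 items when factor correlations are free"
        )
    if np.any(pattern.sum(axis=1) != 1):
        raise ValueError("each modelled item must load on exactly one factor")
    load_idx = np.nonzero(pattern)
    n_load = len(load_idx[0])
    n_angles = m * (m - 1) // 2

    names = [f"lambda_{i + 1}" for i in range(n_load)]
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * n_load
    names += [f"phi_{i + 1}" for i in range(n_angles)]
    bounds += [(1e-3, np.pi - 1e-3)] * n_angles
    names += [f"psi_{i + 1}" for i in range(p)]
    bounds += [(1e-3, None)] * p
    names += [f"mean_{i + 1}" for i in range(p)]
    bounds += [(None, None)] * p
    start = np.concatenate([
        np.full(n_load, 0.6),
        np.full(n_angles, np.arccos(start_corr)),
        np.full(p, 0.7),
        np.zeros(p),
    ])

    from .biometric import _corr_from_angles  # shared correlation parameterisation

    def builder(theta):
        off = 0
        lam = np.zeros((p, m))
        lam[load_idx] = theta[off : off + n_load]
        off += n_load
        phi = _corr_from_angles(m, theta[off : off + n_angles])
        off += n_angles
        psi = theta[off : off + p]
        off += p
        mu = theta[off : off + p]
        sigma = lam @ phi @ lam.T + np.diag(psi**2)
        return [(mu, sigma)]

    return ModelSpec(
        name=f"cfa_{m}factor", param_names=names, builder=builder,
        start=start, bounds=bounds,
        meta={"structure": "cfa", "pattern": pattern, "p": p, "m": m},
    )


def _independence_minus2ll(items: np.ndarray) -> tuple[float, int]:
    p = items.shape[1]
    names = [f"s_{i}" for i in range(p)] + [f"mean_{i}" for i in range(p)]
    start = np.concatenate([np.nanstd(items, axis=0), np.nanmean(items, axis=0)])
    bounds = [(1e-4, None)] * p + [(None, None)] * p

    def builder(theta):
        return [(theta[p:], np.diag(theta[:p] ** 2))]

    spec = ModelSpec("independence", names, builder, start, bounds)
    res = fit(spec, [items], n_starts=1, standard_errors=False)
    return res.minus2ll, res.k


def cfa(items: np.ndarray, pattern: np.ndarray, n_starts: int = 2,
        seed: int = 0) -> CfaFit:
    """Fit a confirmatory factor model by FIML and compute fit indices
    against the saturated and independence baselines."""
    items = np.asarray(items, dtype=float)
    keep = ~np.isnan(items).all(axis=1)
    items = items[keep]
    n, p = items.shape
    spec = cfa_spec(p, pattern)
    res = fit(spec, [items], n_starts=n_starts, seed=seed, standard_errors=False)
    sat = fit_saturated([items], standard_errors=False)
    chi2 = max(res.minus2ll - sat.minus2ll, 0.0)
    df = (p * (p + 3)) // 2 - res.k
    b2ll, bk = _independence_minus2ll(items)
    chi2_b = max(b2ll - sat.minus2ll, 0.0)
    df_b = (p * (p + 3)) // 2 - bk
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * n)) if df > 0 else 0.0

    # unpack estimates
    m = pattern.shape[1]
    load_idx = np.nonzero(np.asarray(pattern, bool))
    n_load = len(load_idx[0])
    n_angles = m * (m - 1) // 2
    from .biometric import _corr_from_angles

    lam = np.zeros((p, m))
    lam[load_idx] = res.theta[:n_load]
    phi = _corr_from_angles(m, res.theta[n_load : n_load + n_angles])
    psi = res.theta[n_load + n_angles : n_load + n_angles + p] ** 2

    # SRMR on correlation scale
    implied = lam @ phi @ lam.T + np.diag(psi)
    d = np.sqrt(np.diag(implied))
    implied_corr = implied / np.outer(d, d)
    obs_corr = pairwise_corr(items)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.nanmean((obs_corr[iu] - implied_corr[iu]) ** 2)))

    return CfaFit(
        loadings=lam, factor_corr=phi, uniquenesses=psi,
        minus2ll=res.minus2ll, k=res.k, chi2=chi2, df=df,
        cfi=float(min(cfi, 1.0)), tli=float(tli), rmsea=float(rmsea),
        srmr=srmr, n_obs=n, converged=res.converged,
        meta={"aic": res.aic, "saturated_minus2ll": sat.minus2ll},
    )
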