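"""Structured-covariance maximum-likelihood fitting.

A :class:`ModelSpec` maps a free parameter vector to per-group mean vectors
and covariance matrices; :func:`fit` minimises the FIML -2 log likelihood over
all groups jointly with a quasi-Newton optimiser, multiple jittered starts,
and gradients assembled from the analytic mean/covariance gradient of the
likelihood contracted with a finite-difference Jacobian of the (cheap)
builder.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize as opt

from .fiml import PatternStats, _check_pd, neg2_loglik, neg2_loglik_grad

_PENALTY = 1e12


@dataclass
class ModelSpec:
    """A parametric model for one or more multivariate-normal groups.

    ``builder(theta)`` returns ``[(mu_g, sigma_g), ...]``, one pair per group.
    Covariance builders must return symmetric matrices; positive definiteness
    may fail transiently during optimisation and is handled by penalty.
    """

    name: str
    param_names: list[str]
    builder: Callable[[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]
    start: np.ndarray
    bounds: list[tuple[float | None, float | None]] | None = None
    # optional map theta -> {quantity name: value} for delta-method CIs on
    # derived (standardised) quantities
    summarize: Callable[[np.ndarray], dict[str, float]] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.start)


@dataclass
class FitResult:
    model: str
    theta: np.ndarray
    param_names: list[str]
    minus2ll: float
    k: int
    n_rows: int
    n_values: int
    converged: bool
    se: np.ndarray | None = None
    cov: np.ndarray | None = None
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    start_diagnostics: list[dict] = field(default_factory=list)
    data_fingerprint: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def df(self) -> int:
        """Observed data values minus free parameters (OpenMx convention)."""
        return self.n_values - self.k

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.k

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "theta": [float(t) for t in self.theta],
            "param_names": list(self.param_names),
            "minus2ll": float(self.minus2ll),
            "k": int(self.k),
            "df": int(self.df),
            "aic": float(self.aic),
            "n_rows": int(self.n_rows),
            "n_values": int(self.n_values),
            "converged": bool(self.converged),
            "se": None if self.se is None else [float(s) for s in self.se],
            "summaries": self.summaries,
        }


def drop_empty_rows(arr: np.ndarray) -> np.ndarray:
    """Remove rows with no observed value (they carry no FIML information)."""
    arr = np.asarray(arr, dtype=float)
    return arr[~np.isnan(arr).all(axis=1)]


def data_fingerprint(groups: Sequence[np.ndarray]) -> str:
    """Stable hash of the group data (values and missingness pattern)."""
    h = hashlib.sha256()
    for g in groups:
        g = np.asarray(g, dtype=float)
        h.update(np.ascontiguousarray(np.nan_to_num(g, nan=-1.2345e30)).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def _objective(spec: ModelSpec, stats: list[PatternStats]):
    k = spec.k

    def fun_and_grad(theta):
        models = spec.builder(theta)
        f = 0.0
        grads = []  # (dmu, dsig) per group, or None when penalised
        for (mu, sigma), st in zip(models, stats):
            if not _check_pd(sigma):
                lam_min = float(np.linalg.eigvalsh(sigma).min())
                return _PENALTY * (1.0 + abs(lam_min)), np.zeros(k)
            fg, dmu, dsig = neg2_loglik_grad(mu, sigma, st)
            f += fg
            grads.append((dmu, dsig))
        # contract with builder Jacobian (central differences; builders are
        # cheap closed-form matrix constructions)
        grad = np.zeros(k)
        h = 1e-6
        for j in range(k):
            tp = theta.copy()
            tp[j] += h
            tm = theta.copy()
            tm[j] -= h
            mp = spec.builder(tp)
            mm = spec.builder(tm)
            gj = 0.0
            for (mu_p, sig_p), (mu_m, sig_m), (dmu, dsig) in zip(mp, mm, grads):
                dmu_j = (mu_p - mu_m) / (2 * h)
                dsig_j = (sig_p - sig_m) / (2 * h)
                gj += float(np.sum(dsig * dsig_j) + dmu @ dmu_j)
            grad[j] = gj
        return f, grad

    return fun_and_grad


def _jittered_starts(spec, n_starts, seed, jitter):
    rng = np.random.default_rng(seed)
    starts = [np.asarray(spec.start, dtype=float)]
    scale = np.maximum(np.abs(spec.start), 0.1)
    for _ in range(n_starts - 1):
        cand = spec.start + rng.uniform(-jitter, jitter, spec.k) * scale
        if spec.bounds is not None:
            lo = np.array([-np.inf if b[0] is None else b[0] for b in spec.bounds])
            hi = np.array([np.inf if b[1] is None else b[1] for b in spec.bounds])
            cand = np.clip(cand, lo + 1e-8, hi - 1e-8)
        starts.append(cand)
    return starts


def fit(
    spec: ModelSpec,
    groups: Sequence[np.ndarray],
    n_starts: int = 5,
    seed: int = 0,
    standard_errors: bool = True,
    jitter: float = 0.2,
    maxiter: int = 1000,
) -> FitResult:
    """Fit ``spec`` to one data matrix per group by FIML.

    The best of ``n_starts`` quasi-Newton runs (first start = ``spec.start``,
    the rest jittered) is returned; -2LL ties below 1e-6 are broken in favour
    of the earliest start.
    """
    stats = [PatternStats.from_data(np.asarray(g, dtype=float)) for g in groups]
    fun = _objective(spec, stats)
    best = None
    diagnostics = []
    for i, x0 in enumerate(_jittered_starts(spec, n_starts, seed, jitter)):
        res = opt.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=spec.bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        diagnostics.append(
            {"start": i, "fun": float(res.fun), "success": bool(res.success),
             "nit": int(res.nit), "message": str(res.message)}
        )
        if res.fun < _PENALTY / 10 and (best is None or res.fun < best.fun - 1e-6):
            best = res
    if best is None:
        raise RuntimeError(
            f"no start converged for model '{spec.name}': {diagnostics}"
        )

    theta = best.x
    result = FitResult(
        model=spec.name,
        theta=theta,
        param_names=list(spec.param_names),
        minus2ll=float(best.fun),
        k=spec.k,
        n_rows=sum(st.n_rows for st in stats),
        n_values=sum(st.n_values for st in stats),
        converged=any(d["success"] for d in diagnostics),
        start_diagnostics=diagnostics,
        data_fingerprint=data_fingerprint(groups),
        meta=dict(spec.meta),
    )
    if standard_errors:
        cov = _theta_covariance(fun, theta)
        result.cov = cov
        if cov is not None:
            result.se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if spec.summarize is not None:
        result.summaries = _delta_summaries(spec, theta, result.cov)
    return result


def _theta_covariance(fun_and_grad, theta, h: float = 1e-5):
    """Covariance of theta-hat from a finite-difference Hessian of -2LL."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = fun_and_grad(tp)
        _, gm = fun_and_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        # -2LL Hessian = 2 * observed information
        return 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def _delta_summaries(spec, theta, cov, h: float = 1e-6):
    base = spec.summarize(theta)
    names = list(base)
    out = {n: {"estimate": float(base[n])} for n in names}
    if cov is None:
        return out
    k = len(theta)
    J = np.zeros((len(names), k))
    for j in range(k):
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        sp = spec.summarize(tp)
        sm = spec.summarize(tm)
        for i, n in enumerate(names):
            J[i, j] = (sp[n] - sm[n]) / (2 * h)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.clip(var, 0.0, None))
    for i, n in enumerate(names):
        est = out[n]["estimate"]
        out[n]["se"] = float(se[i])
        out[n]["ci_lower"] = float(est - 1.959963984540054 * se[i])
        out[n]["ci_upper"] = float(est + 1.959963984540054 * se[i])
    return out


# ---------------------------------------------------------------------------
# saturated models


def _tril_indices(p):
    return np.tril_indices(p)


def _chol_param_count(p):
    return p * (p + 1) // 2


def _sigma_from_chol_params(params, p):
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = params
    return L @ L.T


def _moment_start(stats_data: np.ndarray):
    """NaN-aware mean and covariance start values (pairwise complete)."""
    df_mean = np.nanmean(stats_data, axis=0)
    masked = np.ma.masked_invalid(stats_data)
    cov = np.ma.cov(masked, rowvar=False, allow_masked=True).filled(0.0)
    cov = np.atleast_2d(cov)
    # project to PD
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    w = np.clip(w, 1e-4, None)
    return df_mean, (v * w) @ v.T


def saturated_spec(groups: Sequence[np.ndarray]) -> ModelSpec:
    """Unstructured means and covariances, one set per group."""
    p = np.asarray(groups[0]).shape[1]
    nm = _chol_param_count(p)
    starts = []
    names = []
    bounds: list[tuple[float | None, float | None]] = []
    for g, data in enumerate(groups):
        mu0, cov0 = _moment_start(np.asarray(data, dtype=float))
        L0 = np.linalg.cholesky(cov0)
        starts.append(mu0)
        starts.append(L0[np.tril_indices(p)])
        names += [f"mu{g}_{i}" for i in range(p)]
        names += [f"L{g}_{i}" for i in range(nm)]
        bounds += [(None, None)] * p
        diag_pos = set(np.ravel_multi_index(np.diag_indices(p), (p, p)))
        tril_flat = np.ravel_multi_index(np.tril_indices(p), (p, p))
        bounds += [
            (1e-6, None) if f in diag_pos else (None, None) for f in tril_flat
        ]
    start = np.concatenate(starts)
    n_groups = len(groups)

    def builder(theta):
        out = []
        off = 0
        for g in range(n_groups):
            mu = theta[off : off + p]
            off += p
            sig = _sigma_from_chol_params(theta[off : off + nm], p)
            off += nm
            out.append((mu, sig))
        return out

    return ModelSpec(
        name="saturated", param_names=names, builder=builder, start=start,
        bounds=bounds, meta={"family": "saturated"},
    )


def constrained_saturated_spec(groups: Sequence[np.ndarray]) -> ModelSpec:
    """Saturated twin model with equal means and variances across twins and
    zygosity groups and symmetric cross-twin blocks (per group).

    Data columns must be ordered [twin1 waves..., twin2 waves...].
    """
    p = np.asarray(groups[0]).shape[1]
    if p % 2:
        raise ValueError("twin data must have an even number of columns")
    w = p // 2
    nw = _chol_param_count(w)
    n_groups = len(groups)

    mu0s, cov0s = zip(*(_moment_start(np.asarray(g, dtype=float)) for g in groups))
    mu0 = np.mean([0.5 * (m[:w] + m[w:]) for m in mu0s], axis=0)
    within0 = np.mean(
        [0.25 * (c[:w, :w] + c[w:, w:] + c[:w, :w].T + c[w:, w:].T) for c in cov0s],
        axis=0,
    )
    ww, vv = np.linalg.eigh(within0)
    within0 = (vv * np.clip(ww, 1e-4, None)) @ vv.T
    L0 = np.linalg.cholesky(within0)

    starts = [mu0, L0[np.tril_indices(w)]]
    names = [f"mu_{i}" for i in range(w)] + [f"Lw_{i}" for i in range(nw)]
    diag_pos = set(np.ravel_multi_index(np.diag_indices(w), (w, w)))
    tril_flat = np.ravel_multi_index(np.tril_indices(w), (w, w))
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * w + [
        (1e-6, None) if f in diag_pos else (None, None) for f in tril_flat
    ]
    iu = np.triu_indices(w)
    ncross = len(iu[0])
    for g, c in enumerate(cov0s):
        cross = 0.5 * (c[:w, w:] + c[:w, w:].T) * 0.9
        starts.append(cross[iu])
        names += [f"B{g}_{i}" for i in range(ncross)]
        bounds += [(None, None)] * ncross
    start = np.concatenate(starts)

    def builder(theta):
        mu_w = theta[:w]
        L = np.zeros((w, w))
        L[np.tril_indices(w)] = theta[w : w + nw]
        V = L @ L.T
        mu = np.concatenate([mu_w, mu_w])
        out = []
        off = w + nw
        for g in range(n_groups):
            B = np.zeros((w, w))
            B[iu] = theta[off : off + ncross]
            B = B + B.T - np.diag(np.diag(B))
            off += ncross
            sig = np.block([[V, B], [B, V]])
            out.append((mu, sig))
        return out

    return ModelSpec(
        name="saturated_constrained", param_names=names, builder=builder,
        start=start, bounds=bounds, meta={"family": "saturated"},
    )


def fit_saturated(
    groups: Sequence[np.ndarray],
    constrained: bool = False,
    n_starts: int = 1,
    seed: int = 0,
    standard_errors: bool = False,
    **kw,
) -> FitResult:
    """Fit the (optionally constrained) saturated model; comparison baseline.

    With complete data and no constraints the ML solution is the closed-form
    sample moments; the optimiser reaches it quickly from the moment start,
    so a single start is the default here.
    """
    spec = constrained_saturated_spec(groups) if constrained else saturated_spec(groups)
    return fit(spec, groups, n_starts=n_starts, seed=seed,
               standard_errors=standard_errors, **kw)
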