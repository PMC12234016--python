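"""Biometric twin-model covariance builders and post-fit decompositions.

The classical twin design contrasts monozygotic (MZ) pairs, who share all
segregating genes, with dizygotic (DZ) pairs, who share half on average.
Phenotypic covariance is decomposed into additive genetic (A), dominance
genetic (D), shared environmental (C) and non-shared environmental (E)
components; the cross-twin weight of each component is its kinship
coefficient: A 1/0.5, D 1/0.25, C 1/1, E 0/0 for MZ/DZ.

All model families are parameterised in *paths*: free parameters enter the
covariance through squares or cross-products (Cholesky factors, loadings),
so every component covariance matrix is positive semi-definite by
construction and shares are reported as squared paths over total variance.

Data convention throughout: per-pair rows with columns ordered
[twin1 var1..varP, twin2 var1..varP]; groups ordered [MZ, DZ].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import FitResult, ModelSpec

KINSHIP = {"A": (1.0, 0.5), "C": (1.0, 1.0), "D": (1.0, 0.25), "E": (0.0, 0.0)}

FAMILIES = {
    "ACE": ("A", "C", "E"),
    "ADE": ("A", "D", "E"),
    "AE": ("A", "E"),
    "CE": ("C", "E"),
    "E": ("E",),
}

_E_FLOOR = 1e-4  # keeps the non-shared component, hence Sigma, positive definite


def _validate_components(components) -> tuple[str, ...]:
    components = tuple(components)
    for c in components:
        if c not in KINSHIP:
            raise ValueError(f"unknown component '{c}'")
    if "E" not in components:
        raise ValueError("the non-shared environmental component E is required")
    if "C" in components and "D" in components:
        raise ValueError(
            "C and D cannot be estimated simultaneously in a design of twins "
            "reared together (confounded cross-twin weights)"
        )
    return components


def compose_twin_cov(
    component_cov: dict[str, np.ndarray], means: np.ndarray | None = None
):
    """Assemble MZ and DZ per-pair covariance matrices from component
    covariance matrices over the P phenotypes of one twin.

    Within-twin block: sum of all components.  Cross-twin block: kinship-
    weighted sum.  Returns ``(sigma_mz, sigma_dz, mu)`` where ``mu`` repeats
    the per-variable means for both twins (constrained means).
    """
    comps = _validate_components(component_cov.keys())
    p = np.asarray(component_cov[comps[0]]).shape[0]
    within = np.zeros((p, p))
    cross_mz = np.zeros((p, p))
    cross_dz = np.zeros((p, p))
    for c in comps:
        m = np.asarray(component_cov[c], dtype=float)
        if m.shape != (p, p):
            raise ValueError(f"component '{c}' has shape {m.shape}, expected {(p, p)}")
        within += m
        k_mz, k_dz = KINSHIP[c]
        cross_mz += k_mz * m
        cross_dz += k_dz * m
    sigma_mz = np.block([[within, cross_mz], [cross_mz, within]])
    sigma_dz = np.block([[within, cross_dz], [cross_dz, within]])
    if means is None:
        means = np.zeros(p)
    mu = np.concatenate([np.asarray(means, float), np.asarray(means, float)])
    return sigma_mz, sigma_dz, mu


def univariate_expected_cov(family: str, means: float = 0.0, **shares):
    """Expected 2x2 MZ/DZ covariances of a univariate model from variance
    shares, e.g. ``univariate_expected_cov("AE", a2=0.39, e2=0.61)``.
    """
    comps = FAMILIES[family]
    key = {"A": "a2", "C": "c2", "D": "d2", "E": "e2"}
    mats = {c: np.array([[float(shares.get(key[c], 0.0))]]) for c in comps}
    return compose_twin_cov(mats, np.array([float(means)]))


# ---------------------------------------------------------------------------
# moment (method-of-moments) starting values


def twin_moment_blocks(groups, w: int):
    """Pooled within-twin covariance, per-group cross-twin covariance and
    wave means from the raw group arrays (pairwise-complete, NaN-aware)."""
    crosses = []
    withins = []
    means = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        masked = np.ma.masked_invalid(g)
        c = np.ma.cov(masked, rowvar=False, allow_masked=True).filled(0.0)
        c = np.atleast_2d(c)
        withins.append(0.5 * (c[:w, :w] + c[w:, w:]))
        crosses.append(0.5 * (c[:w, w:] + c[:w, w:].T))
        m = np.nanmean(g, axis=0)
        means.append(0.5 * (m[:w] + m[w:]))
    pooled_within = np.mean(withins, axis=0)
    pooled_means = np.mean(means, axis=0)
    return pooled_within, crosses, pooled_means


def _psd_project(m, floor=1e-3):
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    return (v * np.clip(w, floor, None)) @ v.T


def moment_component_estimates(groups, w: int, components) -> dict[str, np.ndarray]:
    """Falconer-style component matrices from observed twin covariances,
    projected to positive definite; used for starting values only."""
    P, (c_mz, c_dz), _ = twin_moment_blocks(groups, w)
    comps = _validate_components(components)
    est: dict[str, np.ndarray] = {}
    if comps == ("A", "C", "E"):
        est["A"] = 2.0 * (c_mz - c_dz)
        est["C"] = 2.0 * c_dz - c_mz
    elif comps == ("A", "D", "E"):
        est["A"] = 4.0 * c_dz - c_mz
        est["D"] = 2.0 * c_mz - 4.0 * c_dz
    elif comps == ("A", "E"):
        est["A"] = c_mz
    elif comps == ("C", "E"):
        est["C"] = 0.5 * (c_mz + c_dz)
    shared = sum(est.values()) if est else np.zeros((w, w))
    est["E"] = P - shared
    return {c: _psd_project(m) for c, m in est.items()}


# ---------------------------------------------------------------------------
# Cholesky decomposition (and univariate as its W=1 case)


def _tril_count(w):
    return w * (w + 1) // 2


def build_cholesky(
    W: int,
    components=("A", "E"),
    data=None,
    name: str | None = None,
) -> ModelSpec:
    """Multivariate Cholesky decomposition over W repeated measures.

    Each component's covariance is X X' with X lower triangular; factor k's
    loadings on waves k..W quantify continuity of influences arising at wave
    k, the diagonal quantifies innovation.  ``data`` (optional ``[mz, dz]``
    arrays) provides method-of-moments starting values.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    comps = _validate_components(components)
    nt = _tril_count(W)
    tril = np.tril_indices(W)
    diag_flat = {i for i, (r, c) in enumerate(zip(*tril)) if r == c}

    names = []
    bounds: list[tuple[float | None, float | None]] = []
    for c in comps:
        names += [f"x{c}_{r + 1}{col + 1}" for r, col in zip(*tril)]
        lo = _E_FLOOR if c == "E" else 0.0
        bounds += [(lo, None) if i in diag_flat else (None, None) for i in range(nt)]
    names += [f"mean_w{i + 1}" for i in range(W)]
    bounds += [(None, None)] * W

    if data is not None:
        est = moment_component_estimates(data, W, comps)
        _, _, mu0 = twin_moment_blocks(data, W)
        start_parts = []
        for c in comps:
            L = np.linalg.cholesky(_psd_project(est[c], 1e-3))
            start_parts.append(L[tril])
        start_parts.append(mu0)
        start = np.concatenate(start_parts)
    else:
        chunks = []
        for c in comps:
            X0 = 0.55 * np.eye(W) + 0.1 * np.tri(W, k=-1)
            chunks.append(X0[tril])
        chunks.append(np.zeros(W))
        start = np.concatenate(chunks)

    def unpack(theta):
        mats = {}
        off = 0
        for c in comps:
            X = np.zeros((W, W))
            X[tril] = theta[off : off + nt]
            mats[c] = X
            off += nt
        return mats, theta[off : off + W]

    def builder(theta):
        paths, means = unpack(theta)
        cov = {c: X @ X.T for c, X in paths.items()}
        s_mz, s_dz, mu = compose_twin_cov(cov, means)
        return [(mu, s_mz), (mu, s_dz)]

    def summarize(theta):
        paths, _ = unpack(theta)
        total = sum(X @ X.T for X in paths.values())
        tv = np.diag(total)
        out = {}
        for c, X in paths.items():
            sq = X**2
            for wv in range(W):
                for k in range(wv + 1):
                    out[f"{c}{k + 1}_share_w{wv + 1}"] = sq[wv, k] / tv[wv]
                out[f"{c}_total_w{wv + 1}"] = sq[wv, : wv + 1].sum() / tv[wv]
        return out

    family = "".join(c for c in comps)
    return ModelSpec(
        name=name or (f"cholesky_{family}" if W > 1 else f"univariate_{family}"),
        param_names=names,
        builder=builder,
        start=start,
        bounds=bounds,
        summarize=summarize,
        meta={"structure": "cholesky", "W": W, "components": comps,
              "family": family, "tril_count": nt},
    )


def build_univariate(family: str, data=None) -> ModelSpec:
    """Univariate ACE/ADE/AE/CE/E model (W=1 Cholesky)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family '{family}'")
    return build_cholesky(1, FAMILIES[family], data=data, name=f"univariate_{family}")


# ---------------------------------------------------------------------------
# common pathway model


def _spherical_paths(angles):
    """Unit-norm path vector from spherical angles (all entries >= 0 when
    angles lie in [0, pi/2])."""
    paths = []
    rem = 1.0
    for a in angles:
        paths.append(rem * np.cos(a))
        rem = rem * np.sin(a)
    paths.append(rem)
    return np.array(paths)


def build_common_pathway(
    W: int, components=("A", "E"), data=None, name: str | None = None
) -> ModelSpec:
    """Common pathway model: a single latent stability factor, with unit
    variance split between the components (e.g. a_c^2 + e_c^2 = 1), loads on
    every wave; wave-specific residuals carry their own component split.

    y_w = lambda_w * L + s_w, var(L) = 1, specifics independent across waves.
    """
    if W < 3:
        raise ValueError(
            "common pathway model needs at least 3 repeated measures for "
            "identification"
        )
    comps = _validate_components(components)
    m = len(comps)
    n_angles = m - 1

    names = [f"lambda_w{i + 1}" for i in range(W)]
    bounds: list[tuple[float | None, float | None]] = [(0.0, None)] * W
    names += [f"phi_latent_{i + 1}" for i in range(n_angles)]
    bounds += [(0.0, np.pi / 2)] * n_angles
    for c in comps:
        names += [f"s{c}_w{i + 1}" for i in range(W)]
        lo = _E_FLOOR if c == "E" else 0.0
        bounds += [(lo, None)] * W
    names += [f"mean_w{i + 1}" for i in range(W)]
    bounds += [(None, None)] * W

    if data is not None:
        P, _, mu0 = twin_moment_blocks(data, W)
        w_eig, v_eig = np.linalg.eigh(P)
        lam0 = np.abs(v_eig[:, -1]) * np.sqrt(max(w_eig[-1], 1e-3))
        lam0 = np.clip(lam0, 0.1, None)
        resid = np.clip(np.diag(P) - lam0**2, 0.05, None)
        sA0 = np.sqrt(resid * 0.3)
        sE0 = np.sqrt(resid * 0.7)
        spec_start = {"A": sA0, "C": np.sqrt(resid * 0.2), "D": np.sqrt(resid * 0.2),
                      "E": sE0}
        start = np.concatenate(
            [lam0, np.full(n_angles, 0.9)]
            + [spec_start.get(c, sE0) for c in comps]
            + [mu0]
        )
    else:
        start = np.concatenate(
            [np.full(W, 0.7), np.full(n_angles, 0.9)]
            + [np.full(W, 0.5) for _ in comps]
            + [np.zeros(W)]
        )

    def unpack(theta):
        off = 0
        lam = theta[off : off + W]
        off += W
        latent_paths = _spherical_paths(theta[off : off + n_angles])
        off += n_angles
        specifics = {}
        for c in comps:
            specifics[c] = theta[off : off + W]
            off += W
        means = theta[off : off + W]
        return lam, dict(zip(comps, latent_paths)), specifics, means

    def builder(theta):
        lam, latent, specifics, means = unpack(theta)
        common = np.outer(lam, lam)
        cov = {
            c: latent[c] ** 2 * common + np.diag(specifics[c] ** 2) for c in comps
        }
        s_mz, s_dz, mu = compose_twin_cov(cov, means)
        return [(mu, s_mz), (mu, s_dz)]

    def summarize(theta):
        lam, latent, specifics, _ = unpack(theta)
        total = lam**2 + sum(specifics[c] ** 2 for c in comps)
        out = {}
        for c in comps:
            out[f"latent_{c}_share"] = latent[c] ** 2
        for wv in range(W):
            out[f"communality_w{wv + 1}"] = lam[wv] ** 2 / total[wv]
            for c in comps:
                out[f"specific_{c}_share_w{wv + 1}"] = (
                    specifics[c][wv] ** 2 / total[wv]
                )
                out[f"{c}_total_w{wv + 1}"] = (
                    latent[c] ** 2 * lam[wv] ** 2 + specifics[c][wv] ** 2
                ) / total[wv]
        return out

    family = "".join(comps)
    return ModelSpec(
        name=name or f"common_pathway_{family}",
        param_names=names,
        builder=builder,
        start=start,
        bounds=bounds,
        summarize=summarize,
        meta={"structure": "common_pathway", "W": W, "components": comps,
              "family": family},
    )


# ---------------------------------------------------------------------------
# correlated-factor model


def _corr_from_angles(V, angles):
    """Correlation matrix from a lower-triangular factor with unit-norm rows
    (hyperspherical row parameterisation); PD whenever every angle lies
    strictly inside (0, pi)."""
    T = np.zeros((V, V))
    T[0, 0] = 1.0
    pos = 0
    for i in range(1, V):
        row_angles = angles[pos : pos + i]
        pos += i
        rem = 1.0
        for j, a in enumerate(row_angles):
            T[i, j] = rem * np.cos(a)
            rem = rem * np.sin(a)
        T[i, i] = rem
    return T @ T.T


def build_correlated_factors(
    V: int, components=("A", "E"), data=None, name: str | None = None
) -> ModelSpec:
    """Correlated-factor model for V phenotypes: each variable has its own
    component variances, and component correlation matrices (genetic rG,
    environmental rE, ...) capture etiological overlap between variables.

    Component covariance: S R S with S = diag(paths) and R a correlation
    matrix parameterised through a triangular factor with unit-norm rows.
    """
    if V < 2:
        raise ValueError("correlated-factor model needs at least 2 variables")
    comps = _validate_components(components)
    n_angles = V * (V - 1) // 2

    names = []
    bounds: list[tuple[float | None, float | None]] = []
    for c in comps:
        names += [f"s{c}_{v + 1}" for v in range(V)]
        lo = _E_FLOOR if c == "E" else 0.0
        bounds += [(lo, None)] * V
        names += [f"phi{c}_{i + 1}" for i in range(n_angles)]
        bounds += [(1e-3, np.pi - 1e-3)] * n_angles
    names += [f"mean_{v + 1}" for v in range(V)]
    bounds += [(None, None)] * V

    if data is not None:
        est = moment_component_estimates(data, V, comps)
        _, _, mu0 = twin_moment_blocks(data, V)
        chunks = []
        for c in comps:
            sd = np.sqrt(np.clip(np.diag(est[c]), 1e-3, None))
            corr = est[c] / np.outer(sd, sd)
            angles = []
            # crude row-wise angles: first column only, rest neutral
            for i in range(1, V):
                r = float(np.clip(corr[i, 0], -0.95, 0.95))
                angles.append(np.arccos(r))
                angles.extend([np.pi / 2] * (i - 1))
            chunks.append(sd)
            chunks.append(np.array(angles))
        chunks.append(mu0)
        start = np.concatenate(chunks)
    else:
        chunks = []
        for c in comps:
            chunks.append(np.full(V, 0.6))
            chunks.append(np.full(n_angles, np.pi / 3))
        chunks.append(np.zeros(V))
        start = np.concatenate(chunks)

    def unpack(theta):
        off = 0
        sd = {}
        corr = {}
        for c in comps:
            sd[c] = theta[off : off + V]
            off += V
            corr[c] = _corr_from_angles(V, theta[off : off + n_angles])
            off += n_angles
        means = theta[off : off + V]
        return sd, corr, means

    def builder(theta):
        sd, corr, means = unpack(theta)
        cov = {c: corr[c] * np.outer(sd[c], sd[c]) for c in comps}
        s_mz, s_dz, mu = compose_twin_cov(cov, means)
        return [(mu, s_mz), (mu, s_dz)]

    _R_NAME = {"A": "rG", "C": "rC", "D": "rD", "E": "rE"}

    def summarize(theta):
        sd, corr, _ = unpack(theta)
        total = sum(sd[c] ** 2 for c in comps)
        out = {}
        for c in comps:
            for v in range(V):
                out[f"{c}_share_{v + 1}"] = sd[c][v] ** 2 / total[v]
            for i in range(V):
                for j in range(i):
                    out[f"{_R_NAME[c]}_{j + 1}{i + 1}"] = corr[c][i, j]
        return out

    family = "".join(comps)
    return ModelSpec(
        name=name or f"correlated_factors_{family}",
        param_names=names,
        builder=builder,
        start=start,
        bounds=bounds,
        summarize=summarize,
        meta={"structure": "correlated_factors", "V": V, "components": comps,
              "family": family},
    )


# ---------------------------------------------------------------------------
# post-fit decompositions


@dataclass
class CholeskyEstimates:
    components: tuple[str, ...]
    paths: dict[str, np.ndarray]          # lower-triangular W x W per component
    shares: dict[str, np.ndarray]         # squared paths / total variance
    total_shares: dict[str, np.ndarray]   # per-wave total share per component
    means: np.ndarray

    def to_dict(self):
        return {
            "components": list(self.components),
            "paths": {c: m.tolist() for c, m in self.paths.items()},
            "shares": {c: m.tolist() for c, m in self.shares.items()},
            "total_shares": {c: m.tolist() for c, m in self.total_shares.items()},
            "means": self.means.tolist(),
        }


@dataclass
class CommonPathwayEstimates:
    components: tuple[str, ...]
    loadings: np.ndarray
    latent_shares: dict[str, float]       # e.g. a_c^2, e_c^2 (sum to 1)
    specific_shares: dict[str, np.ndarray]
    communalities: np.ndarray
    total_shares: dict[str, np.ndarray]   # per-wave heritability etc.
    means: np.ndarray

    @property
    def latent_heritability(self) -> float:
        return self.latent_shares.get("A", 0.0) + self.latent_shares.get("D", 0.0)

    def to_dict(self):
        return {
            "components": list(self.components),
            "loadings": self.loadings.tolist(),
            "latent_shares": self.latent_shares,
            "specific_shares": {c: v.tolist() for c, v in self.specific_shares.items()},
            "communalities": self.communalities.tolist(),
            "total_shares": {c: v.tolist() for c, v in self.total_shares.items()},
            "means": self.means.tolist(),
        }


@dataclass
class CorrelatedFactorEstimates:
    components: tuple[str, ...]
    variance_shares: dict[str, np.ndarray]   # per variable
    correlations: dict[str, np.ndarray]      # rG / rE / ... matrices
    means: np.ndarray

    def to_dict(self):
        return {
            "components": list(self.components),
            "variance_shares": {c: v.tolist() for c, v in self.variance_shares.items()},
            "correlations": {c: m.tolist() for c, m in self.correlations.items()},
            "means": self.means.tolist(),
        }


def standardize(result: FitResult):
    """Turn a fitted biometric model into its standardised decomposition.

    Dispatches on the structure recorded in the fit's metadata and returns
    :class:`CholeskyEstimates`, :class:`CommonPathwayEstimates` or
    :class:`CorrelatedFactorEstimates`.
    """
    structure = result.meta.get("structure")
    comps = tuple(result.meta.get("components", ()))
    theta = result.theta
    if structure == "cholesky":
        W = result.meta["W"]
        nt = _tril_count(W)
        tril = np.tril_indices(W)
        paths = {}
        off = 0
        for c in comps:
            X = np.zeros((W, W))
            X[tril] = theta[off : off + nt]
            paths[c] = X
            off += nt
        means = theta[off : off + W]
        total = sum(X @ X.T for X in paths.values())
        tv = np.diag(total)
        if np.any(tv <= 0):
            raise ValueError("zero total variance: shares undefined")
        shares = {c: X**2 / tv[:, None] for c, X in paths.items()}
        totals = {c: (X**2).sum(axis=1) / tv for c, X in paths.items()}
        return CholeskyEstimates(comps, paths, shares, totals, means)
    if structure == "common_pathway":
        W = result.meta["W"]
        off = 0
        lam = theta[off : off + W]
        off += W
        latent = _spherical_paths(theta[off : off + len(comps) - 1])
        off += len(comps) - 1
        specifics = {}
        for c in comps:
            specifics[c] = theta[off : off + W]
            off += W
        means = theta[off : off + W]
        total = lam**2 + sum(specifics[c] ** 2 for c in comps)
        latent_shares = {c: float(p**2) for c, p in zip(comps, latent)}
        spec_shares = {c: specifics[c] ** 2 / total for c in comps}
        communal = lam**2 / total
        totals = {
            c: (latent_shares[c] * lam**2 + specifics[c] ** 2) / total for c in comps
        }
        return CommonPathwayEstimates(
            comps, lam, latent_shares, spec_shares, communal, totals, means
        )
    if structure == "correlated_factors":
        V = result.meta["V"]
        n_angles = V * (V - 1) // 2
        off = 0
        sd = {}
        corr = {}
        for c in comps:
            sd[c] = theta[off : off + V]
            off += V
            corr[c] = _corr_from_angles(V, theta[off : off + n_angles])
            off += n_angles
        means = theta[off : off + V]
        total = sum(sd[c] ** 2 for c in comps)
        shares = {c: sd[c] ** 2 / total for c in comps}
        return CorrelatedFactorEstimates(comps, shares, corr, means)
    raise ValueError(f"fit '{result.model}' carries no biometric structure metadata")


def component_correlations(component_cov: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a component covariance matrix, e.g. the
    genetic correlations rG(i,j) = A_ij / sqrt(A_ii A_jj)."""
    d = np.sqrt(np.diag(component_cov))
    if np.any(d <= 0):
        raise ValueError("zero component variance: correlation undefined")
    return component_cov / np.outer(d, d)
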