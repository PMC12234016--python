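"""Ground-truthed twin-pair simulators.

Every structure is simulated directly from its biometric path equations:
each variance component is drawn as a multivariate-normal latent vector per
pair whose cross-twin correlation equals the component's kinship coefficient
(A: 1 MZ / 0.5 DZ, D: 1 / 0.25, C: 1 / 1, E: independent), and the phenotype
is the sum of the component contributions.  The implied covariance of the
generated data therefore matches :func:`twinstab.biometric.compose_twin_cov`
applied to the same truth, which is the basis of the simulator's own
validation suite.

Right-skewed raw scores (questionnaire-like) are emulated by squaring a
shifted standard-normal phenotype, so the analysis pipeline's square-root
transform approximately restores normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .biometric import KINSHIP, compose_twin_cov, component_correlations
from .data import TwinDataset

DEFAULT_SKEW_SHIFT = 3.0

STRUCTURES = (
    "univariate", "cholesky", "common_pathway", "correlated_factors",
    "item_factors",
)


@dataclass
class SimConfig:
    """Truth specification for one simulated twin cohort.

    ``params`` is structure-specific:

    - univariate: ``{"a2": .., "c2": .., "d2": .., "e2": ..}`` (variance
      shares; omitted components are 0)
    - cholesky: ``{"paths": {comp: lower-triangular W x W path matrix}}``
    - common_pathway: ``{"loadings": (W,), "latent_shares": {comp: share},
      "specific": {comp: (W,) specific variances}}``
    - correlated_factors: ``{"variances": {comp: (V,)},
      "correlations": {comp: (V, V) or scalar off-diagonal}}``
    - item_factors: see :func:`simulate_items`
    """

    n_mz: int
    n_dz: int
    n_waves: int
    structure: str
    params: dict[str, Any] = field(default_factory=dict)
    missing_rate: float = 0.0
    skew: bool = False
    skew_shift: float = DEFAULT_SKEW_SHIFT
    likert: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("n_mz and n_dz must be >= 1")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure '{self.structure}'")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Generating truth alongside its standardised bookkeeping."""

    structure: str
    component_cov: dict[str, np.ndarray]
    shares: dict[str, np.ndarray]      # per-variable standardised shares
    params: dict[str, Any]
    means: np.ndarray
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "structure": self.structure,
            "component_cov": conv(self.component_cov),
            "shares": conv(self.shares),
            "params": conv(self.params),
            "means": conv(self.means),
            "extras": conv(self.extras),
        }


# ---------------------------------------------------------------------------
# truth -> component covariance matrices


def _component_cov_from_config(config: SimConfig) -> dict[str, np.ndarray]:
    p = config.params
    s = config.structure
    if s == "univariate":
        key = {"a2": "A", "c2": "C", "d2": "D", "e2": "E"}
        out = {
            key[k]: np.array([[float(v)]])
            for k, v in p.items()
            if k in key and float(v) != 0.0
        }
        if "E" not in out:
            out["E"] = np.array([[0.0]])
        return out
    if s == "cholesky":
        return {c: np.asarray(X, float) @ np.asarray(X, float).T
                for c, X in p["paths"].items()}
    if s == "common_pathway":
        lam = np.asarray(p["loadings"], float)
        latent = {c: float(v) for c, v in p["latent_shares"].items()}
        if abs(sum(latent.values()) - 1.0) > 1e-9:
            raise ValueError("latent shares must sum to 1")
        common = np.outer(lam, lam)
        out = {}
        for c, share in latent.items():
            spec = np.asarray(p["specific"].get(c, np.zeros(len(lam))), float)
            out[c] = share * common + np.diag(spec)
        return out
    if s == "correlated_factors":
        out = {}
        for c, var in p["variances"].items():
            var = np.asarray(var, float)
            V = len(var)
            corr = p.get("correlations", {}).get(c, np.eye(V))
            if np.isscalar(corr):
                corr = np.full((V, V), float(corr))
                np.fill_diagonal(corr, 1.0)
            corr = np.asarray(corr, float)
            sd = np.sqrt(var)
            out[c] = corr * np.outer(sd, sd)
        return out
    raise ValueError(f"structure '{s}' has no phenotype-level component form")


def _check_psd(component_cov: dict[str, np.ndarray]) -> None:
    for c, m in component_cov.items():
        lam = np.linalg.eigvalsh(0.5 * (m + np.asarray(m).T))
        if lam.min() < -1e-8:
            raise ValueError(
                f"implied covariance of component '{c}' is not positive "
                f"semi-definite (min eigenvalue {lam.min():.3g})"
            )


def _truth_shares(component_cov: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    total = sum(np.diag(m) for m in component_cov.values())
    return {c: np.diag(m) / total for c, m in component_cov.items()}


# ---------------------------------------------------------------------------
# core draw


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """B with B B' = m, tolerant of rank deficiency."""
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_component(rng, B, n, kinship):
    """(n, 2p) latent draws for one component: columns [twin1, twin2] with
    cross-twin correlation ``kinship`` on the component scale."""
    p = B.shape[0]
    if kinship >= 1.0:
        u = rng.standard_normal((n, p))
        z = u @ B.T
        return np.hstack([z, z])
    common = rng.standard_normal((n, p))
    zs = []
    for _ in range(2):
        unique = rng.standard_normal((n, p))
        latent = np.sqrt(kinship) * common + np.sqrt(1.0 - kinship) * unique
        zs.append(latent @ B.T)
    return np.hstack(zs)


def _assemble_dataset(config, mz, dz, n_vars):
    W, V = config.n_waves, n_vars
    cols = [
        (f"score_w{w}_t{t}" if V == 1 else f"score_v{v}_w{w}_t{t}")
        for t in (1, 2)
        for v in range(1, V + 1)
        for w in range(1, W + 1)
    ]
    df = pd.DataFrame(np.vstack([mz, dz]), columns=cols)
    df.insert(0, "zygosity", ["MZ"] * len(mz) + ["DZ"] * len(dz))
    df.insert(0, "pair_id", np.arange(1, len(df) + 1))
    return TwinDataset(df=df, n_waves=W, n_vars=V)


def simulate(config: SimConfig) -> tuple[TwinDataset, TruthRecord]:
    """Draw a twin cohort under the configured biometric truth.

    Returns the dataset together with a :class:`TruthRecord` holding the
    component covariance matrices and standardised shares actually used.
    """
    if config.structure == "item_factors":
        return simulate_items(config)
    component_cov = _component_cov_from_config(config)
    _check_psd(component_cov)
    p = next(iter(component_cov.values())).shape[0]
    n_vars = p // config.n_waves
    if n_vars * config.n_waves != p:
        raise ValueError(
            f"component dimension {p} inconsistent with n_waves={config.n_waves}"
        )
    means = np.asarray(config.params.get("means", np.zeros(p)), float)
    rng = np.random.default_rng(config.seed)
    groups = []
    for n, (zyg_idx) in ((config.n_mz, 0), (config.n_dz, 1)):
        z = np.zeros((n, 2 * p))
        for c, m in component_cov.items():
            k = KINSHIP[c][zyg_idx]
            z += _draw_component(rng, _psd_factor(m), n, k)
        z += np.concatenate([means, means])
        groups.append(z)
    extras = {}
    if config.skew:
        groups = [(g + config.skew_shift) ** 2 for g in groups]
        extras["skew_shift"] = config.skew_shift
    if config.likert is not None:
        cut = np.asarray(config.likert, float)
        groups = [np.digitize(g, cut).astype(float) for g in groups]
        extras["likert"] = cut
    data = _assemble_dataset(config, groups[0], groups[1], n_vars)
    if config.missing_rate > 0:
        data = apply_missingness(data, config.missing_rate, seed=config.seed + 1)
    truth = TruthRecord(
        structure=config.structure,
        component_cov=component_cov,
        shares=_truth_shares(component_cov),
        params=dict(config.params),
        means=means,
        extras=extras,
    )
    return data, truth


def expected_twin_cov(truth: TruthRecord):
    """(sigma_mz, sigma_dz, mu) implied by a truth record — single code path
    through the same composition rule the model builders use."""
    return compose_twin_cov(truth.component_cov, truth.means)


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(data: TwinDataset, rate: float, seed: int = 0) -> TwinDataset:
    """Knock out each twin-by-wave phenotype cell independently (MCAR) with
    probability ``rate``; pairs in which neither twin retains any observed
    wave are dropped (cohort inclusion mirrors 'at least one twin with data
    for at least one wave')."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = data.copy()
    if rate == 0.0:
        return out
    cols = out.phenotype_columns(1) + out.phenotype_columns(2)
    rng = np.random.default_rng(seed)
    vals = out.df[cols].to_numpy(dtype=float)
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    out.df[cols] = vals
    empty = np.isnan(vals).all(axis=1)
    if empty.any():
        out.df = out.df.loc[~empty].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# item-level simulator


def simulate_items(config: SimConfig) -> tuple[TwinDataset, TruthRecord]:
    """Simulate per-item 0-4 responses from a correlated-factor measurement
    model with a biometric (A/E) split of the factors.

    ``params`` keys: ``loadings`` (n_items x n_factors), ``factor_corr``
    (scalar or matrix), ``uniquenesses`` (optional; default 1 - communality),
    ``thresholds`` (cutpoints mapping the continuous response to 0..4;
    ``None`` keeps responses continuous), ``factor_a2`` (heritability of the
    factors, default 0.4).
    """
    p = config.params
    lam = np.asarray(p["loadings"], float)
    n_items, n_fac = lam.shape
    phi = p.get("factor_corr", np.eye(n_fac))
    if np.isscalar(phi):
        phi = np.full((n_fac, n_fac), float(phi))
        np.fill_diagonal(phi, 1.0)
    phi = np.asarray(phi, float)
    communality = np.einsum("if,fg,ig->i", lam, phi, lam)
    if np.any(communality > 1.0 + 1e-9):
        bad = np.nonzero(communality > 1.0 + 1e-9)[0] + 1
        raise ValueError(f"communality exceeds 1 for item(s) {bad.tolist()}")
    psi = np.asarray(p.get("uniquenesses", 1.0 - communality), float)
    if np.any(psi < 0):
        raise ValueError("negative uniqueness")
    thresholds = p.get("thresholds", (-0.5, 0.5, 1.5, 2.5))
    a2 = float(p.get("factor_a2", 0.4))

    rng = np.random.default_rng(config.seed)
    B = _psd_factor(phi)
    rows = []
    zygs = []
    for n, zyg, zi in ((config.n_mz, "MZ", 0), (config.n_dz, "DZ", 1)):
        k = KINSHIP["A"][zi]
        # factor scores with cross-twin correlation a2 * kinship
        fa = _draw_component(rng, B * np.sqrt(a2), n, k)
        fe = _draw_component(rng, B * np.sqrt(1.0 - a2), n, 0.0)
        f = fa + fe  # (n, 2 * n_fac)
        resp = []
        for t in range(2):
            ft = f[:, t * n_fac : (t + 1) * n_fac]
            u = rng.standard_normal((n, n_items)) * np.sqrt(psi)
            resp.append(ft @ lam.T + u)
        rows.append(np.hstack(resp))
        zygs += [zyg] * n
    raw = np.vstack(rows)
    if thresholds is not None:
        raw = np.digitize(raw, np.asarray(thresholds, float)).astype(float)
        const = raw.std(axis=0) == 0.0
        if const.any():
            items = sorted({(i % n_items) + 1 for i in np.nonzero(const)[0]})
            warnings.warn(
                f"degenerate constant item(s) after discretisation: {items}",
                stacklevel=2,
            )

    cols = [
        f"item_w1_i{i}_t{t}"
        for t in (1, 2)
        for i in range(1, n_items + 1)
    ]
    df = pd.DataFrame(raw, columns=cols)
    df.insert(0, "zygosity", zygs)
    df.insert(0, "pair_id", np.arange(1, len(df) + 1))
    data = TwinDataset(df=df, n_waves=1, n_vars=1, n_items=n_items)

    implied_corr = lam @ phi @ lam.T + np.diag(psi)
    implied_corr = component_correlations(implied_corr)
    truth = TruthRecord(
        structure="item_factors",
        component_cov={},
        shares={},
        params=dict(p),
        means=np.zeros(n_items),
        extras={"implied_item_corr": implied_corr, "communality": communality},
    )
    return data, truth
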