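"""Full-information maximum likelihood for multivariate normal data with
arbitrary missingness.

Each row contributes the log density of its *observed* subvector under the
corresponding sub-mean and sub-covariance of the model-implied moments.  Rows
are grouped by missingness pattern and, within a pattern, summarised by their
count, mean and scatter, so a likelihood evaluation costs one small Cholesky
factorisation per distinct pattern rather than one per row.  Patterns of equal
size are batched through numpy's stacked linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PatternStats:
    """Sufficient statistics of one data matrix, grouped by missing pattern.

    Parameters
    ----------
    data : (n, p) array with NaN marking missing cells.  Rows with no
        observed cell are rejected: they carry no likelihood information and
        upstream code is expected to have dropped them.
    """

    p: int
    n_rows: int
    n_values: int
    # one entry per distinct pattern *size* s: (idx (m,s), n (m,), xbar (m,s),
    # scatter (m,s,s)) where scatter is the ML (biased, /n) within-pattern
    # second moment about the pattern mean.
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )

    @classmethod
    def from_data(cls, data: np.ndarray) -> "PatternStats":
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D array of shape (n, p)")
        n, p = data.shape
        obs = ~np.isnan(data)
        if not obs.any(axis=1).all():
            raise ValueError("rows with no observed values are not allowed")
        self = cls(p=p, n_rows=n, n_values=int(obs.sum()))
        # encode each row's pattern as bytes for grouping
        keys = np.packbits(obs, axis=1)
        order = np.lexsort(keys.T[::-1])
        keys_sorted = keys[order]
        change = np.any(keys_sorted[1:] != keys_sorted[:-1], axis=1)
        starts = np.concatenate(([0], np.nonzero(change)[0] + 1, [n]))

        by_size: dict[int, list[tuple[np.ndarray, int, np.ndarray, np.ndarray]]] = {}
        for a, b in zip(starts[:-1], starts[1:]):
            rows = order[a:b]
            mask = obs[rows[0]]
            idx = np.nonzero(mask)[0]
            sub = data[np.ix_(rows, idx)]
            m = len(rows)
            xbar = sub.mean(axis=0)
            dev = sub - xbar
            scatter = dev.T @ dev / m
            by_size.setdefault(len(idx), []).append((idx, m, xbar, scatter))

        for s in sorted(by_size):
            entries = by_size[s]
            idx = np.array([e[0] for e in entries])
            cnt = np.array([e[1] for e in entries], dtype=float)
            xbar = np.array([e[2] for e in entries])
            scat = np.array([e[3] for e in entries])
            self.groups.append((idx, cnt, xbar, scat))
        return self


def _check_pd(sigma: np.ndarray) -> bool:
    """True when sigma is symmetric positive definite.

    Every principal submatrix of a PD matrix is PD, so a single check on the
    full matrix guarantees all pattern submatrices can be factorised.
    """
    try:
        np.linalg.cholesky(sigma)
        return True
    except np.linalg.LinAlgError:
        return False


def neg2_loglik(mu: np.ndarray, sigma: np.ndarray, stats: PatternStats) -> float:
    """-2 log likelihood of the data summarised in ``stats``."""
    val, _, _ = _neg2_core(mu, sigma, stats, want_grad=False)
    return val


def neg2_loglik_grad(
    mu: np.ndarray, sigma: np.ndarray, stats: PatternStats
) -> tuple[float, np.ndarray, np.ndarray]:
    """-2LL and its gradient with respect to every entry of mu and sigma.

    The sigma gradient is returned as a full (p, p) symmetric matrix G such
    that df = sum(G * dSigma) for any symmetric perturbation dSigma.
    """
    return _neg2_core(mu, sigma, stats, want_grad=True)


def _neg2_core(mu, sigma, stats, want_grad):
    p = stats.p
    f = 0.0
    dmu = np.zeros(p) if want_grad else None
    dsig = np.zeros((p, p)) if want_grad else None
    for idx, cnt, xbar, scat in stats.groups:
        s = idx.shape[1]
        sub = sigma[idx[:, :, None], idx[:, None, :]]  # (m, s, s)
        chol = np.linalg.cholesky(sub)
        logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        d = xbar - mu[idx]  # (m, s)
        moment = scat + d[:, :, None] * d[:, None, :]
        sinv_m = np.linalg.solve(sub, moment)
        trace = np.trace(sinv_m, axis1=1, axis2=2)
        f += float((cnt * (s * _LOG_2PI + logdet + trace)).sum())
        if want_grad:
            sinv = np.linalg.inv(sub)
            g = cnt[:, None, None] * (sinv - sinv_m @ sinv)
            np.add.at(dsig, (idx[:, :, None], idx[:, None, :]), g)
            gm = -2.0 * cnt[:, None] * np.einsum("mij,mj->mi", sinv, d)
            np.add.at(dmu, idx, gm)
    return f, dmu, dsig


def complete_data_neg2_loglik(mu, sigma, n, xbar, scatter) -> float:
    """-2LL from complete-data sufficient statistics (n, mean, ML scatter).

    Closed form used as an independent oracle for the pattern-wise FIML path
    when no cell is missing.
    """
    p = len(mu)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("sigma not positive definite")
    d = np.asarray(xbar) - np.asarray(mu)
    sinv = np.linalg.inv(sigma)
    return float(
        n * (p * _LOG_2PI + logdet + np.trace(sinv @ scatter) + d @ sinv @ d)
    )
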