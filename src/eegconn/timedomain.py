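"""Time-domain connectivity: Pearson correlation and the Gaussian-copula
information measures (MI, conditional MI, symbol-weighted MI, O-information)
computed on broadband region series.

The information measures use the Gaussian-copula estimator: each marginal is
rank-transformed to uniform (average ranks for ties, mapped to rank/(n+1))
and pushed through the inverse normal CDF.  Entropies are then the
closed-form Gaussian entropies of the covariance of the transformed
variables, which makes every estimator invariant to strictly monotone
marginal transforms.  All information quantities are reported in nats.

O-information is evaluated pair-vs-rest: the pair's two series and the
remaining regions as a single multivariate block, three blocks in total.
Its sign separates redundancy-dominated (positive) from synergy-dominated
(negative) interaction structure; with fewer than three blocks it is
identically zero.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "copula_normalize",
    "pearson_rho",
    "copula_mi",
    "copula_cmi",
    "symbolize",
    "symbolic_similarity",
    "weighted_mi",
    "o_information",
    "timedomain_edge_values",
    "TIMEDOMAIN_METRICS",
]

TIMEDOMAIN_METRICS = ("rho", "MI", "CMI", "WMI", "O_info")

_COND_LIMIT = 1e10  # covariance condition number above which we refuse


def copula_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-map a series to (0, 1) and apply the inverse normal CDF.

    Average ranks are used for ties; ranks are scaled by 1/(n+1) so the
    transform never touches the infinite tails.  If more than half the
    samples are involved in ties the rank transform is degenerate and a
    warning is raised.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    uniq, counts = np.unique(x, return_counts=True)
    if counts[counts > 1].sum() > n / 2:
        warnings.warn("more than 50% tied samples: rank transform is "
                      "degenerate", RuntimeWarning, stacklevel=2)
    r = rankdata(x, method="average")
    return norm.ppf(r / (n + 1))


def _gauss_entropy(cov: np.ndarray) -> float:
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    sign, ld = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance not positive definite")
    return 0.5 * (d * np.log(2 * np.pi * np.e) + ld)


def _as_z_block(arr: np.ndarray | None) -> np.ndarray:
    """Copula-normalize each row/column of a conditioning block; returns an
    (n, d) matrix of z columns (possibly d = 0)."""
    if arr is None:
        return np.empty((0, 0))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        return np.empty((0, 0))
    # rows are variables (region series)
    return np.column_stack([copula_normalize(row) for row in arr])


def pearson_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient rho = S_xy / (sigma_x sigma_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def copula_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-copula mutual information MI(X;Y) = H(X)+H(Y)-H(X,Y), in
    nats; non-negative, zero for independent variables."""
    zx = copula_normalize(x)
    zy = copula_normalize(y)
    if zx.size != zy.size:
        raise ValueError("x and y must have equal length")
    if zx.size < 10:
        raise ValueError("need at least 10 samples")
    r = np.corrcoef(zx, zy)[0, 1]
    mi = -0.5 * np.log1p(-min(r * r, 1 - 1e-15))
    return _clamp_nonneg(mi)


def _clamp_nonneg(v: float) -> float:
    return float(max(v, 0.0)) if v > -1e-10 else _raise_neg(v)


def _raise_neg(v: float) -> float:
    raise ValueError(f"information estimate {v} below zero tolerance")


def copula_cmi(x: np.ndarray, y: np.ndarray,
               Z: np.ndarray | None = None) -> float:
    """Conditional MI(X;Y|Z) under the Gaussian copula, Z a (d, n) block of
    conditioning series (typically every other region).  With empty Z this
    is exactly ``copula_mi``."""
    zb = _as_z_block(Z)
    if zb.shape[1] == 0:
        return copula_mi(x, y)
    zx = copula_normalize(x)
    zy = copula_normalize(y)
    n = zx.size
    if zb.shape[0] != n or zy.size != n:
        raise ValueError("all series must have equal length")
    if zb.shape[1] > n / 10:
        raise ValueError(
            f"conditioning set of {zb.shape[1]} dims needs more than "
            f"{10 * zb.shape[1]} samples for a stable covariance")
    J = np.column_stack([zx, zy, zb])
    C = np.cov(J, rowvar=False)
    if np.linalg.cond(C) > _COND_LIMIT:
        raise ValueError(
            "ill-conditioned joint covariance; apply shrinkage or condition "
            "on fewer regions")
    # CMI = H(x,Z) + H(y,Z) - H(Z) - H(x,y,Z)
    idx_z = np.arange(2, 2 + zb.shape[1])
    cmi = (_gauss_entropy(C[np.ix_(np.r_[0, idx_z], np.r_[0, idx_z])])
           + _gauss_entropy(C[np.ix_(np.r_[1, idx_z], np.r_[1, idx_z])])
           - _gauss_entropy(C[np.ix_(idx_z, idx_z)])
           - _gauss_entropy(C))
    return _clamp_nonneg(cmi)


def symbolize(x: np.ndarray) -> np.ndarray:
    """Map a series to its local-trend symbol stream of length n-2.

    Symbol 'a' where x(t-1) < x(t) < x(t+1) (local increase), 'b' where
    x(t-1) > x(t) > x(t+1) (local decrease), '0' otherwise; exact ties fall
    into '0'.  Returned as a unicode array over {'a', 'b', '0'}.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to symbolize")
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    out = np.full(x.size - 2, "0", dtype="<U1")
    out[(prev < cur) & (cur < nxt)] = "a"
    out[(prev > cur) & (cur > nxt)] = "b"
    return out


def symbolic_similarity(sx: np.ndarray, sy: np.ndarray) -> float:
    """s_w = 1 - Hamming distance / stream length, in [0, 1]; 1 means the
    symbol streams are identical."""
    sx = np.asarray(sx)
    sy = np.asarray(sy)
    if sx.shape != sy.shape:
        raise ValueError("symbol streams must have equal length")
    if sx.size == 0:
        raise ValueError("empty symbol stream")
    return float(1.0 - np.mean(sx != sy))


def weighted_mi(x: np.ndarray, y: np.ndarray) -> float:
    """WMI(X;Y) = s_w(X^, Y^) * MI(X;Y): copula MI down-weighted by symbolic
    dissimilarity of the local-trend patterns; 0 <= WMI <= MI."""
    return symbolic_similarity(symbolize(x), symbolize(y)) * copula_mi(x, y)


def o_information(x: np.ndarray, y: np.ndarray,
                  Z: np.ndarray | None = None) -> float:
    """Pair-vs-rest O-information over the three blocks {x, y, Z}.

    For blocks X_1..X_n the statistic is
    Omega = (n-2) H(X_1..X_n) + sum_j [H(X_j) - H(X_-j)];
    positive values indicate redundancy-dominated structure, negative values
    synergy.  With an empty Z only two blocks remain and the statistic is
    identically zero.
    """
    zb = _as_z_block(Z)
    zx = copula_normalize(x)
    zy = copula_normalize(y)
    if zb.shape[1] == 0:
        return 0.0
    n = zx.size
    if zb.shape[0] != n or zy.size != n:
        raise ValueError("all series must have equal length")
    if zb.shape[1] > n / 10:
        raise ValueError(
            f"conditioning set of {zb.shape[1]} dims needs more than "
            f"{10 * zb.shape[1]} samples for a stable covariance")
    J = np.column_stack([zx, zy, zb])
    C = np.cov(J, rowvar=False)
    if np.linalg.cond(C) > _COND_LIMIT:
        raise ValueError(
            "ill-conditioned joint covariance; apply shrinkage or condition "
            "on fewer regions")
    idx_z = np.arange(2, 2 + zb.shape[1])
    h_all = _gauss_entropy(C)
    h_x = _gauss_entropy(C[:1, :1])
    h_y = _gauss_entropy(C[1:2, 1:2])
    h_z = _gauss_entropy(C[np.ix_(idx_z, idx_z)])
    h_yz = _gauss_entropy(C[np.ix_(np.r_[1, idx_z], np.r_[1, idx_z])])
    h_xz = _gauss_entropy(C[np.ix_(np.r_[0, idx_z], np.r_[0, idx_z])])
    h_xy = _gauss_entropy(C[:2, :2])
    # (n-2) = 1 for three blocks
    return float(h_all + (h_x - h_yz) + (h_y - h_xz) + (h_z - h_xy))


# ---------------------------------------------------------------------------
# Whole-matrix evaluation
# ---------------------------------------------------------------------------

def timedomain_edge_values(data: np.ndarray) -> dict[str, np.ndarray]:
    """All five time-domain metrics for every region pair of one subject.

    ``data`` is (n_regions, n_samples) broadband series.  The copula
    transform, covariance and symbol streams are computed once per region;
    pair values are read off sub-determinants, so this matches the
    per-pair operations exactly while scaling to full parcellations.
    Returns condensed upper-triangle vectors keyed by metric name.
    """
    data = np.asarray(data, dtype=float)
    R, n = data.shape
    if R < 2:
        raise ValueError("need at least two regions")
    iu, ju = np.triu_indices(R, k=1)

    rho_mat = np.corrcoef(data)
    Zc = np.column_stack([copula_normalize(row) for row in data])
    C = np.cov(Zc, rowvar=False)
    rz = np.corrcoef(Zc, rowvar=False)

    mi = -0.5 * np.log1p(-np.minimum(rz[iu, ju] ** 2, 1 - 1e-15))
    mi = np.maximum(mi, 0.0)

    symbols = np.stack([symbolize(row) for row in data])
    s_w = 1.0 - np.mean(symbols[iu] != symbols[ju], axis=-1)
    wmi = s_w * mi

    cmi = np.empty(iu.size)
    o_info = np.empty(iu.size)
    if R >= 3:
        if R - 2 > n / 10:
            raise ValueError(
                f"{R - 2} conditioning dims need more than {10 * (R - 2)} "
                "samples; record longer series or shrink the parcellation")
        sign, ld_all = np.linalg.slogdet(C)
        if sign <= 0 or np.linalg.cond(C) > _COND_LIMIT:
            raise ValueError(
                "ill-conditioned joint covariance; apply shrinkage or "
                "condition on fewer regions")
        ld_minus1 = np.empty(R)
        for k in range(R):
            keep = np.r_[0:k, k + 1:R]
            ld_minus1[k] = np.linalg.slogdet(C[np.ix_(keep, keep)])[1]
        ld_pair = np.log(C[iu, iu] * C[ju, ju] - C[iu, ju] ** 2)
        for e, (a, b) in enumerate(zip(iu, ju)):
            keep = np.r_[0:a, a + 1:b, b + 1:R]
            ld_z = np.linalg.slogdet(C[np.ix_(keep, keep)])[1]
            # CMI = 0.5 [ld(C_-b) + ld(C_-a) - ld(C_Z) - ld(C)]
            cmi[e] = 0.5 * (ld_minus1[b] + ld_minus1[a] - ld_z - ld_all)
            # 3-block O-information; unit-variance marginals drop out
            o_info[e] = 0.5 * (ld_all + np.log(C[a, a]) + np.log(C[b, b])
                               + ld_z - ld_minus1[a] - ld_minus1[b]
                               - ld_pair[e])
        cmi = np.maximum(cmi, 0.0)
    else:
        cmi = mi.copy()
        o_info = np.zeros(iu.size)

    return {"rho": rho_mat[iu, ju], "MI": mi, "CMI": cmi, "WMI": wmi,
            "O_info": o_info}
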