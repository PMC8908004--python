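"""Restricted-maximum-likelihood machinery for the single-kinship mixed model.

Solves y = X b + g + e with g ~ N(0, sigma_g^2 K) and e ~ N(0, sigma_e^2 I)
by rotating into the eigenbasis of K, so the covariance becomes diagonal,
V = sigma_e^2 diag(delta * d_i + 1) with delta = sigma_g^2 / sigma_e^2.
The REML criterion is profiled down to the scalar ratio delta and maximised
on a dense log grid refined by fixed-iteration golden-section search; the
fixed iteration count makes the search branch-free, so the same code path
serves one response vector or a whole matrix of permuted responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: log10-spaced candidate values of the variance ratio delta.
DELTA_GRID = np.logspace(-8.0, 8.0, 81)
#: golden-section refinement iterations (bracket shrinks by 0.618 each).
N_GOLDEN = 80

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class RotatedDesign:
    """A fixed-effect design expressed in the eigenbasis of the kinship.

    Attributes
    ----------
    eigvals : (n,) eigenvalues of K, ascending.
    U : (n, n) orthonormal eigenvectors of K.
    X : (n, p) rotated fixed-effect design, ``U.T @ X_raw``.
    """

    eigvals: np.ndarray
    U: np.ndarray
    X: np.ndarray


def rotate(K: np.ndarray, X_raw: np.ndarray) -> RotatedDesign:
    """Eigendecompose a symmetric PSD kinship and rotate the design."""
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8 * max(1.0, abs(d.max())):
        raise ValueError(
            f"kinship matrix is not positive semi-definite "
            f"(min eigenvalue {d.min():.3e})"
        )
    d = np.clip(d, 0.0, None)
    return RotatedDesign(eigvals=d, U=U, X=U.T @ X_raw)


def _reml_loglik(Y: np.ndarray, X: np.ndarray, d: np.ndarray,
                 delta: np.ndarray) -> np.ndarray:
    """Profiled REML log-likelihood, vectorised over response columns.

    Parameters
    ----------
    Y : (n, m) rotated responses (one column per response).
    X : (n, p) rotated design shared by all columns.
    d : (n,) kinship eigenvalues.
    delta : (m,) variance ratio, one per column.

    Returns
    -------
    (m,) REML log-likelihood at each column's delta.
    """
    n, p = X.shape
    W = delta[:, None] * d[None, :] + 1.0          # (m, n)
    iW = 1.0 / W
    A = np.einsum("ni,mn,nj->mij", X, iW, X)       # (m, p, p)
    b = np.einsum("ni,mn,nm->mi", X, iW, Y)        # (m, p)
    yy = np.einsum("nm,mn,nm->m", Y, iW, Y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = yy - np.einsum("mi,mi->m", b, beta)
    rss = np.maximum(rss, 1e-300)
    sign, logdetA = np.linalg.slogdet(A)
    nu = n - p
    return -0.5 * (
        nu * (np.log(2.0 * np.pi * rss / nu) + 1.0)
        + np.log(W).sum(axis=1)
        + logdetA
    )


def optimize_delta(Y: np.ndarray, rot: RotatedDesign) -> np.ndarray:
    """Maximise the profiled REML criterion over delta for each column of Y.

    Grid search over :data:`DELTA_GRID` followed by golden-section
    refinement of the bracketing interval in log space. Deterministic.
    """
    Y = np.atleast_2d(Y.T).T if Y.ndim == 1 else Y
    d, X = rot.eigvals, rot.X
    m = Y.shape[1]
    grid = DELTA_GRID
    ll = np.empty((grid.size, m))
    for k, dl in enumerate(grid):
        ll[k] = _reml_loglik(Y, X, d, np.full(m, dl))
    best = ll.argmax(axis=0)
    lo = np.log(grid[np.maximum(best - 1, 0)])
    hi = np.log(grid[np.minimum(best + 1, grid.size - 1)])
    # golden-section on log(delta); fixed iterations keep it vectorisable
    x1 = hi - _INVPHI * (hi - lo)
    x2 = lo + _INVPHI * (hi - lo)
    f1 = _reml_loglik(Y, X, d, np.exp(x1))
    f2 = _reml_loglik(Y, X, d, np.exp(x2))
    for _ in range(N_GOLDEN):
        take1 = f1 >= f2  # maximum lies in [lo, x2]; else in [x1, hi]
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x2_keep, f2_keep = x1, f1  # becomes the new x2 when take1
        x1_keep, f1_keep = x2, f2  # becomes the new x1 otherwise
        x_new = np.where(take1, hi - _INVPHI * (hi - lo),
                         lo + _INVPHI * (hi - lo))
        f_new = _reml_loglik(Y, X, d, np.exp(x_new))
        x1 = np.where(take1, x_new, x1_keep)
        f1 = np.where(take1, f_new, f1_keep)
        x2 = np.where(take1, x2_keep, x_new)
        f2 = np.where(take1, f2_keep, f_new)
    return np.exp((lo + hi) / 2.0)


def gls_last_coef(Y: np.ndarray, rot: RotatedDesign,
                  delta: np.ndarray) -> tuple[np.ndarray, ...]:
    """GLS fit at fixed delta; returns stats for the LAST design column.

    Returns ``(beta_last, se_last, sigma2_e, sigma2_g, rss_dof)`` where each
    element is an (m,) array aligned with the columns of Y.
    """
    Y = np.atleast_2d(Y.T).T if Y.ndim == 1 else Y
    d, X = rot.eigvals, rot.X
    n, p = X.shape
    delta = np.broadcast_to(np.atleast_1d(delta), (Y.shape[1],))
    W = delta[:, None] * d[None, :] + 1.0
    iW = 1.0 / W
    A = np.einsum("ni,mn,nj->mij", X, iW, X)
    b = np.einsum("ni,mn,nm->mi", X, iW, Y)
    yy = np.einsum("nm,mn,nm->m", Y, iW, Y)
    Ainv = np.linalg.inv(A)
    beta = np.einsum("mij,mj->mi", Ainv, b)
    rss = np.maximum(yy - np.einsum("mi,mi->m", b, beta), 0.0)
    nu = n - p
    sigma2_e = rss / nu
    se = np.sqrt(Ainv[:, -1, -1] * sigma2_e)
    return beta[:, -1], se, sigma2_e, delta * sigma2_e, np.full(Y.shape[1], nu)


def reml_fit(y: np.ndarray, X_raw: np.ndarray,
             K: np.ndarray) -> tuple[float, float, float]:
    """One-shot REML fit: returns (sigma2_g, sigma2_e, loglik)."""
    rot = rotate(K, X_raw)
    delta = optimize_delta(y[:, None], rot)
    ll = _reml_loglik(y[:, None], rot.X, rot.eigvals, delta)[0]
    _, _, s2e, s2g, _ = gls_last_coef(y[:, None], rot, delta)
    return float(s2g[0]), float(s2e[0]), float(ll)
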