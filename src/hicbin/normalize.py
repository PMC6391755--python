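"""Two-stage contact-map bias removal.

Raw Hi-C counts carry biases from restriction-site density, mappability and
accessibility.  Stage one divides each count ``c_ij`` by the product of the
contigs' cut-site tallies ``n_i * n_j`` (summed over the library's enzymes,
floored at 1).  Stage two finds a positive diagonal scaling ``x`` rendering
the site-normalized matrix bistochastic — every row of
``diag(x) A diag(x)`` sums to 1 — with the Knight-Ruiz inexact-Newton
algorithm, falling back to Sinkhorn-Knopp alternating scaling when the
Newton iteration stalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from hicbin.contacts import ContactMap
from hicbin.contigs import ContigRecord

logger = logging.getLogger(__name__)


@dataclass
class KrResult:
    x: np.ndarray
    balanced: sp.csr_matrix
    converged: bool
    method: str  # "kr" or "sinkhorn"
    residual: float


@dataclass
class BalancedMap:
    """Balanced contact weights plus the KR scale vector that produced them.

    ``weights`` is ``diag(x) A diag(x)`` for the site-normalized matrix A,
    restricted to contigs with non-zero off-diagonal support (rows without
    any inter-contig signal cannot carry graph edges and are dropped,
    recorded in ``dropped_ids``).
    """

    contigs: list[ContigRecord]
    weights: sp.csr_matrix
    kr_scale: np.ndarray
    tol: float
    converged: bool
    method: str = "kr"
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.contigs]


def site_normalize(
    cmap: ContactMap, table: Sequence[ContigRecord] | None = None, enzymes: Sequence[str] | None = None
) -> sp.csr_matrix:
    """Divide each raw count by the cut-site product ``max(n_i,1) * max(n_j,1)``.

    ``n_i`` sums the contig's tallies over ``enzymes`` (all tallied enzymes
    when None).  The pseudocount floor keeps contigs with no recognition
    site analyzable.  Zero entries stay zero and symmetry is preserved.
    """
    contigs = list(table) if table is not None else cmap.contigs
    n = np.array([max(c.total_sites(enzymes), 1) for c in contigs], dtype=float)
    d = sp.diags(1.0 / n)
    return (d @ cmap.counts.astype(float) @ d).tocsr()


def _sinkhorn(A: sp.csr_matrix, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Symmetric Sinkhorn-Knopp: x <- x / sqrt(rowsum(diag(x) A diag(x)))."""
    n = A.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        r = x * (A @ x)
        if np.max(np.abs(r - 1.0)) <= tol:
            return x, True
        x = x / np.sqrt(r)
    r = x * (A @ x)
    return x, bool(np.max(np.abs(r - 1.0)) <= tol)


def _kr_newton(
    A: sp.csr_matrix, tol: float, max_iter: int, delta: float = 0.1, Delta: float = 3.0
) -> tuple[np.ndarray, bool]:
    """Knight-Ruiz inexact-Newton balancing (conjugate-gradient inner loop).

    Port of the classic ``bnewt`` scheme for symmetric non-negative A with
    total support.  ``max_iter`` bounds the matrix-vector product count.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g = 0.9
    eta = etamax = 0.1
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    mvp = 0
    while rout > rt and mvp < max_iter:
        k = 0
        y = e.copy()
        inner_tol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0 or not np.isfinite(denom):
                return x, False
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = np.min((delta - y[ind]) / ap[ind]) if ind.any() else 1.0
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = np.min((Delta - y[ind]) / ap[ind]) if ind.any() else 1.0
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k + mvp > max_iter:
                break
        x = x * y
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return np.where(np.isfinite(x) & (x > 0), x, 1.0), False
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        mvp += k + 1
        # adaptive forcing term for the inexact Newton step
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, np.finfo(float).tiny))
    return x, bool(rout <= rt)


def kr_balance(A: sp.spmatrix | np.ndarray, tol: float = 1e-6, max_iter: int = 1000) -> KrResult:
    """Bistochastically balance a symmetric non-negative matrix.

    Returns the positive scale vector ``x``, the balanced matrix
    ``S = diag(x) A diag(x)``, and which method converged.  All-zero rows
    are excluded from balancing and assigned scale 1; their row sums stay 0
    and are not held to the row-sum criterion.
    """
    A = sp.csr_matrix(A, dtype=float)
    n = A.shape[0]
    x = np.ones(n)
    active = np.flatnonzero(np.asarray((A != 0).sum(axis=1)).ravel() > 0)
    method = "kr"
    converged = True
    if len(active):
        sub = A[active][:, active].tocsr()
        # guard: rows whose support vanished inside the active submatrix
        row_nz = np.asarray((sub != 0).sum(axis=1)).ravel()
        if (row_nz == 0).any():
            lost = active[row_nz == 0]
            logger.warning("%d rows have support only outside the active set; excluded", len(lost))
            active = active[row_nz > 0]
            sub = A[active][:, active].tocsr()
        xs, converged = _kr_newton(sub, tol, max_iter)
        if not converged:
            logger.info("KR Newton did not converge; falling back to Sinkhorn-Knopp")
            xs, converged = _sinkhorn(sub, tol, max_iter * 10)
            method = "sinkhorn"
        x[active] = xs
    d = sp.diags(x)
    S = (d @ A @ d).tocsr()
    rowsum = np.asarray(S.sum(axis=1)).ravel()
    residual = float(np.max(np.abs(rowsum[active] - 1.0))) if len(active) else 0.0
    converged = converged and residual <= tol
    return KrResult(x=x, balanced=S, converged=converged, method=method, residual=residual)


def normalize_map(
    cmap: ContactMap,
    enzymes: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> BalancedMap:
    """Full bias removal: site-product division, then KR balancing.

    Contigs with zero off-diagonal support after site normalization are
    dropped before balancing (they cannot carry clustering edges).
    """
    A = site_normalize(cmap, enzymes=enzymes)
    offdiag = A - sp.diags(A.diagonal())
    support = np.asarray((offdiag != 0).sum(axis=1)).ravel() > 0
    dropped = [c.id for c, keep in zip(cmap.contigs, support) if not keep]
    if dropped:
        logger.info("dropping %d contigs with no off-diagonal support before balancing", len(dropped))
    keep = np.flatnonzero(support)
    sub = A[keep][:, keep].tocsr()
    res = kr_balance(sub, tol=tol, max_iter=max_iter)
    return BalancedMap(
        contigs=[cmap.contigs[k] for k in keep],
        weights=res.balanced,
        kr_scale=res.x,
        tol=tol,
        converged=res.converged,
        method=res.method,
        dropped_ids=dropped,
    )
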