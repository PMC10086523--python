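"""Matrix balancing and distance-decay expectation.

Knight-Ruiz balancing finds per-bin weights ``w`` such that every unmasked
row of ``diag(w) C diag(w)`` sums to 1. Bins with too few informative pixels
are masked (weight NaN) before balancing. The expected profile is the mean
balanced value per diagonal; observed/expected (O/E) divides each pixel by
that profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import ContactMap

log = logging.getLogger(__name__)

__all__ = ["ExpectedProfile", "kr_balance", "expected_by_distance",
           "observed_over_expected"]

MIN_NONZERO_FRACTION = 0.1  # rows sparser than this are masked


@dataclass
class ExpectedProfile:
    """Mean balanced contact value per diagonal, one array per chromosome."""

    values: dict[str, np.ndarray]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tdistance_bins\texpected\n")
            for chrom in sorted(self.values):
                for d, v in enumerate(self.values[chrom]):
                    if np.isfinite(v):
                        fh.write(f"{chrom}\t{d}\t{v:.6g}\n")


def _bnewt(A: np.ndarray, tol: float, max_iter: int,
           delta: float = 0.1, big_delta: float = 3.0) -> np.ndarray:
    """Knight-Ruiz balancing (inner-outer Newton with conjugate gradients).

    Returns x with diag(x) A diag(x) doubly stochastic; raises on failure.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    n_mvp = 0
    while rout > rt:
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        n_mvp += k + 1
        if n_mvp > max_iter:
            raise RuntimeError("Knight-Ruiz did not converge")
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Symmetric Sinkhorn-Knopp fixed point as a fallback balancer."""
    n = A.shape[0]
    r = np.ones(n)
    c = np.ones(n)
    for _ in range(max_iter):
        r = 1.0 / (A @ c)
        c = 1.0 / (A @ r)
        w = np.sqrt(r * c)
        resid = np.abs(w * (A @ w) - 1.0).max()
        if resid < tol:
            return w
    raise RuntimeError("Sinkhorn fallback did not converge")


def kr_balance(cmap: ContactMap, tol: float = 1e-8, max_iter: int = 1000) -> ContactMap:
    """Balance each chromosome's raw matrix; weights are stored on the map.

    Rows with fewer than 10% non-zero pixels are masked (NaN weight) before
    balancing; non-convergence of both KR and the Sinkhorn fallback raises,
    which usually indicates the mask needs review.
    """
    weights: dict[str, np.ndarray] = {}
    for chrom in cmap.chroms():
        C = cmap.dense(chrom)
        n = C.shape[0]
        nnz_frac = (C > 0).sum(axis=1) / n
        keep = nnz_frac >= MIN_NONZERO_FRACTION
        w = np.full(n, np.nan)
        m = int(keep.sum())
        if m == 0:
            log.warning("chromosome %s fully masked; no balancing", chrom)
            weights[chrom] = w
            continue
        sub = C[np.ix_(keep, keep)]
        try:
            x = _bnewt(sub, tol=tol, max_iter=max_iter)
        except (RuntimeError, FloatingPointError, ZeroDivisionError):
            log.warning("KR failed on %s; falling back to Sinkhorn", chrom)
            x = _sinkhorn(sub, tol=tol, max_iter=100 * max_iter)
        w[keep] = x
        weights[chrom] = w
    return ContactMap(cmap.grid, cmap.counts, weights)


def expected_by_distance(cmap: ContactMap) -> ExpectedProfile:
    """Mean balanced value per diagonal over unmasked pixel pairs."""
    if not cmap.is_balanced:
        raise ValueError("map must be balanced before computing expectations")
    values = {}
    for chrom in cmap.chroms():
        B = cmap.balanced_dense(chrom)
        n = B.shape[0]
        prof = np.full(n, np.nan)
        for d in range(n):
            diag = np.diagonal(B, offset=d)
            good = np.isfinite(diag)
            if good.any():
                prof[d] = diag[good].mean()
        values[chrom] = prof
    return ExpectedProfile(values)


def observed_over_expected(
    cmap: ContactMap, profile: ExpectedProfile | None = None
) -> dict[str, np.ndarray]:
    """Dense O/E matrix per chromosome; NaN where masked or expected is 0."""
    if profile is None:
        profile = expected_by_distance(cmap)
    out = {}
    for chrom in cmap.chroms():
        B = cmap.balanced_dense(chrom)
        n = B.shape[0]
        if len(profile[chrom]) != n:
            raise ValueError(f"profile for {chrom} does not match grid")
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        exp = profile[chrom][d]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = B / exp
        oe[~np.isfinite(oe)] = np.nan
        out[chrom] = oe
    return out
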