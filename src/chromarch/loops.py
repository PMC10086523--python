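"""Focal-peak (HiCCUPS-style) loop calling, APA, and loop comparisons.

Each candidate pixel is tested against the maximum of four local expectation
estimators (donut annulus, horizontal and vertical stripes, lower-left
quadrant), scaled to raw-count space via the balancing weights, with a
Poisson upper-tail p-value and global BH correction. Significant pixels are
clustered by 8-connectivity; cluster centroids become loops, merged across
resolutions preferring the finest call. APA averages mean-normalized O/E
submatrices around loops; its score is the center over the mean of the
6x6 lower-left (diagonal-proximal) corner block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.signal import fftconvolve

from .balance import expected_by_distance, observed_over_expected
from .config import LoopCallConfig
from .model import Boundary, ContactMap, Domain, Loop

log = logging.getLogger(__name__)

__all__ = ["PixelTest", "ApaResult", "call_loops", "apa",
           "classify_loops_vs_tads", "match_loops"]


@dataclass
class PixelTest:
    pixel: tuple[int, int]
    observed: float
    expected: dict[str, float]   # donut / horizontal / vertical / lowerleft
    pvalue: float
    qvalue: float


@dataclass
class ApaResult:
    matrix: np.ndarray   # (2W+1) x (2W+1), mean of mean-normalized submatrices
    score: float
    n_loops: int


def _kernels(p: int, w: int) -> dict[str, np.ndarray]:
    size = 2 * w + 1
    di = np.arange(-w, w + 1)[:, None] * np.ones((1, size), dtype=int)
    dj = np.arange(-w, w + 1)[None, :] * np.ones((size, 1), dtype=int)
    cheb = np.maximum(np.abs(di), np.abs(dj))
    donut = (cheb > p) & (cheb <= w) & (di != 0) & (dj != 0)
    horiz = (np.abs(di) <= 1) & (np.abs(dj) > p) & (np.abs(dj) <= w)
    vert = (np.abs(dj) <= 1) & (np.abs(di) > p) & (np.abs(di) <= w)
    lowerleft = (di >= 1) & (dj <= -1) & ~((di <= p) & (-dj <= p))
    return {"donut": donut, "horizontal": horiz, "vertical": vert,
            "lowerleft": lowerleft}


def _conv(mat: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # correlate == convolve with flipped kernel; kernels here are symmetric
    # under 180-degree rotation except lowerleft, so flip explicitly.
    return fftconvolve(mat, kernel[::-1, ::-1].astype(float), mode="same")


def _call_one_resolution(cmap: ContactMap, res_idx: int, cfg: LoopCallConfig
                         ) -> list[Loop]:
    r = cfg.resolutions[res_idx]
    p = cfg.peak_widths[res_idx]
    w = cfg.windows[res_idx]
    fdr = cfg.fdr[res_idx]
    min_d_bins = cfg.min_diagonal_distances[res_idx] // r
    t_q, t_hv, t_donut, t_ll = cfg.enrichment_thresholds
    kernels = _kernels(p, w)
    loops: list[Loop] = []
    for chrom in cmap.chroms():
        B = cmap.balanced_dense(chrom)
        C = cmap.dense(chrom)
        weights = cmap.weights[chrom]
        n = B.shape[0]
        good = cmap.unmasked(chrom)
        valid2d = good[:, None] & good[None, :]
        prof = expected_by_distance(cmap)[chrom]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        E = np.nan_to_num(prof)[d] * valid2d
        Bf = np.nan_to_num(B)
        oe = observed_over_expected(cmap)[chrom]
        exp_raw: dict[str, np.ndarray] = {}
        for name, K in kernels.items():
            sum_b = _conv(Bf, K)
            sum_e = _conv(E, K)
            with np.errstate(divide="ignore", invalid="ignore"):
                e_bal = np.nan_to_num(prof)[d] * sum_b / sum_e
                e_raw = e_bal / (weights[:, None] * weights[None, :])
            exp_raw[name] = e_raw
        e_max = np.maximum.reduce(list(exp_raw.values()))
        iu, ju = np.triu_indices(n, k=min_d_bins + 1)
        cand = (
            valid2d[iu, ju]
            & (C[iu, ju] >= 1)
            & np.isfinite(oe[iu, ju])
            & (oe[iu, ju] > 1)
            & np.isfinite(e_max[iu, ju])
            & (e_max[iu, ju] > 0)
        )
        iu, ju = iu[cand], ju[cand]
        if iu.size == 0:
            continue
        obs = C[iu, ju]
        pv = stats.poisson.sf(obs - 1, e_max[iu, ju])
        qv = stats.false_discovery_control(pv, method="bh")
        sig = qv < fdr
        if not sig.any():
            continue
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[sig], ju[sig]] = True
        qmat = np.ones((n, n))
        qmat[iu, ju] = qv
        labeled, n_clusters = ndimage.label(mask, structure=np.ones((3, 3)))
        for c in range(1, n_clusters + 1):
            pi, pj = np.nonzero(labeled == c)
            wts = C[pi, pj]
            ci = int(round(np.average(pi, weights=wts)))
            cj = int(round(np.average(pj, weights=wts)))
            if not mask[ci, cj]:  # centroid fell between pixels; snap
                k = np.argmin((pi - ci) ** 2 + (pj - cj) ** 2)
                ci, cj = int(pi[k]), int(pj[k])
            o = C[ci, cj]
            if qmat[ci, cj] > t_q:
                continue
            if (o < t_hv * exp_raw["horizontal"][ci, cj]
                    or o < t_hv * exp_raw["vertical"][ci, cj]
                    or o < t_donut * exp_raw["donut"][ci, cj]
                    or o < t_ll * exp_raw["lowerleft"][ci, cj]):
                continue
            loops.append(Loop(
                chrom, ci * r, (ci + 1) * r, cj * r, (cj + 1) * r,
                resolution=r, qvalue=float(qmat[ci, cj]),
                observed=float(o), expected=float(e_max[ci, cj]),
            ))
    return loops


def call_loops(maps: dict[int, ContactMap] | ContactMap,
               cfg: LoopCallConfig | None = None) -> list[Loop]:
    """Call loops at every configured resolution present and merge the lists,
    preferring the finest-resolution call within the merge distance."""
    cfg = cfg or LoopCallConfig()
    if isinstance(maps, ContactMap):
        maps = {maps.grid.resolution: maps}
    order = np.argsort(cfg.resolutions)  # finest first
    merged: list[Loop] = []
    seen_any = False
    for res_idx in order:
        r = cfg.resolutions[res_idx]
        if r not in maps:
            continue
        seen_any = True
        if not maps[r].is_balanced:
            raise ValueError(f"map at {r} bp must be balanced")
        calls = _call_one_resolution(maps[r], int(res_idx), cfg)
        merge_d = cfg.merge_distances[res_idx]
        for lp in calls:
            dup = any(
                lp.chrom == m.chrom
                and abs((lp.start1 + lp.end1) - (m.start1 + m.end1)) // 2 <= merge_d
                and abs((lp.start2 + lp.end2) - (m.start2 + m.end2)) // 2 <= merge_d
                for m in merged
            )
            if not dup:
                merged.append(lp)
    if not seen_any:
        raise ValueError(
            f"no map provided at any configured resolution {cfg.resolutions}")
    return sorted(merged)


def apa(cmap: ContactMap, loops: list[Loop], W: int = 10,
        corner: int = 6) -> ApaResult:
    """Aggregate mean-normalized O/E submatrices centered on loop pixels.

    Loops closer than 2W+1 bins to the diagonal or clipped by the matrix
    edge are skipped. Score = center pixel of the aggregate over the mean of
    the ``corner`` x ``corner`` lower-left (diagonal-proximal) block.
    """
    oe = observed_over_expected(cmap)
    res = cmap.grid.resolution
    size = 2 * W + 1
    subs = []
    for lp in loops:
        M = oe[lp.chrom]
        n = M.shape[0]
        i = ((lp.start1 + lp.end1) // 2) // res
        j = ((lp.start2 + lp.end2) // 2) // res
        if j - i <= size or i - W < 0 or j + W >= n:
            continue
        sub = M[i - W: i + W + 1, j - W: j + W + 1]
        mu = np.nanmean(sub)
        if not np.isfinite(mu) or mu <= 0:
            continue
        subs.append(sub / mu)
    if not subs:
        raise ValueError("no eligible loops for APA")
    agg = np.nanmean(np.stack(subs), axis=0)
    corner_block = agg[-corner:, :corner]
    score = float(agg[W, W] / np.nanmean(corner_block))
    return ApaResult(agg, score, len(subs))


def classify_loops_vs_tads(loops: list[Loop], tads: list[Domain],
                           boundaries: list[Boundary] | None = None,
                           tol: int = 0) -> tuple[list[str], dict[str, float]]:
    """Per-loop class in {within-TAD, cross-TAD, boundary-anchored} plus
    summary fractions. Boundaries default to the TAD edges."""
    if boundaries is None:
        pts: dict[str, set[int]] = {}
        for t in tads:
            pts.setdefault(t.chrom, set()).update((t.start, t.end))
        bpos = {c: sorted(v) for c, v in pts.items()}
    else:
        bpos = {}
        for b in boundaries:
            bpos.setdefault(b.chrom, []).append((b.start + b.end) // 2)
        bpos = {c: sorted(v) for c, v in bpos.items()}
    classes = []
    for lp in loops:
        m1 = (lp.start1 + lp.end1) // 2
        m2 = (lp.start2 + lp.end2) // 2
        host1 = host2 = None
        for t in tads:
            if t.chrom != lp.chrom:
                continue
            if t.start <= m1 < t.end:
                host1 = t
            if t.start <= m2 < t.end:
                host2 = t
        if host1 is not None and host1 == host2:
            classes.append("within-TAD")
            continue
        near_boundary = any(
            lp.start1 - tol <= p <= lp.end1 + tol
            or lp.start2 - tol <= p <= lp.end2 + tol
            for p in bpos.get(lp.chrom, [])
        )
        classes.append("boundary-anchored" if near_boundary else "cross-TAD")
    n = max(len(classes), 1)
    summary = {c: classes.count(c) / n
               for c in ("within-TAD", "cross-TAD", "boundary-anchored")}
    return classes, summary


def match_loops(loops_young: list[Loop], loops_aged: list[Loop], tol: int
                ) -> tuple[list[Loop], list[Loop]]:
    """One-to-one mutual-nearest matching: loops match when both anchor
    midpoints agree within ``tol`` bp. Matched -> stable; unmatched young ->
    lost; unmatched aged -> gained."""
    def mid(lp: Loop) -> tuple[int, int]:
        return (lp.start1 + lp.end1) // 2, (lp.start2 + lp.end2) // 2

    cands = []
    for yi, ly in enumerate(loops_young):
        a1y, a2y = mid(ly)
        for ai, la in enumerate(loops_aged):
            if ly.chrom != la.chrom:
                continue
            a1a, a2a = mid(la)
            d1, d2 = abs(a1y - a1a), abs(a2y - a2a)
            if d1 <= tol and d2 <= tol:
                cands.append((max(d1, d2), a1y, a1a, yi, ai))
    cands.sort()
    used_y: set[int] = set()
    used_a: set[int] = set()
    for _, _, _, yi, ai in cands:
        if yi in used_y or ai in used_a:
            continue
        used_y.add(yi)
        used_a.add(ai)
    young = [Loop(l.chrom, l.start1, l.end1, l.start2, l.end2, l.resolution,
                  l.qvalue, l.observed, l.expected,
                  "stable" if i in used_y else "lost")
             for i, l in enumerate(loops_young)]
    aged = [Loop(l.chrom, l.start1, l.end1, l.start2, l.end2, l.resolution,
                 l.qvalue, l.observed, l.expected,
                 "stable" if i in used_a else "gained")
            for i, l in enumerate(loops_aged)]
    return young, aged
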