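"""TAD boundaries, domains, rearrangements, connectivity and disorder.

Boundaries come from a multi-window TAD separation score: for each bin the
mean balanced value of the "diamond" submatrix spanning it is z-scored per
window size and averaged across windows; significant local minima are
boundaries and consecutive boundaries delimit domains. Cross-condition
comparisons classify boundaries as stable/lost/gained and domains as
stable/shift/split/merge/indeterminate. Intra-TAD connectivity relates mean
per-pixel intra-TAD counts to contacts with flanking TADs, and the degree
of disorder measures how dispersed a TAD's strongest contacts are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .balance import observed_over_expected
from .config import DoDConfig, TadCallConfig
from .model import Boundary, ContactMap, Domain, SignalTrack

log = logging.getLogger(__name__)

__all__ = [
    "SeparationTrack",
    "RearrangementReport",
    "ConnectivityRecord",
    "tad_separation_score",
    "find_boundaries",
    "assemble_domains",
    "match_boundaries",
    "classify_rearrangements",
    "intra_tad_connectivity",
    "degree_of_disorder",
    "distance_to_nearest",
]


@dataclass
class SeparationTrack:
    score: SignalTrack
    pvalue: SignalTrack


@dataclass
class RearrangementReport:
    """Per-TAD rearrangement classes and per-boundary stability labels."""

    young: list[Domain]
    aged: list[Domain]
    class_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ConnectivityRecord:
    tad: Domain
    intra_mean: float
    flank_left: float
    flank_right: float
    connectivity: float   # NaN when the flanking denominator is 0
    dod: float = float("nan")


def _diamond_pixels(B: np.ndarray, i: int, w: int) -> np.ndarray:
    """Balanced values of {(a, b): i-w <= a < i <= b < i+w}, clipped."""
    n = B.shape[0]
    a0, a1 = max(i - w, 0), i
    b0, b1 = i, min(i + w, n)
    if a0 >= a1 or b0 >= b1:
        return np.empty(0)
    block = B[a0:a1, b0:b1].ravel()
    return block[np.isfinite(block)]


def tad_separation_score(cmap: ContactMap,
                         window_sizes: tuple[int, ...] = (4, 6, 8, 10)
                         ) -> SeparationTrack:
    """Multi-window z-scored diamond means plus a rank-sum boundary p-value.

    The p-value compares each bin's pooled diamond pixels against the pooled
    diamonds at the bins one window away on either side (one-sided: lower
    contact density at a boundary).
    """
    if not cmap.is_balanced:
        raise ValueError("map must be balanced")
    scores: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    for chrom in cmap.chroms():
        B = cmap.balanced_dense(chrom)
        n = B.shape[0]
        if max(window_sizes) >= n:
            raise ValueError(f"window {max(window_sizes)} exceeds {chrom} size {n}")
        good = cmap.unmasked(chrom)
        zsum = np.zeros(n)
        nz = np.zeros(n)
        diamonds: list[list[np.ndarray]] = [[] for _ in range(n)]
        for w in window_sizes:
            d = np.full(n, np.nan)
            for i in range(n):
                px = _diamond_pixels(B, i, w)
                diamonds[i].append(px)
                if px.size:
                    d[i] = px.mean()
            mu, sd = np.nanmean(d[good]), np.nanstd(d[good])
            # zero spread (e.g. uniform matrix): every bin is exactly average
            z = (d - mu) / sd if sd > 0 else np.where(np.isfinite(d), 0.0, np.nan)
            ok = np.isfinite(z)
            zsum[ok] += z[ok]
            nz[ok] += 1
        with np.errstate(invalid="ignore"):
            score = zsum / nz
        score[~good] = np.nan
        p = np.full(n, np.nan)
        for i in range(n):
            if not good[i]:
                continue
            here = np.concatenate(diamonds[i]) if diamonds[i] else np.empty(0)
            flank_parts = []
            for wi, w in enumerate(window_sizes):
                for j in (i - w, i + w):
                    if 0 <= j < n:
                        flank_parts.append(diamonds[j][wi])
            flank = np.concatenate(flank_parts) if flank_parts else np.empty(0)
            if here.size >= 3 and flank.size >= 3 and (
                    np.ptp(np.concatenate([here, flank])) > 0):
                p[i] = stats.mannwhitneyu(here, flank, alternative="less").pvalue
            else:
                p[i] = 1.0
        scores[chrom] = score
        pvals[chrom] = p
    grid = cmap.grid
    return SeparationTrack(SignalTrack(grid, scores), SignalTrack(grid, pvals))


def find_boundaries(track: SeparationTrack, fdr: float = 0.01,
                    delta: float = 0.01) -> list[Boundary]:
    """Significant local score minima: BH-adjusted rank-sum p < fdr and a
    score drop versus the flanking local maxima exceeding ``delta``."""
    grid = track.score.grid
    res = grid.resolution
    cand: list[tuple[str, int, float, float]] = []
    for chrom in grid.chroms:
        if chrom not in track.score.values:
            continue
        s = track.score.values[chrom]
        p = track.pvalue.values[chrom]
        n = len(s)
        for i in range(1, n - 1):
            if not np.isfinite(s[i]):
                continue
            left = s[i - 1] if np.isfinite(s[i - 1]) else np.inf
            right = s[i + 1] if np.isfinite(s[i + 1]) else np.inf
            if not (s[i] < left and s[i] <= right):
                continue
            # flanking local maxima
            lmax = -np.inf
            for j in range(i - 1, -1, -1):
                if np.isfinite(s[j]):
                    lmax = max(lmax, s[j])
                    if j < i - 1 and s[j] < lmax:
                        break
            rmax = -np.inf
            for j in range(i + 1, n):
                if np.isfinite(s[j]):
                    rmax = max(rmax, s[j])
                    if j > i + 1 and s[j] < rmax:
                        break
            drop = min(lmax, rmax) - s[i]
            if drop > delta:
                cand.append((chrom, i, s[i], p[i]))
    if not cand:
        log.info("no boundary candidates found")
        return []
    pv = np.array([c[3] for c in cand])
    qv = stats.false_discovery_control(pv, method="bh")
    out = [
        Boundary(chrom, i * res, (i + 1) * res, score=sc, pvalue=q)
        for (chrom, i, sc, _), q in zip(cand, qv)
        if q < fdr
    ]
    return sorted(out)


def assemble_domains(boundaries: list[Boundary], grid,
                     min_domain_bins: int = 3, condition: str = "") -> list[Domain]:
    """Tile each chromosome between consecutive boundaries (and chromosome
    ends); domains shorter than ``min_domain_bins`` are dropped."""
    res = grid.resolution
    domains: list[Domain] = []
    by_chrom: dict[str, list[int]] = {}
    for b in boundaries:
        by_chrom.setdefault(b.chrom, []).append(b.start)
    for chrom in grid.chroms:
        cuts = sorted(by_chrom.get(chrom, []))
        if not cuts:
            continue
        edges = [0] + cuts + [grid.n_bins(chrom) * res]
        for s, e in zip(edges, edges[1:]):
            if (e - s) >= min_domain_bins * res:
                domains.append(Domain(chrom, s, e, condition=condition))
    return domains


def match_boundaries(b_young: list[Boundary], b_aged: list[Boundary],
                     tol_bins: int, resolution: int
                     ) -> tuple[list[Boundary], list[Boundary]]:
    """Greedy mutual-nearest one-to-one matching within ``tol_bins``.

    Matched boundaries are labeled stable; unmatched young are lost and
    unmatched aged gained. Distance ties resolve to the leftmost boundary.
    """
    tol = tol_bins * resolution
    cands = []
    for yi, by in enumerate(b_young):
        for ai, ba in enumerate(b_aged):
            if by.chrom != ba.chrom:
                continue
            d = abs(by.start - ba.start)
            if d <= tol:
                cands.append((d, by.start, ba.start, yi, ai))
    cands.sort()
    used_y: set[int] = set()
    used_a: set[int] = set()
    for d, _, _, yi, ai in cands:
        if yi in used_y or ai in used_a:
            continue
        used_y.add(yi)
        used_a.add(ai)
    young_out = [
        Boundary(b.chrom, b.start, b.end, b.score, b.pvalue,
                 "stable" if i in used_y else "lost")
        for i, b in enumerate(b_young)
    ]
    aged_out = [
        Boundary(b.chrom, b.start, b.end, b.score, b.pvalue,
                 "stable" if i in used_a else "gained")
        for i, b in enumerate(b_aged)
    ]
    return young_out, aged_out


def _check_non_overlapping(tads: list[Domain]) -> None:
    srt = sorted(tads)
    for a, b in zip(srt, srt[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping TADs {a} / {b}")


def classify_rearrangements(tads_young: list[Domain], tads_aged: list[Domain],
                            tol_bins: int, resolution: int
                            ) -> RearrangementReport:
    """Classify connected components of the young/aged TAD overlap graph.

    1<->1 within tolerance -> stable; 1<->1 beyond -> shift; 1<->many ->
    split; many<->1 -> merge; many<->many -> indeterminate. Unpaired TADs
    are indeterminate.
    """
    _check_non_overlapping(tads_young)
    _check_non_overlapping(tads_aged)
    tol = tol_bins * resolution
    ys = sorted(tads_young)
    as_ = sorted(tads_aged)
    edges: dict[int, set[int]] = {i: set() for i in range(len(ys))}
    redges: dict[int, set[int]] = {j: set() for j in range(len(as_))}
    for i, ty in enumerate(ys):
        for j, ta in enumerate(as_):
            if ty.chrom == ta.chrom and min(ty.end, ta.end) > max(ty.start, ta.start):
                edges[i].add(j)
                redges[j].add(i)
    seen_y: set[int] = set()
    class_y = {}
    class_a = {}
    for i in range(len(ys)):
        if i in seen_y:
            continue
        comp_y, comp_a = {i}, set()
        stack = [("y", i)]
        while stack:
            side, k = stack.pop()
            if side == "y":
                for j in edges[k]:
                    if j not in comp_a:
                        comp_a.add(j)
                        stack.append(("a", j))
            else:
                for j in redges[k]:
                    if j not in comp_y:
                        comp_y.add(j)
                        stack.append(("y", j))
        seen_y |= comp_y
        if len(comp_y) == 1 and len(comp_a) == 1:
            ty, ta = ys[next(iter(comp_y))], as_[next(iter(comp_a))]
            cls = ("stable"
                   if abs(ty.start - ta.start) <= tol and abs(ty.end - ta.end) <= tol
                   else "shift")
        elif len(comp_y) == 1 and len(comp_a) > 1:
            cls = "split"
        elif len(comp_y) > 1 and len(comp_a) == 1:
            cls = "merge"
        elif len(comp_a) == 0:
            cls = "indeterminate"
        else:
            cls = "indeterminate"
        for k in comp_y:
            class_y[k] = cls
        for k in comp_a:
            class_a[k] = cls
    for j in range(len(as_)):
        class_a.setdefault(j, "indeterminate")
    young = [Domain(t.chrom, t.start, t.end, t.condition or "young", class_y[i])
             for i, t in enumerate(ys)]
    aged = [Domain(t.chrom, t.start, t.end, t.condition or "aged", class_a[j])
            for j, t in enumerate(as_)]
    counts: dict[str, int] = {}
    for d in young:
        counts[d.rearrangement] = counts.get(d.rearrangement, 0) + 1
    return RearrangementReport(young, aged, counts)


def intra_tad_connectivity(cmap: ContactMap, tads: list[Domain],
                           denominator: str = "sum") -> list[ConnectivityRecord]:
    """Mean raw count per intra-TAD pixel over contacts with flanking TADs.

    Numerator: sum of raw counts over pixels with both bins in the TAD
    (upper triangle including the diagonal) divided by the pixel count.
    Denominator: total raw counts (or per-pixel mean when
    ``denominator="mean"``) over pixels linking the TAD to its immediate
    neighbors. Edge TADs use their single flank; a zero denominator flags
    the record as missing (NaN).
    """
    res = cmap.grid.resolution
    out: list[ConnectivityRecord] = []
    srt = sorted(tads)
    for idx, t in enumerate(srt):
        C = cmap.dense(t.chrom)
        s, e = t.start // res, -(-t.end // res)
        k = e - s
        n_intra = k * (k + 1) // 2
        intra_sum = np.triu(C[s:e, s:e]).sum()
        numer = intra_sum / n_intra
        left = srt[idx - 1] if idx > 0 and srt[idx - 1].chrom == t.chrom else None
        right = (srt[idx + 1]
                 if idx + 1 < len(srt) and srt[idx + 1].chrom == t.chrom else None)
        fl = fr = 0.0
        n_flank = 0
        if left is not None:
            ls, le = left.start // res, -(-left.end // res)
            fl = C[ls:le, s:e].sum()
            n_flank += (le - ls) * k
        if right is not None:
            rs, re = right.start // res, -(-right.end // res)
            fr = C[s:e, rs:re].sum()
            n_flank += (re - rs) * k
        denom = fl + fr
        if denominator == "mean" and n_flank > 0:
            denom = denom / n_flank
        conn = numer / denom if denom > 0 else float("nan")
        out.append(ConnectivityRecord(t, numer, fl, fr, conn))
    return out


def distance_to_nearest(boundaries: list[Boundary],
                        features: list[Domain | Boundary]) -> np.ndarray:
    """Distance (bp) from each boundary midpoint to the nearest feature
    midpoint on the same chromosome; inf where no feature exists."""
    by_chrom: dict[str, list[int]] = {}
    for f in features:
        mid = (f.start + f.end) // 2
        by_chrom.setdefault(f.chrom, []).append(mid)
    by_chrom = {c: np.array(sorted(v)) for c, v in by_chrom.items()}
    out = np.full(len(boundaries), np.inf)
    for i, b in enumerate(boundaries):
        mids = by_chrom.get(b.chrom)
        if mids is None or mids.size == 0:
            continue
        out[i] = np.abs(mids - b.midpoint).min()
    return out


def degree_of_disorder(cmap: ContactMap, tad: Domain,
                       dod: DoDConfig | None = None) -> float:
    """Mean k-nearest-neighbor distance among a TAD's significant contacts.

    Significant contacts are the off-diagonal upper-triangle pixels inside
    the TAD whose O/E is at or above the ``top`` quantile of the TAD's
    pixels. For each such pixel the mean Euclidean distance (bin units) to
    its k nearest significant peers is taken; the DoD is the mean over
    pixels. NaN when fewer than k+1 significant pixels exist. Of the
    configured parameters only ``k`` and ``top`` drive the statistic; ww,
    pw, ratio and gap are accepted for interface parity and logged unused.
    """
    dod = dod or DoDConfig()
    log.debug("DoD parameters ww=%s pw=%s ratio=%s gap=%s accepted but unused",
              dod.ww, dod.pw, dod.ratio, dod.gap)
    oe = observed_over_expected(cmap)[tad.chrom]
    res = cmap.grid.resolution
    s, e = tad.start // res, -(-tad.end // res)
    sub = oe[s:e, s:e]
    iu, ju = np.triu_indices(e - s, k=1)
    vals = sub[iu, ju]
    ok = np.isfinite(vals)
    iu, ju, vals = iu[ok], ju[ok], vals[ok]
    if vals.size == 0:
        return float("nan")
    thresh = np.quantile(vals, dod.top)
    sig = vals >= thresh
    pts = np.column_stack([iu[sig], ju[sig]]).astype(float)
    if len(pts) < dod.k + 1:
        return float("nan")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    knn = np.sort(dist, axis=1)[:, : dod.k]
    return float(knn.mean())
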