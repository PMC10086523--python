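"""A/B compartment calling, switching, and saddle/compartment strength.

Compartments are the sign pattern of the leading eigenvector (largest
algebraic eigenvalue) of the Pearson correlation matrix of O/E rows,
computed per chromosome at 100 kb. The sign is oriented so bins with
positive eigenvector values have the higher mean GC content (A compartment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .balance import observed_over_expected
from .model import ContactMap, SignalTrack

log = logging.getLogger(__name__)

__all__ = ["CompartmentCall", "SaddleResult", "call_compartments",
           "compartment_switches", "saddle", "saddle_from_oe"]

MIN_UNMASKED_BINS = 10


@dataclass
class CompartmentCall:
    """Signed eigenvector (E1) and A/B label per bin; NaN/None where masked."""

    e1: SignalTrack
    labels: dict[str, np.ndarray]  # "A" / "B" / "" per bin


@dataclass
class SaddleResult:
    matrix: np.ndarray          # q x q mean O/E over E1-quantile pairs
    strength: float


def call_compartments(cmap: ContactMap, gc: SignalTrack) -> CompartmentCall:
    """Leading correlation-matrix eigenvector per chromosome, GC-oriented."""
    oe = observed_over_expected(cmap)
    e1_values: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom in cmap.chroms():
        n = cmap.grid.n_bins(chrom)
        e1 = np.full(n, np.nan)
        lab = np.full(n, "", dtype=object)
        good = cmap.unmasked(chrom)
        if good.sum() < MIN_UNMASKED_BINS:
            log.warning("chromosome %s has <%d unmasked bins; skipped",
                        chrom, MIN_UNMASKED_BINS)
            e1_values[chrom] = e1
            labels[chrom] = lab.astype(str)
            continue
        sub = oe[chrom][np.ix_(good, good)]
        sub = np.nan_to_num(sub, nan=1.0)  # isolated missing pixels -> neutral
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        evals, evecs = np.linalg.eigh(corr)
        vec = evecs[:, -1]  # largest algebraic eigenvalue
        gc_vals = gc.values[chrom][good]
        pos, neg = vec > 0, vec < 0
        if pos.any() and neg.any():
            if np.nanmean(gc_vals[pos]) < np.nanmean(gc_vals[neg]):
                vec = -vec
        e1[good] = vec
        lab[good] = np.where(vec > 0, "A", np.where(vec < 0, "B", ""))
        e1_values[chrom] = e1
        labels[chrom] = lab.astype(str)
    return CompartmentCall(SignalTrack(cmap.grid, e1_values), labels)


def compartment_switches(call_y: CompartmentCall, call_a: CompartmentCall
                         ) -> dict[str, float]:
    """Fractions of shared labeled bins in {A->A, A->B, B->A, B->B}.

    ``switch`` is the A->B + B->A share. Bins missing in either call are
    excluded from the denominator.
    """
    chroms_y = set(call_y.labels)
    if chroms_y != set(call_a.labels):
        raise ValueError("compartment calls cover different chromosomes")
    counts = {"A->A": 0, "A->B": 0, "B->A": 0, "B->B": 0}
    for chrom in sorted(chroms_y):
        ly, la = call_y.labels[chrom], call_a.labels[chrom]
        if len(ly) != len(la):
            raise ValueError(f"grid mismatch on {chrom}")
        keep = (ly != "") & (la != "")
        for a, b in zip(ly[keep], la[keep]):
            counts[f"{a}->{b}"] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no bins labeled in both calls")
    out = {k: v / total for k, v in counts.items()}
    out["switch"] = out["A->B"] + out["B->A"]
    return out


def saddle_from_oe(oe: np.ndarray, e1: np.ndarray, n_quantiles: int = 50,
                   corner_fraction: float = 0.2) -> SaddleResult:
    """Saddle statistic on a given O/E matrix and eigenvector track.

    Exposed separately so the strength arithmetic can be driven with an
    analytic O/E (e.g. an exact two-block pattern) as well as with the O/E
    derived from a balanced map.
    """
    if n_quantiles < 5:
        raise ValueError("need at least 5 quantiles")
    sums = np.zeros((n_quantiles, n_quantiles))
    cnts = np.zeros((n_quantiles, n_quantiles))
    _saddle_accumulate(oe, e1, n_quantiles, sums, cnts)
    return _saddle_finish(sums, cnts, n_quantiles, corner_fraction)


def _saddle_accumulate(oe: np.ndarray, e1: np.ndarray, n_quantiles: int,
                       sums: np.ndarray, cnts: np.ndarray) -> None:
    good = np.isfinite(e1)
    m = int(good.sum())
    if m < n_quantiles:
        return
    ranks = np.argsort(np.argsort(e1[good]))
    q = np.minimum((ranks * n_quantiles) // m, n_quantiles - 1)
    sub = oe[np.ix_(good, good)]
    valid = np.isfinite(sub)
    sub = np.nan_to_num(sub)
    for a in range(n_quantiles):
        ia = q == a
        for b in range(a, n_quantiles):
            ib = q == b
            block = sub[np.ix_(ia, ib)]
            vb = valid[np.ix_(ia, ib)]
            s, c = block[vb].sum(), vb.sum()
            sums[a, b] += s
            cnts[a, b] += c
            if a != b:
                sums[b, a] += s
                cnts[b, a] += c


def _saddle_finish(sums: np.ndarray, cnts: np.ndarray, n_quantiles: int,
                   corner_fraction: float) -> SaddleResult:
    with np.errstate(invalid="ignore"):
        mat = sums / cnts
    k = max(1, int(round(corner_fraction * n_quantiles)))
    bb = np.nanmean(mat[:k, :k])
    aa = np.nanmean(mat[-k:, -k:])
    ab = np.nanmean(mat[:k, -k:])
    ba = np.nanmean(mat[-k:, :k])
    return SaddleResult(mat, float((aa + bb) / (ab + ba)))


def saddle(cmap: ContactMap, call: CompartmentCall, n_quantiles: int = 50,
           corner_fraction: float = 0.2) -> SaddleResult:
    """Mean O/E over E1-quantile pairs and the compartment strength.

    Bins are ranked by E1 (ascending: strongest B first) into equal-count
    quantiles; cell (a, b) is the mean O/E over pixel pairs drawn from
    quantiles a and b. Strength = (mean BB corner + mean AA corner) /
    (2 * mean of the two AB corners), corners being the extreme
    ``corner_fraction`` share of quantiles.
    """
    if n_quantiles < 5:
        raise ValueError("need at least 5 quantiles")
    oe = observed_over_expected(cmap)
    sums = np.zeros((n_quantiles, n_quantiles))
    cnts = np.zeros((n_quantiles, n_quantiles))
    for chrom in cmap.chroms():
        e1 = call.e1.values[chrom].copy()
        e1[~cmap.unmasked(chrom)] = np.nan
        _saddle_accumulate(oe[chrom], e1, n_quantiles, sums, cnts)
    return _saddle_finish(sums, cnts, n_quantiles, corner_fraction)
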