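"""Two-condition synthetic data with planted ground truth.

The Hi-C generator draws Poisson counts around a multiplicative expectation:
power-law distance decay times compartment, TAD and focal-loop enrichment
factors. The multiome generator plants latent-factor peak-gene linkages and
co-accessibility communities in sparse binarized accessibility and count
expression matrices. Every generator emits a TruthSet sufficient to
recompute its expectation, so downstream stages have recovery oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import (
    BinGrid,
    CellMatrices,
    ContactMap,
    Domain,
    GenomeAssembly,
    Interval,
    SignalTrack,
    SitePair,
)

log = logging.getLogger(__name__)

__all__ = [
    "HiCSimParams",
    "MultiomeSimParams",
    "PlantedLinkage",
    "TruthSet",
    "default_hic_params",
    "simulate_contact_map",
    "simulate_gc_track",
    "simulate_multiome",
    "simulate_site_pairs",
    "simulate_indifferent_pairs",
]


@dataclass
class HiCSimParams:
    """Parameters of the contact-map generator (single synthetic chromosome).

    Expected count at pixel (i, j):
    ``Z * (1+|i-j|)**(-alpha) * c_comp^[same compartment] * c_tad^[same TAD]
    * c_loop^[within w_peak of a planted loop pixel]`` with Z set so the
    expected total over the upper triangle equals ``depth``.
    """

    n_bins: int = 500
    resolution: int = 40_000
    chrom: str = "chrS"
    alpha: float = 1.0
    block_len: int = 50          # compartment block length, bins
    c_comp: float = 1.0
    tads: tuple[tuple[int, int], ...] = ()  # half-open bin spans
    c_tad: float = 1.0
    loops: tuple[tuple[int, int], ...] = ()  # (i, j) bin pixels, i < j
    c_loop: float = 1.0
    w_peak: int = 1
    depth: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c_comp, self.c_tad, self.c_loop) < 1:
            raise ValueError("enrichment factors must be >= 1")
        spans = sorted(self.tads)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("TADs must be non-overlapping")
        for i, j in self.loops:
            if not 0 <= i < j < self.n_bins:
                raise ValueError("loop pixels must satisfy 0 <= i < j < n_bins")

    @property
    def grid(self) -> BinGrid:
        asm = GenomeAssembly((self.chrom,), (self.n_bins * self.resolution,))
        return BinGrid(asm, self.resolution)


@dataclass
class PlantedLinkage:
    peak: int
    gene: int
    rho: float       # latent correlation between peak and gene signal
    condition: str = "shared"  # "shared" or a condition label

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")


@dataclass
class MultiomeSimParams:
    """Parameters of the two-condition single-cell multiome generator.

    Cells occupy a low-dimensional latent state; each planted linkage's
    shared factor z is one state coordinate (orthogonal regulatory
    programs), so k-nearest-neighbor aggregation of similar cells averages
    away per-cell sampling noise while preserving the programs — the
    structure aggregate-based correlation analysis assumes.
    """

    n_cells: int = 500           # per condition
    n_peaks: int = 60
    n_genes: int = 20
    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    peak_width: int = 500
    state_dim: int = 5           # latent programs shared by linkages
    linkages: tuple[PlantedLinkage, ...] = ()
    ccan_communities: tuple[tuple[int, ...], ...] = ()  # peak-index sets
    community_strength: float = 1.5  # logit loading of community factor
    background_loading: float = 1.0  # program loading of unlinked peaks
    base_accessibility: float = 0.3
    base_expression: float = 5.0     # mean counts for unlinked genes
    signal_scale: float = 2.5        # latent-to-logit / latent-to-lograte scale
    conditions: tuple[str, str] = ("young", "aged")
    noiseless: bool = False          # emit latents directly (limit-case tests)
    seed: int = 0


@dataclass
class TruthSet:
    """Planted ground truth emitted by the generators."""

    compartment_labels: Optional[np.ndarray] = None   # "A"/"B" per bin
    tads: tuple[tuple[int, int], ...] = ()
    boundaries: tuple[int, ...] = ()
    loop_pixels: tuple[tuple[int, int], ...] = ()
    lam: Optional[np.ndarray] = None                  # expected counts (dense)
    linkages: tuple[PlantedLinkage, ...] = ()
    ccan_communities: tuple[tuple[int, ...], ...] = ()
    latent: dict = field(default_factory=dict)        # per-condition latents


def default_hic_params(
    seed: int = 0,
    n_bins: int = 500,
    depth: float = 1e6,
    c_comp: float = 1.5,
    c_tad: float = 3.0,
    c_loop: float = 1.0,
    n_blocks: int = 10,
    n_tads: int = 10,
    loops: tuple[tuple[int, int], ...] = (),
) -> HiCSimParams:
    """Study-condition defaults: 20 Mb chromosome at 40 kb (500 bins),
    10 alternating compartment blocks and 10 equal TADs."""
    block = n_bins // n_blocks
    tad = n_bins // n_tads
    tads = tuple((k * tad, (k + 1) * tad) for k in range(n_tads))
    return HiCSimParams(
        n_bins=n_bins,
        block_len=block,
        c_comp=c_comp,
        tads=tads,
        c_tad=c_tad,
        loops=loops,
        c_loop=c_loop,
        depth=depth,
        seed=seed,
    )


def _compartment_labels(n_bins: int, block_len: int) -> np.ndarray:
    blocks = (np.arange(n_bins) // block_len) % 2
    return np.where(blocks == 0, "A", "B")


def expected_matrix(params: HiCSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense symmetric expectation lambda and the compartment label vector."""
    n = params.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = (1.0 + d) ** (-params.alpha)
    labels = _compartment_labels(n, params.block_len)
    if params.c_comp > 1:
        same = labels[:, None] == labels[None, :]
        lam = lam * np.where(same, params.c_comp, 1.0)
    if params.c_tad > 1 and params.tads:
        tad_id = np.full(n, -1)
        for t, (s, e) in enumerate(params.tads):
            tad_id[s:e] = t
        same_tad = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
        lam = lam * np.where(same_tad, params.c_tad, 1.0)
    if params.c_loop > 1:
        half = params.w_peak // 2
        for i, j in params.loops:
            lam[
                max(i - half, 0): i + half + 1,
                max(j - half, 0): j + half + 1,
            ] *= params.c_loop
            lam[
                max(j - half, 0): j + half + 1,
                max(i - half, 0): i + half + 1,
            ] *= params.c_loop
    upper_total = np.triu(lam).sum()
    Z = params.depth / upper_total
    return lam * Z, labels


def simulate_contact_map(params: HiCSimParams) -> tuple[ContactMap, TruthSet]:
    """Draw a Poisson contact map around the multiplicative expectation."""
    lam, labels = expected_matrix(params)
    n = params.n_bins
    if n > 1 and np.diagonal(lam, 1).mean() < 1:
        log.warning("depth %.3g leaves <1 expected count on the first diagonal",
                    params.depth)
    rng = np.random.default_rng(params.seed)
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(lam[iu, ju])
    mat = sp.coo_matrix((counts, (iu, ju)), shape=(n, n)).tocsr()
    cmap = ContactMap(params.grid, {params.chrom: mat})
    edges = {s for s, _ in params.tads} | {e for _, e in params.tads}
    boundaries = tuple(sorted(b for b in edges if 0 < b < n))  # interior only
    truth = TruthSet(
        compartment_labels=labels,
        tads=params.tads,
        boundaries=boundaries,
        loop_pixels=params.loops,
        lam=lam,
    )
    return cmap, truth


def simulate_gc_track(params: HiCSimParams, gc_contrast: float = 0.05,
                      noise: float = 0.005) -> SignalTrack:
    """GC fraction per bin, elevated in planted A-compartment bins."""
    labels = _compartment_labels(params.n_bins, params.block_len)
    rng = np.random.default_rng(params.seed + 1)
    gc = 0.42 + gc_contrast * (labels == "A") + rng.normal(0, noise, params.n_bins)
    return SignalTrack(params.grid, {params.chrom: gc})


# -- multiome ----------------------------------------------------------------

def _place_peaks(params: MultiomeSimParams, rng) -> pd.DataFrame:
    gap = params.chrom_length // (params.n_peaks + 1)
    starts = (np.arange(1, params.n_peaks + 1) * gap
              + rng.integers(-gap // 4, gap // 4, params.n_peaks))
    starts = np.clip(starts, 0, params.chrom_length - params.peak_width)
    return pd.DataFrame({
        "chrom": params.chrom,
        "start": starts,
        "end": starts + params.peak_width,
        "name": [f"peak_{k}" for k in range(params.n_peaks)],
    })


def _place_genes(params: MultiomeSimParams, peaks: pd.DataFrame, rng) -> pd.DataFrame:
    """Genes get TSSs near a subset of peaks so planted links are cis-local."""
    tss = np.empty(params.n_genes, dtype=int)
    linked = {pl.gene: pl.peak for pl in params.linkages}
    for g in range(params.n_genes):
        if g in linked:
            center = int(peaks.loc[linked[g], ["start", "end"]].mean())
            tss[g] = np.clip(center + int(rng.integers(5_000, 50_000)),
                             0, params.chrom_length - 1)
        else:
            tss[g] = rng.integers(0, params.chrom_length)
    return pd.DataFrame({
        "name": [f"gene_{g}" for g in range(params.n_genes)],
        "chrom": params.chrom,
        "tss": tss,
        "strand": rng.choice(["+", "-"], params.n_genes),
    })


def simulate_multiome(params: MultiomeSimParams) -> tuple[CellMatrices, TruthSet]:
    """Two-condition cell x peak / cell x gene matrices with planted links.

    Cells draw a latent state s ~ N(0, I). Planted linkage l uses the state
    coordinate ``l mod state_dim`` as its shared program z; the peak's
    accessibility latent and the gene's expression latent are each
    ``sqrt(rho) * z + sqrt(1-rho) * noise`` with iid per-cell noise, giving
    latent correlation rho. Accessibility is Bernoulli through a logit;
    expression is Poisson through a log rate. Condition-specific links load
    only in their condition; the other condition keeps pure noise. CCAN
    community m loads its member peaks jointly on an extra state coordinate.
    """
    rng = np.random.default_rng(params.seed)
    peaks = _place_peaks(params, rng)
    genes = _place_genes(params, peaks, rng)
    n_cond = params.n_cells
    total = 2 * n_cond
    conditions = np.repeat(list(params.conditions), n_cond)

    n_state = params.state_dim + len(params.ccan_communities)
    state = rng.normal(0, 1, (total, n_state))
    peak_latent = rng.normal(0, 1, (total, params.n_peaks))
    gene_latent = rng.normal(0, 1, (total, params.n_genes))
    latent_store: dict[str, np.ndarray] = {"state": state}
    for li, pl in enumerate(params.linkages):
        z = state[:, li % params.state_dim]
        if pl.condition != "shared":
            mask = conditions == pl.condition
        else:
            mask = np.ones(total, dtype=bool)
        a, b = np.sqrt(pl.rho), np.sqrt(1 - pl.rho)
        peak_latent[mask, pl.peak] = a * z[mask] + b * peak_latent[mask, pl.peak]
        gene_latent[mask, pl.gene] = a * z[mask] + b * gene_latent[mask, pl.gene]
        latent_store[f"link_{li}"] = z
    for ci, comm in enumerate(params.ccan_communities):
        g = state[:, params.state_dim + ci]
        for p in comm:
            peak_latent[:, p] = (params.community_strength * g
                                 + peak_latent[:, p]) / np.sqrt(
                                     1 + params.community_strength ** 2)
        latent_store[f"community_{ci}"] = g
    # peaks outside planted links/communities still ride the cell-state
    # programs (global accessibility structure), as real scATAC peaks do
    if params.background_loading > 0:
        touched = ({pl.peak for pl in params.linkages}
                   | {p for comm in params.ccan_communities for p in comm})
        bg = params.background_loading
        for p in range(params.n_peaks):
            if p in touched:
                continue
            z = state[:, rng.integers(params.state_dim)]
            peak_latent[:, p] = (bg * z + peak_latent[:, p]) / np.sqrt(1 + bg ** 2)

    latent_store["peak_latent"] = peak_latent
    latent_store["gene_latent"] = gene_latent

    if params.noiseless:
        acc = sp.csr_matrix(peak_latent)
        expr = sp.csr_matrix(gene_latent)
    else:
        logit0 = np.log(params.base_accessibility / (1 - params.base_accessibility))
        p_open = 1.0 / (1.0 + np.exp(-(logit0 + params.signal_scale * peak_latent)))
        acc = sp.csr_matrix((rng.random((total, params.n_peaks)) < p_open)
                            .astype(np.int8))
        rate = params.base_expression * np.exp(
            params.signal_scale * 0.5 * gene_latent)
        expr = sp.csr_matrix(rng.poisson(rate))
        # conditional means E[data|latent]: deterministic transforms of the
        # latents, stored so recovery tests have a sampling-free oracle
        latent_store["peak_prob"] = p_open
        latent_store["gene_rate"] = rate

    cells = CellMatrices(
        acc, expr, peaks, genes,
        cell_ids=[f"cell_{i}" for i in range(total)],
        conditions=conditions,
    )
    truth = TruthSet(
        linkages=params.linkages,
        ccan_communities=params.ccan_communities,
        latent=latent_store,
    )
    return cells, truth


# -- site pairs --------------------------------------------------------------

def _uniform_score(rng) -> float:
    return float(rng.uniform(0.1, 0.6))


def simulate_community_pairs(
    n_communities: int = 4,
    sites_per_community: int = 6,
    n_background_sites: int = 20,
    within_mean: float = 0.4,
    background_mean: float = 0.02,
    noise_sd: float = 0.03,
    chrom: str = "chrS",
    site_spacing: int = 10_000,
    seed: int = 0,
) -> tuple[list[SitePair], tuple[tuple[Interval, ...], ...]]:
    """Scored site pairs with planted co-accessibility communities.

    Within-community pairs score around ``within_mean``; all other pairs
    (community-background, background-background and cross-community) score
    around ``background_mean``. Returns the pairs and the planted community
    member tuples. Scores are clipped to [-1, 1].
    """
    rng = np.random.default_rng(seed)
    n_sites = n_communities * sites_per_community + n_background_sites
    sites = [Interval(chrom, k * site_spacing, k * site_spacing + 500)
             for k in range(n_sites)]
    member_of = np.full(n_sites, -1)
    order = rng.permutation(n_sites)
    for c in range(n_communities):
        for m in order[c * sites_per_community:(c + 1) * sites_per_community]:
            member_of[m] = c
    pairs = []
    for a in range(n_sites):
        for b in range(a + 1, n_sites):
            same = member_of[a] >= 0 and member_of[a] == member_of[b]
            mu = within_mean if same else background_mean
            score = float(np.clip(mu + rng.normal(0, noise_sd), -1, 1))
            pairs.append(SitePair(sites[a], sites[b], score))
    communities = tuple(
        tuple(sites[k] for k in np.flatnonzero(member_of == c))
        for c in range(n_communities)
    )
    return pairs, communities


def simulate_site_pairs(
    tads: Sequence[Domain],
    n_within: int,
    n_between: int,
    score_dist: Optional[Callable] = None,
    seed: int = 0,
    site_width: int = 500,
    min_distance: int = 1_000,
) -> list[SitePair]:
    """Plant exactly ``n_within`` within-TAD and ``n_between`` straddling
    pairs; distances spread over the 25-kb bins used downstream."""
    rng = np.random.default_rng(seed)
    score = score_dist or _uniform_score
    tads = sorted(tads, key=lambda t: (t.chrom, t.start))
    usable = [t for t in tads if t.end - t.start >= min_distance + 2 * site_width]
    for t in set(map(id, tads)) - set(map(id, usable)):
        log.info("TAD shorter than minimum pair distance skipped")
    if n_within and not usable:
        raise ValueError("no TAD long enough to host within-TAD pairs")
    pairs: list[SitePair] = []
    for _ in range(n_within):
        t = usable[rng.integers(len(usable))]
        lo, hi = t.start, t.end - site_width
        for _attempt in range(100):
            a, b = sorted(rng.integers(lo, hi, 2))
            if b - a >= min_distance:
                break
        pairs.append(SitePair(
            Interval(t.chrom, int(a), int(a + site_width)),
            Interval(t.chrom, int(b), int(b + site_width)),
            score(rng),
        ))
    for _ in range(n_between):
        i = int(rng.integers(len(tads) - 1)) if len(tads) > 1 else 0
        t1, t2 = tads[i], tads[min(i + 1, len(tads) - 1)]
        a = int(rng.integers(t1.start, t1.end - site_width))
        b = int(rng.integers(t2.start, t2.end - site_width))
        if b < a:
            a, b = b, a
        pairs.append(SitePair(
            Interval(t1.chrom, a, a + site_width),
            Interval(t1.chrom, b, b + site_width),
            score(rng),
        ))
    return pairs


def simulate_indifferent_pairs(
    chrom: str,
    chrom_length: int,
    n_pairs: int,
    seed: int = 0,
    site_width: int = 500,
    max_distance: int = 1_000_000,
    n_sites: Optional[int] = None,
) -> list[SitePair]:
    """Pairs placed with no regard to any domain structure (null fixture).

    Sites are laid down uniformly, then linked at random subject to a
    maximum separation, so each site's link count is organic rather than
    fixed — matching the degree-preserving null the enrichment test shuffles.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_sites or max(2 * n_pairs // 3, 10)
    starts = np.sort(rng.integers(0, chrom_length - site_width, n_sites))
    sites = [Interval(chrom, int(s), int(s + site_width)) for s in starts]
    pairs: list[SitePair] = []
    attempts = 0
    while len(pairs) < n_pairs and attempts < 100 * n_pairs:
        attempts += 1
        a, b = rng.integers(0, n_sites, 2)
        if a == b:
            continue
        s1, s2 = sorted((sites[a], sites[b]))
        if s2.midpoint - s1.midpoint > max_distance:
            continue
        pairs.append(SitePair(s1, s2, float(rng.uniform(0.1, 0.6))))
    return pairs
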