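"""Core genomic data model shared by every pipeline stage.

Coordinates are 0-based, half-open throughout (BED convention); bin index
``i`` at resolution ``r`` covers ``[i*r, (i+1)*r)``. Only intra-chromosomal
(cis) contacts are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GenomeAssembly",
    "BinGrid",
    "ContactMap",
    "SignalTrack",
    "Interval",
    "Domain",
    "Boundary",
    "Loop",
    "SitePair",
    "CCAN",
    "CellMatrices",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class BinGrid:
    """A genome partitioned into fixed-width bins."""

    assembly: GenomeAssembly
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def n_bins(self, chrom: str) -> int:
        return -(-self.assembly.length(chrom) // self.resolution)

    def bin_index(self, chrom: str, pos: int) -> int:
        i = pos // self.resolution
        if not 0 <= i < self.n_bins(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return i

    def bin_interval(self, chrom: str, i: int) -> "Interval":
        start = i * self.resolution
        end = min((i + 1) * self.resolution, self.assembly.length(chrom))
        return Interval(chrom, start, end)

    @property
    def chroms(self) -> tuple[str, ...]:
        return self.assembly.chrom_names


class ContactMap:
    """Per-chromosome symmetric binned contact counts.

    Only the upper triangle (i <= j) is stored, as CSR matrices of raw
    counts. Balancing weights ``w`` (np.nan on masked bins) turn raw counts
    ``c(i,j)`` into balanced values ``w_i * c(i,j) * w_j``.
    """

    def __init__(
        self,
        grid: BinGrid,
        counts: Mapping[str, sp.spmatrix],
        weights: Optional[Mapping[str, np.ndarray]] = None,
    ) -> None:
        self.grid = grid
        self.counts: dict[str, sp.csr_matrix] = {}
        for chrom, mat in counts.items():
            n = grid.n_bins(chrom)
            mat = sp.triu(sp.csr_matrix(mat, shape=(n, n))).tocsr()
            if mat.nnz and mat.data.min() < 0:
                raise ValueError("contact counts must be non-negative")
            self.counts[chrom] = mat
        self.weights: Optional[dict[str, np.ndarray]] = (
            {c: np.asarray(w, dtype=float) for c, w in weights.items()}
            if weights is not None
            else None
        )

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def chroms(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def dense(self, chrom: str) -> np.ndarray:
        """Symmetric dense raw-count matrix."""
        u = self.counts[chrom].toarray().astype(float)
        return u + np.triu(u, 1).T

    def unmasked(self, chrom: str) -> np.ndarray:
        """Boolean vector of bins that survived balancing (all True if raw)."""
        n = self.grid.n_bins(chrom)
        if self.weights is None:
            return np.ones(n, dtype=bool)
        return np.isfinite(self.weights[chrom])

    def balanced_dense(self, chrom: str) -> np.ndarray:
        """Symmetric balanced matrix; masked rows/cols are NaN."""
        if self.weights is None:
            raise ValueError("contact map is not balanced; run kr_balance first")
        w = self.weights[chrom]
        return self.dense(chrom) * w[:, None] * w[None, :]


@dataclass
class SignalTrack:
    """One scalar per bin (GC fraction, eigenvector, ...); NaN = missing."""

    grid: BinGrid
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if len(v) != self.grid.n_bins(chrom):
                raise ValueError(
                    f"track for {chrom} has {len(v)} values, "
                    f"expected {self.grid.n_bins(chrom)}"
                )
            self.values[chrom] = v


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True, order=True)
class Domain:
    chrom: str
    start: int
    end: int
    condition: str = ""
    rearrangement: str = ""  # stable / shift / split / merge / indeterminate

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty domain {self.chrom}:{self.start}-{self.end}")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass(frozen=True, order=True)
class Boundary:
    chrom: str
    start: int
    end: int
    score: float = float("nan")
    pvalue: float = float("nan")
    stability: str = ""  # stable / lost / gained

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, order=True)
class Loop:
    """Paired anchors on one chromosome; anchor1 is upstream of anchor2."""

    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    resolution: int = 0
    qvalue: float = float("nan")
    observed: float = float("nan")
    expected: float = float("nan")
    stability: str = ""

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("empty loop anchor")
        if self.start1 > self.start2:
            raise ValueError("anchor1 must be upstream of anchor2")

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start1, self.end2)


@dataclass(frozen=True)
class SitePair:
    """Two accessible sites on one chromosome with a co-accessibility score."""

    site1: Interval
    site2: Interval
    score: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.site1.chrom != self.site2.chrom:
            raise ValueError("site pair must be cis")
        if self.site1 == self.site2:
            raise ValueError("sites must be distinct")
        if self.site1 > self.site2:
            raise ValueError("site1 must be upstream of site2")

    @property
    def distance(self) -> int:
        return abs(self.site2.midpoint - self.site1.midpoint)


@dataclass(frozen=True)
class CCAN:
    """A cis-co-accessibility network: a community of >=3 linked sites."""

    id: int
    condition: str
    members: frozenset[Interval]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("CCAN needs at least 2 member sites")

    @property
    def span(self) -> Interval:
        chrom = next(iter(self.members)).chrom
        return Interval(
            chrom,
            min(m.start for m in self.members),
            max(m.end for m in self.members),
        )


class CellMatrices:
    """Sparse cell x peak accessibility and cell x gene expression.

    ``conditions`` holds exactly two distinct labels across cells. Peaks are
    a DataFrame (chrom, start, end, name); genes (name, chrom, tss, strand).
    """

    def __init__(self, accessibility, expression, peaks, genes, cell_ids, conditions):
        import pandas as pd

        self.accessibility = sp.csr_matrix(accessibility)
        self.expression = sp.csr_matrix(expression)
        self.peaks = pd.DataFrame(peaks).reset_index(drop=True)
        self.genes = pd.DataFrame(genes).reset_index(drop=True)
        self.cell_ids = list(cell_ids)
        self.conditions = np.asarray(conditions)
        n = len(self.cell_ids)
        if self.accessibility.shape != (n, len(self.peaks)):
            raise ValueError(
                f"accessibility shape {self.accessibility.shape} does not match "
                f"{n} cells x {len(self.peaks)} peaks"
            )
        if self.expression.shape != (n, len(self.genes)):
            raise ValueError(
                f"expression shape {self.expression.shape} does not match "
                f"{n} cells x {len(self.genes)} genes"
            )
        if len(self.conditions) != n:
            raise ValueError("condition labels must cover all cells")
        labels = sorted(set(self.conditions.tolist()))
        if len(labels) != 2:
            raise ValueError(f"exactly two conditions required, got {labels}")
        self.condition_labels = tuple(labels)

    def cells_of(self, condition: str) -> np.ndarray:
        if condition not in self.condition_labels:
            raise ValueError(f"unknown condition {condition!r}")
        return np.flatnonzero(self.conditions == condition)
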