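"""Readers and writers for the plain-text genomic formats the pipeline uses.

Contact maps travel as COO triplet text (``chrom  bin_i  bin_j  count``);
intervals as BED, loops as BEDPE, per-bin tracks as bedGraph, site pairs and
reports as TSV, and cell matrices as MatrixMarket MTX plus name files. All
emitted coordinates are 0-based half-open, and writers sort records
(chrom, start, end) so round-trips are order-normalized.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import (
    BinGrid,
    Boundary,
    CellMatrices,
    ContactMap,
    Domain,
    Interval,
    Loop,
    SignalTrack,
    SitePair,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_contact_map",
    "write_contact_map",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "read_site_pairs",
    "write_site_pairs",
    "read_cell_matrices",
    "write_cell_matrices",
]


def read_contact_map(path, grid: BinGrid) -> ContactMap:
    """Read a COO triplet text file into an upper-triangular ContactMap.

    Lower-triangle entries are folded onto (i, j) with i <= j and duplicate
    pixels are summed. Lines naming unknown chromosomes, out-of-range bins
    or negative counts raise a parse error citing the offending line.
    """
    rows: dict[str, list] = {c: [] for c in grid.chroms}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, si, sj, sc = parts
            if chrom not in rows:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            i, j, count = int(si), int(sj), float(sc)
            n = grid.n_bins(chrom)
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{path}:{lineno}: bin index out of range (n_bins={n})")
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            if j < i:
                i, j = j, i
            rows[chrom].append((i, j, count))
    counts = {}
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        if rows[chrom]:
            i, j, c = map(np.asarray, zip(*rows[chrom]))
            counts[chrom] = sp.coo_matrix((c, (i, j)), shape=(n, n)).tocsr()
        else:
            counts[chrom] = sp.csr_matrix((n, n))
    return ContactMap(grid, counts)


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in cmap.chroms():
            coo = cmap.counts[chrom].tocoo()
            order = np.lexsort((coo.col, coo.row))
            for i, j, c in zip(coo.row[order], coo.col[order], coo.data[order]):
                val = int(c) if float(c).is_integer() else c
                fh.write(f"{chrom}\t{i}\t{j}\t{val}\n")


# -- interval formats --------------------------------------------------------

def write_bed(records: Sequence, path) -> None:
    """Write Domains, Boundaries or Intervals as BED with extra columns."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            fields = [r.chrom, str(r.start), str(r.end)]
            if isinstance(r, Domain):
                fields += [r.condition or ".", r.rearrangement or "."]
            elif isinstance(r, Boundary):
                fields += [
                    f"{r.score:.6g}" if np.isfinite(r.score) else ".",
                    f"{r.pvalue:.6g}" if np.isfinite(r.pvalue) else ".",
                    r.stability or ".",
                ]
            fh.write("\t".join(fields) + "\n")


def read_bed(path, kind: str = "interval") -> list:
    """Read BED; kind in {"interval", "domain", "boundary"}."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if kind == "domain":
                cond = f[3] if len(f) > 3 and f[3] != "." else ""
                rearr = f[4] if len(f) > 4 and f[4] != "." else ""
                out.append(Domain(chrom, start, end, cond, rearr))
            elif kind == "boundary":
                score = float(f[3]) if len(f) > 3 and f[3] != "." else float("nan")
                pval = float(f[4]) if len(f) > 4 and f[4] != "." else float("nan")
                stab = f[5] if len(f) > 5 and f[5] != "." else ""
                out.append(Boundary(chrom, start, end, score, pval, stab))
            else:
                out.append(Interval(chrom, start, end))
    return out


def write_bedpe(loops: Sequence[Loop], path) -> None:
    loops = sorted(loops, key=lambda l: (l.chrom, l.start1, l.start2))
    with open(path, "w") as fh:
        for l in loops:
            fh.write(
                f"{l.chrom}\t{l.start1}\t{l.end1}\t{l.chrom}\t{l.start2}\t{l.end2}"
                f"\t{l.resolution}\t{l.qvalue:.6g}\t{l.observed:.6g}"
                f"\t{l.expected:.6g}\t{l.stability or '.'}\n"
            )


def read_bedpe(path) -> list[Loop]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                Loop(
                    chrom=f[0],
                    start1=int(f[1]),
                    end1=int(f[2]),
                    start2=int(f[4]),
                    end2=int(f[5]),
                    resolution=int(f[6]) if len(f) > 6 else 0,
                    qvalue=float(f[7]) if len(f) > 7 else float("nan"),
                    observed=float(f[8]) if len(f) > 8 else float("nan"),
                    expected=float(f[9]) if len(f) > 9 else float("nan"),
                    stability=f[10] if len(f) > 10 and f[10] != "." else "",
                )
            )
    return out


def write_bedgraph(track: SignalTrack, path) -> None:
    res = track.grid.resolution
    with open(path, "w") as fh:
        for chrom in track.grid.chroms:
            if chrom not in track.values:
                continue
            v = track.values[chrom]
            length = track.grid.assembly.length(chrom)
            for i, x in enumerate(v):
                if np.isnan(x):
                    continue
                fh.write(f"{chrom}\t{i * res}\t{min((i + 1) * res, length)}\t{x:.6g}\n")


def read_bedgraph(path, grid: BinGrid) -> SignalTrack:
    values = {c: np.full(grid.n_bins(c), np.nan) for c in grid.chroms}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, val = line.split("\t")[:4]
            if chrom not in values:
                raise ValueError(f"unknown chromosome {chrom!r} in {path}")
            values[chrom][grid.bin_index(chrom, int(start))] = float(val)
    return SignalTrack(grid, values)


# -- site pairs --------------------------------------------------------------

_PAIR_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "score", "condition",
]


def write_site_pairs(pairs: Sequence[SitePair], path) -> None:
    rows = [
        (
            p.site1.chrom, p.site1.start, p.site1.end,
            p.site2.chrom, p.site2.start, p.site2.end,
            p.score, p.condition or ".",
        )
        for p in pairs
    ]
    df = pd.DataFrame(rows, columns=_PAIR_COLS)
    df = df.sort_values(_PAIR_COLS[:6], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_site_pairs(path) -> list[SitePair]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SitePair(
                Interval(r.chrom1, int(r.start1), int(r.end1)),
                Interval(r.chrom2, int(r.start2), int(r.end2)),
                float(r.score),
                "" if str(r.condition) == "." else str(r.condition),
            )
        )
    return out


# -- cell matrices -----------------------------------------------------------

def read_cell_matrices(
    mtx_access, mtx_expr, peak_bed, gene_tsv, labels_tsv
) -> CellMatrices:
    """Assemble CellMatrices from MTX matrices plus name/label side files.

    ``peak_bed``: BED of peak coordinates (name column optional).
    ``gene_tsv``: TSV with columns name, chrom, tss, strand.
    ``labels_tsv``: TSV with columns cell, condition (exactly two conditions).
    """
    acc = sp.csr_matrix(scipy.io.mmread(mtx_access))
    expr = sp.csr_matrix(scipy.io.mmread(mtx_expr))
    peaks = []
    for iv in read_bed(peak_bed):
        peaks.append(
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "name": f"{iv.chrom}:{iv.start}-{iv.end}"}
        )
    peaks = pd.DataFrame(peaks)
    genes = pd.read_csv(gene_tsv, sep="\t")
    labels = pd.read_csv(labels_tsv, sep="\t")
    if acc.shape[0] != len(labels):
        raise ValueError(
            f"{acc.shape[0]} cells in accessibility matrix but "
            f"{len(labels)} labeled cells"
        )
    return CellMatrices(
        acc, expr, peaks, genes,
        cell_ids=labels["cell"].tolist(),
        conditions=labels["condition"].to_numpy(),
    )


def write_cell_matrices(cells: CellMatrices, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "accessibility.mtx", cells.accessibility)
    scipy.io.mmwrite(outdir / "expression.mtx", cells.expression)
    with open(outdir / "peaks.bed", "w") as fh:
        for r in cells.peaks.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    cells.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"cell": cells.cell_ids, "condition": cells.conditions}
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
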