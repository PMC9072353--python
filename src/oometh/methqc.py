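"""Per-cell QC, 100-CpG tiling and methylation quantification.

Single-oocyte bisulphite data are extremely sparse: each cell reports a
methylated/unmethylated call at only a fraction of genomic CpGs.  This module
provides the building blocks shared by every downstream analysis:

* :func:`cell_qc` / :class:`CellQC` — discard cells whose global methylation
  exceeds 50% or whose X-chromosome CpG-island methylation exceeds 16%
  (failed bisulphite conversion or contaminating somatic/cumulus cells).
* :func:`make_tiles` — partition each chromosome into consecutive
  non-overlapping windows of exactly 100 CpGs (the quantification unit).
* :func:`quantify_methylation` — call-weighted pooling of one or many cells
  over tiles or named regions (a merged group's level at a DMR is the pooled
  methylated calls divided by pooled total calls, i.e. the average across all
  CpG sites within the region).
* :func:`profile_correlation` — Pearson correlation of two merged tile
  profiles restricted to tiles that are well covered in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genome import GenomeModel, Region

__all__ = [
    "SingleCellMethylome",
    "TileSet",
    "MethylationQuant",
    "CellQC",
    "cell_qc",
    "make_tiles",
    "quantify_methylation",
    "cell_tile_counts",
    "profile_correlation",
]


class SingleCellMethylome:
    """Sparse per-cell CpG methylation calls.

    Stores, per chromosome, parallel arrays of CpG positions (bp, 0-based)
    and methylated/unmethylated call counts.  For single-cell data the counts
    are 0/1 with exactly one call per observed CpG, but arbitrary
    non-negative counts are accepted so pooled/pseudobulk data can use the
    same container.
    """

    def __init__(
        self,
        cell_id: str,
        sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        condition: str | None = None,
    ) -> None:
        self.cell_id = cell_id
        self.condition = condition
        self.sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        n_total = 0
        for chrom, (pos, meth, unmeth) in sites.items():
            pos = np.asarray(pos)
            meth = np.asarray(meth)
            unmeth = np.asarray(unmeth)
            if not (pos.shape == meth.shape == unmeth.shape):
                raise ValueError(f"{cell_id}/{chrom}: array length mismatch")
            if np.any(meth < 0) or np.any(unmeth < 0):
                raise ValueError(f"{cell_id}/{chrom}: negative call counts")
            order = np.argsort(pos, kind="mergesort")
            self.sites[chrom] = (pos[order], meth[order], unmeth[order])
            n_total += pos.size
        if n_total == 0:
            raise ValueError(f"{cell_id}: no observed CpGs")

    @property
    def n_sites(self) -> int:
        return sum(p.size for p, _, _ in self.sites.values())

    def counts(self, exclude: set[str] | None = None) -> tuple[int, int]:
        """(methylated, total) calls, optionally excluding chromosomes."""
        meth = total = 0
        for chrom, (_, m, u) in self.sites.items():
            if exclude and chrom in exclude:
                continue
            meth += int(m.sum())
            total += int(m.sum() + u.sum())
        return meth, total

    def region_counts(self, region: Region) -> tuple[int, int]:
        """(methylated, total) calls falling inside a region."""
        if region.chrom not in self.sites:
            return 0, 0
        pos, m, u = self.sites[region.chrom]
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        mm = int(m[lo:hi].sum())
        return mm, mm + int(u[lo:hi].sum())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SingleCellMethylome({self.cell_id!r}, n_sites={self.n_sites})"


@dataclass
class TileSet:
    """Non-overlapping fixed-CpG-count windows over a genome model.

    Tiles are numbered 0..n-1 in chromosome order; every tile contains
    exactly ``tile_size`` CpGs and never spans a chromosome boundary.
    Trailing CpGs that cannot fill a complete window are dropped.
    """

    tile_size: int
    chroms: np.ndarray          # per-tile chromosome name
    starts: np.ndarray          # bp of first member CpG
    ends: np.ndarray            # bp just past last member CpG (half-open)
    cpg_lo: np.ndarray          # index of first member CpG within its chromosome
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._by_chrom:
            for chrom in pd.unique(self.chroms):
                idx = np.flatnonzero(self.chroms == chrom)
                self._by_chrom[chrom] = (idx, self.starts[idx], self.ends[idx])

    def __len__(self) -> int:
        return len(self.starts)

    def assign(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Tile index for each position (-1 when outside every tile)."""
        out = np.full(len(positions), -1, dtype=np.int64)
        if chrom not in self._by_chrom:
            return out
        idx, starts, ends = self._by_chrom[chrom]
        k = np.searchsorted(starts, positions, side="right") - 1
        ok = (k >= 0) & (positions < ends[np.clip(k, 0, len(ends) - 1)])
        out[ok] = idx[k[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tile_id": np.arange(len(self)),
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "n_cpgs": self.tile_size,
            }
        )

    def overlapping(self, region: Region) -> np.ndarray:
        """Tile ids whose bp interval overlaps ``region``."""
        if region.chrom not in self._by_chrom:
            return np.empty(0, dtype=np.int64)
        idx, starts, ends = self._by_chrom[region.chrom]
        hit = (starts < region.end) & (ends > region.start)
        return idx[hit]


def make_tiles(genome: GenomeModel, tile_size: int = 100) -> TileSet:
    """Partition every chromosome into consecutive ``tile_size``-CpG windows.

    A chromosome with fewer than ``tile_size`` CpGs contributes no tiles;
    the trailing remainder of each chromosome is dropped so that every tile
    has identical CpG resolution.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    lo: list[int] = []
    for chrom in genome.chrom_names:
        pos = genome.cpg_positions[chrom]
        n_tiles = len(pos) // tile_size
        for k in range(n_tiles):
            member = pos[k * tile_size : (k + 1) * tile_size]
            chroms.append(chrom)
            starts.append(int(member[0]))
            ends.append(int(member[-1]) + 1)
            lo.append(k * tile_size)
    return TileSet(
        tile_size=tile_size,
        chroms=np.asarray(chroms, dtype=object),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        cpg_lo=np.asarray(lo, dtype=np.int64),
    )


@dataclass
class MethylationQuant:
    """Pooled methylation per feature, with the pooled cells recorded.

    ``frame`` columns: feature id index, ``meth``, ``total``, ``fraction``
    (NaN when no calls cover the feature — absence of data, not
    hypomethylation).
    """

    frame: pd.DataFrame
    cell_ids: list[str]

    def __len__(self) -> int:
        return len(self.frame)


def cell_tile_counts(
    cells: list[SingleCellMethylome], tiles: TileSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell, per-tile (methylated, total) call matrices."""
    n_tiles = len(tiles)
    meth = np.zeros((len(cells), n_tiles), dtype=np.int64)
    total = np.zeros((len(cells), n_tiles), dtype=np.int64)
    for i, cell in enumerate(cells):
        for chrom, (pos, m, u) in cell.sites.items():
            t = tiles.assign(chrom, pos)
            ok = t >= 0
            if not ok.any():
                continue
            meth[i] += np.bincount(t[ok], weights=m[ok], minlength=n_tiles).astype(np.int64)
            total[i] += np.bincount(
                t[ok], weights=m[ok] + u[ok], minlength=n_tiles
            ).astype(np.int64)
    return meth, total


def quantify_methylation(
    cells: SingleCellMethylome | list[SingleCellMethylome],
    features: TileSet | list[Region] | Region,
) -> MethylationQuant:
    """Call-weighted pooled methylation of one or more cells per feature.

    Pooling sums methylated and total calls across all supplied cells (it is
    never an average of per-cell fractions), so
    ``quantify(A + B).counts == quantify(A).counts + quantify(B).counts``.
    """
    if isinstance(cells, SingleCellMethylome):
        cells = [cells]
    if isinstance(features, Region):
        features = [features]
    if isinstance(features, TileSet):
        m, t = cell_tile_counts(cells, features)
        meth = m.sum(axis=0)
        total = t.sum(axis=0)
        frame = features.to_frame().set_index("tile_id")
        frame["meth"] = meth
        frame["total"] = total
    else:
        rows = []
        for reg in features:
            mm = tt = 0
            for cell in cells:
                a, b = cell.region_counts(reg)
                mm += a
                tt += b
            rows.append((reg.name, reg.chrom, reg.start, reg.end, reg.kind, mm, tt))
        frame = pd.DataFrame(
            rows, columns=["feature", "chrom", "start", "end", "kind", "meth", "total"]
        ).set_index("feature")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = frame["meth"] / frame["total"]
    frame["fraction"] = frac.where(frame["total"] > 0)
    return MethylationQuant(frame=frame, cell_ids=[c.cell_id for c in cells])


def cell_qc(
    cells: list[SingleCellMethylome],
    x_cgi_regions: list[Region] | None = None,
    global_threshold: float = 0.50,
    x_threshold: float = 0.16,
    x_chrom: str = "chrX",
) -> pd.DataFrame:
    """Per-cell QC report against the global and X-CGI methylation filters.

    A cell fails when its global (autosomal) methylation is strictly greater
    than ``global_threshold`` or its X-chromosome CGI methylation is strictly
    greater than ``x_threshold``; boundary values pass.  Cells with no calls
    in the X CGIs have that criterion skipped and are flagged.

    Returns a frame with columns ``cell_id``, ``global_methylation``,
    ``x_cgi_methylation``, ``n_sites``, ``passed``, ``reason``,
    ``x_criterion_skipped``.
    """
    if not 0 <= global_threshold <= 1 or not 0 <= x_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    x_cgi_regions = x_cgi_regions or []
    rows = []
    for cell in cells:
        g_meth, g_total = cell.counts(exclude={x_chrom})
        if g_total == 0:  # cell observed only on X
            g_meth, g_total = cell.counts()
        global_frac = g_meth / g_total
        x_meth = x_total = 0
        for reg in x_cgi_regions:
            a, b = cell.region_counts(reg)
            x_meth += a
            x_total += b
        x_frac = x_meth / x_total if x_total > 0 else np.nan
        x_skipped = x_total == 0 and bool(x_cgi_regions)
        reasons = []
        if global_frac > global_threshold:
            reasons.append("global")
        if x_total > 0 and x_frac > x_threshold:
            reasons.append("x_cgi")
        rows.append(
            (
                cell.cell_id,
                global_frac,
                x_frac,
                cell.n_sites,
                not reasons,
                "+".join(reasons),
                x_skipped,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "global_methylation",
            "x_cgi_methylation",
            "n_sites",
            "passed",
            "reason",
            "x_criterion_skipped",
        ],
    )


class CellQC(BaseEstimator):
    """Sklearn-style QC filter over a list of single-cell methylomes.

    Parameters
    ----------
    global_threshold, x_threshold
        Strictly-greater-than failure thresholds for global (autosomal) and
        X-CGI methylation.
    x_cgi_regions
        X-chromosome CpG-island regions used for the second criterion.
    x_chrom
        Chromosome excluded from the global fraction and carrying the CGIs.

    Attributes
    ----------
    report_ : pandas.DataFrame
        Per-cell QC table (see :func:`cell_qc`).
    n_pass_ : int
    """

    def __init__(
        self,
        global_threshold: float = 0.50,
        x_threshold: float = 0.16,
        x_cgi_regions: list[Region] | None = None,
        x_chrom: str = "chrX",
    ) -> None:
        self.global_threshold = global_threshold
        self.x_threshold = x_threshold
        self.x_cgi_regions = x_cgi_regions
        self.x_chrom = x_chrom

    def fit(self, X: list[SingleCellMethylome], y=None) -> "CellQC":
        self.report_ = cell_qc(
            X,
            x_cgi_regions=self.x_cgi_regions,
            global_threshold=self.global_threshold,
            x_threshold=self.x_threshold,
            x_chrom=self.x_chrom,
        )
        self.n_pass_ = int(self.report_["passed"].sum())
        return self

    def transform(self, X: list[SingleCellMethylome]) -> list[SingleCellMethylome]:
        """Return only the cells that pass both criteria."""
        report = cell_qc(
            X,
            x_cgi_regions=self.x_cgi_regions,
            global_threshold=self.global_threshold,
            x_threshold=self.x_threshold,
            x_chrom=self.x_chrom,
        )
        keep = set(report.loc[report["passed"], "cell_id"])
        return [c for c in X if c.cell_id in keep]

    def fit_transform(self, X: list[SingleCellMethylome], y=None) -> list[SingleCellMethylome]:
        self.fit(X)
        keep = set(self.report_.loc[self.report_["passed"], "cell_id"])
        return [c for c in X if c.cell_id in keep]


def profile_correlation(
    quant_a: MethylationQuant,
    quant_b: MethylationQuant,
    min_total_calls: int = 10,
) -> tuple[float, int]:
    """Pearson r between two merged tile profiles on well-covered tiles.

    Only tiles with at least ``min_total_calls`` calls in *both*
    quantifications enter the correlation.  Returns ``(r, n_tiles_used)``.
    """
    a = quant_a.frame
    b = quant_b.frame
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        a = a.loc[common]
        b = b.loc[common]
    mask = (a["total"] >= min_total_calls) & (b["total"] >= min_total_calls)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} shared testable tiles; need at least 3")
    r = float(np.corrcoef(a.loc[mask, "fraction"], b.loc[mask, "fraction"])[0, 1])
    return r, n
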