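"""Readers and writers for the plain-text interchange formats.

Coordinates: Bismark-style coverage files are 1-based inclusive; BED is
0-based half-open; everything in memory is 0-based half-open, converted at
these readers/writers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clonal import CloneSet
from .genome import Region
from .methqc import SingleCellMethylome

__all__ = [
    "read_coverage",
    "write_coverage",
    "read_bed",
    "write_bed",
    "read_clones",
    "write_clones",
    "read_ct_table",
    "read_sim_config",
    "write_sim_config",
]

_COV_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


def write_coverage(cell: SingleCellMethylome, path) -> None:
    """Write a cell as a Bismark-coverage-style TSV (1-based inclusive)."""
    frames = []
    for chrom, (pos, m, u) in cell.sites.items():
        with np.errstate(invalid="ignore"):
            pct = np.where(m + u > 0, 100.0 * m / np.maximum(m + u, 1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos + 1,
                    "end": pos + 1,
                    "pct": np.round(pct, 6),
                    "meth": m,
                    "unmeth": u,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def read_coverage(path, cell_id: str | None = None, condition: str | None = None) -> SingleCellMethylome:
    """Read a Bismark-coverage-style TSV into a single-cell methylome."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS)
    sites = {}
    for chrom, sub in table.groupby("chrom", sort=False):
        sites[str(chrom)] = (
            sub["start"].to_numpy(np.int64) - 1,  # to 0-based
            sub["meth"].to_numpy(np.int64),
            sub["unmeth"].to_numpy(np.int64),
        )
    return SingleCellMethylome(cell_id or path.stem, sites, condition=condition)


def write_bed(regions: list[Region], path) -> None:
    """Write regions as BED (0-based half-open); the kind goes in column 5."""
    pd.DataFrame(
        [(r.chrom, r.start, r.end, r.name, r.kind) for r in regions]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[Region]:
    table = pd.read_csv(path, sep="\t", header=None)
    regions = []
    for row in table.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else f"region_{len(regions) + 1}"
        kind = str(row[4]) if len(row) > 4 else ""
        regions.append(Region(name, str(row[0]), int(row[1]), int(row[2]), kind))
    return regions


def write_clones(clones: CloneSet, path) -> None:
    """One row per clone, one column per CpG; missing calls as NA."""
    pd.DataFrame(
        clones.states,
        index=[f"clone_{i + 1}" for i in range(clones.n_clones)],
        columns=[f"cpg_{j + 1}" for j in range(clones.n_cpgs)],
    ).to_csv(path, sep="\t", na_rep="NA")


def read_clones(path, region: str | None = None, label: str = "") -> CloneSet:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return CloneSet(region=region or path.stem, label=label, states=table.to_numpy(float))


def read_ct_table(path) -> pd.DataFrame:
    """Ct table CSV with columns sample, group, gene, replicate, ct."""
    table = pd.read_csv(path)
    missing = {"sample", "gene", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"ct table missing columns {sorted(missing)}")
    return table


def read_sim_config(path):
    from .simulate import SimConfig

    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def write_sim_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
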