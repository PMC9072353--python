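"""Genome coordinate model shared by the simulator and the methylation code.

A :class:`GenomeModel` is an ordered set of chromosomes, each carrying a
strictly increasing array of CpG positions (bp, 0-based), an optional latent
per-CpG methylation probability (the simulation ground truth), and named
annotation :class:`Region` intervals: imprinted germline DMRs (gDMRs),
secondary (somatic) DMRs and X-chromosome CpG islands.  All internal
coordinates are 0-based half-open; file readers/writers convert at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MATERNAL_GDMR = "maternal_gdmr"
PATERNAL_GDMR = "paternal_gdmr"
SECONDARY_DMR = "secondary_dmr"
X_CGI = "x_cgi"


@dataclass(frozen=True)
class Region:
    """A named genomic interval (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    kind: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.name}: end must exceed start")


@dataclass
class GenomeModel:
    """Ordered chromosomes with CpG maps, latent methylation and annotations.

    Parameters
    ----------
    chrom_names
        Chromosome order used for tiling and global CpG indexing.
    cpg_positions
        Per-chromosome strictly increasing CpG coordinates (bp).
    latent
        Optional per-CpG methylation probability, aligned with
        ``cpg_positions`` — the ground truth used by the simulator.
    annotations
        Named regions (gDMRs, secondary DMRs, X CGIs).
    x_chrom
        Name of the X chromosome if the model has one; used by the QC
        criteria (the global-methylation filter excludes it).
    """

    chrom_names: list[str]
    cpg_positions: dict[str, np.ndarray]
    latent: dict[str, np.ndarray] | None = None
    annotations: list[Region] = field(default_factory=list)
    x_chrom: str | None = None

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            pos = np.asarray(self.cpg_positions[name])
            if pos.ndim != 1 or pos.size == 0:
                raise ValueError(f"{name}: empty CpG position array")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{name}: CpG positions must be strictly increasing")
            self.cpg_positions[name] = pos
            if self.latent is not None:
                lat = np.asarray(self.latent[name], dtype=float)
                if lat.shape != pos.shape:
                    raise ValueError(f"{name}: latent shape mismatch")
                if np.any((lat < 0) | (lat > 1)):
                    raise ValueError(f"{name}: latent probabilities outside [0, 1]")
                self.latent[name] = lat
        for reg in self.annotations:
            if reg.chrom not in self.cpg_positions:
                raise ValueError(f"annotation {reg.name} on unknown chromosome {reg.chrom}")
        if self.x_chrom is not None and self.x_chrom not in self.chrom_names:
            raise ValueError(f"x_chrom {self.x_chrom!r} not among chromosomes")

    @property
    def n_cpgs(self) -> int:
        return sum(len(self.cpg_positions[c]) for c in self.chrom_names)

    def region_indices(self, region: Region) -> np.ndarray:
        """Indices (within the region's chromosome) of CpGs inside ``region``."""
        pos = self.cpg_positions[region.chrom]
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        return np.arange(lo, hi)

    def annotations_of(self, kind: str) -> list[Region]:
        return [r for r in self.annotations if r.kind == kind]

    @property
    def x_cgi_regions(self) -> list[Region]:
        return self.annotations_of(X_CGI)
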