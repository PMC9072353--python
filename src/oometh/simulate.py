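"""Synthetic data generators with known ground truth.

Every downstream stage of the package is exercisable without any sequencing
download: this module fabricates

* sparse single-oocyte CpG methylomes over a bimodal (hyper-/hypomethylated
  domain) genome carrying a panel of 19 maternal gDMRs, 3 paternal gDMRs and
  2 secondary DMRs, with a configurable number of 100-CpG tiles spiked with a
  condition effect (:func:`simulate_methylomes`);
* qPCR Ct tables whose Ct differences encode log2 expression ratios plus
  Gaussian noise, including allele-specific assay pairs with a known paternal
  fraction (:func:`simulate_ct_experiment`);
* clonal bisulphite state matrices (:func:`simulate_clone_sets`);
* negative-binomial count matrices with designated fold-changed features
  (:func:`simulate_count_matrix`).

All generators require an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clonal import CloneSet
from .genome import (
    MATERNAL_GDMR,
    PATERNAL_GDMR,
    SECONDARY_DMR,
    X_CGI,
    GenomeModel,
    Region,
)
from .methqc import SingleCellMethylome, TileSet, make_tiles

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_ct_experiment",
    "simulate_clone_sets",
    "simulate_count_matrix",
]


@dataclass
class SimConfig:
    """Configuration of the methylome simulation.

    The defaults describe the reference scenario used throughout the test
    suite: two conditions of 40 oocytes, 500,000 autosomal CpGs (5,000
    100-CpG tiles), per-CpG coverage 0.15, and 50 tiles spiked with a 0.30
    methylation-probability difference.  ``seed`` has no default — every run
    must state one.
    """

    seed: int
    n_chromosomes: int = 4
    n_cpgs: int = 500_000
    cells_per_condition: int = 40
    coverage: float = 0.15
    tile_size: int = 100
    n_spiked_tiles: int = 50
    effect_size: float = 0.30
    hyper_fraction: float = 0.40
    hyper_level: float = 0.85
    hypo_level: float = 0.05
    level_concentration: float = 60.0
    domain_size_range: tuple[int, int] = (500, 3000)
    mean_cpg_spacing: int = 100
    n_maternal_gdmrs: int = 19
    n_paternal_gdmrs: int = 3
    n_secondary_dmrs: int = 2
    dmr_n_cpgs: int = 30
    include_x: bool = True
    x_cpgs: int = 20_000
    n_x_cgis: int = 20
    x_cgi_n_cpgs: int = 30
    cell_noise_sd: float = 0.0
    coverage_mode: str = "independent"  # or "blocks"
    coverage_block_cpgs: int = 50
    condition_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if self.cells_per_condition < 1:
            raise ValueError("cells_per_condition must be positive")
        for name in ("n_chromosomes", "n_cpgs", "tile_size", "mean_cpg_spacing"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not -1 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [-1, 1]")
        if self.n_spiked_tiles < 0:
            raise ValueError("n_spiked_tiles must be non-negative")
        if not 0 <= self.hyper_fraction <= 1:
            raise ValueError("hyper_fraction must lie in [0, 1]")
        if self.coverage_mode not in ("independent", "blocks"):
            raise ValueError("coverage_mode must be 'independent' or 'blocks'")
        if self.cell_noise_sd < 0:
            raise ValueError("cell_noise_sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["domain_size_range"] = list(self.domain_size_range)
        d["condition_names"] = list(self.condition_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "domain_size_range" in d:
            d["domain_size_range"] = tuple(d["domain_size_range"])
        if "condition_names" in d:
            d["condition_names"] = tuple(d["condition_names"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth recorded by the simulators.

    ``differential_tiles`` holds one row per spiked tile: ``tile_id`` and the
    signed, possibly clipping-adjusted methylation-probability difference
    applied to condition B.  The Ct and count simulators return their own
    truth mappings which callers may attach here.
    """

    differential_tiles: pd.DataFrame
    allelic_fractions: dict = field(default_factory=dict)
    count_effects: dict = field(default_factory=dict)

    @property
    def spiked_tile_ids(self) -> np.ndarray:
        return self.differential_tiles["tile_id"].to_numpy()


def _draw_levels(rng: np.random.Generator, mean: float, conc: float, size: int) -> np.ndarray:
    a = mean * conc
    b = (1.0 - mean) * conc
    return np.clip(rng.beta(a, b, size=size), 0.005, 0.995)


def _bimodal_latent(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Per-CpG latent probabilities from alternating hyper/hypo domains."""
    lo, hi = cfg.domain_size_range
    latent = np.empty(n)
    start = 0
    while start < n:
        length = int(rng.integers(lo, hi + 1))
        end = min(start + length, n)
        if rng.random() < cfg.hyper_fraction:
            level = _draw_levels(rng, cfg.hyper_level, cfg.level_concentration, 1)[0]
        else:
            level = _draw_levels(rng, cfg.hypo_level, cfg.level_concentration, 1)[0]
        latent[start:end] = level
        start = end
    return latent


def _place_regions(
    rng: np.random.Generator,
    chrom: str,
    positions: np.ndarray,
    latent: np.ndarray,
    used: list[tuple[int, int]],
    names: list[str],
    n_cpgs: int,
    level_low: float,
    level_high: float,
    kind: str,
) -> list[Region]:
    """Carve non-overlapping annotation regions and override their latent level."""
    regions = []
    n = len(positions)
    for name in names:
        for _ in range(1000):
            i0 = int(rng.integers(0, n - n_cpgs))
            i1 = i0 + n_cpgs
            if all(i1 <= lo or i0 >= hi for lo, hi in used):
                break
        else:  # pragma: no cover - genome too crowded
            raise RuntimeError("could not place annotation region without overlap")
        used.append((i0, i1))
        latent[i0:i1] = rng.uniform(level_low, level_high)
        regions.append(
            Region(
                name=name,
                chrom=chrom,
                start=int(positions[i0]),
                end=int(positions[i1 - 1]) + 1,
                kind=kind,
            )
        )
    return regions


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeModel:
    """Build the oocyte genome model: bimodal domains plus the DMR panel.

    Maternal gDMRs sit at latent methylation >= 0.85 and paternal gDMRs at
    <= 0.10, matching the oocyte ground truth in which maternal germline
    imprints are established and paternal ones absent; secondary DMRs are
    intermediate; X CpG islands are hypomethylated (they feed the QC filter).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    base, rem = divmod(config.n_cpgs, config.n_chromosomes)
    sizes = [base + (1 if i < rem else 0) for i in range(config.n_chromosomes)]

    positions: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    for name, n in zip(chrom_names, sizes):
        gaps = rng.integers(2, 2 * config.mean_cpg_spacing, size=n)
        positions[name] = np.cumsum(gaps).astype(np.int64)
        latent[name] = _bimodal_latent(rng, n, config)

    annotations: list[Region] = []
    # spread the gDMR panel over the autosomes, round-robin
    panel = (
        [(MATERNAL_GDMR, "mat_gDMR_", 0.86, 0.96)] * config.n_maternal_gdmrs
        + [(PATERNAL_GDMR, "pat_gDMR_", 0.02, 0.08)] * config.n_paternal_gdmrs
        + [(SECONDARY_DMR, "sDMR_", 0.40, 0.60)] * config.n_secondary_dmrs
    )
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    counters: dict[str, int] = {}
    for j, (kind, prefix, lo, hi) in enumerate(panel):
        chrom = chrom_names[j % len(chrom_names)]
        counters[kind] = counters.get(kind, 0) + 1
        annotations.extend(
            _place_regions(
                rng,
                chrom,
                positions[chrom],
                latent[chrom],
                used[chrom],
                names=[f"{prefix}{counters[kind]}"],
                n_cpgs=config.dmr_n_cpgs,
                level_low=lo,
                level_high=hi,
                kind=kind,
            )
        )

    x_chrom = None
    if config.include_x:
        x_chrom = "chrX"
        chrom_names.append(x_chrom)
        gaps = rng.integers(2, 2 * config.mean_cpg_spacing, size=config.x_cpgs)
        positions[x_chrom] = np.cumsum(gaps).astype(np.int64)
        latent[x_chrom] = _bimodal_latent(rng, config.x_cpgs, config)
        annotations.extend(
            _place_regions(
                rng,
                x_chrom,
                positions[x_chrom],
                latent[x_chrom],
                [],
                names=[f"xCGI_{k + 1}" for k in range(config.n_x_cgis)],
                n_cpgs=config.x_cgi_n_cpgs,
                level_low=0.01,
                level_high=0.05,
                kind=X_CGI,
            )
        )

    return GenomeModel(
        chrom_names=chrom_names,
        cpg_positions=positions,
        latent=latent,
        annotations=annotations,
        x_chrom=x_chrom,
    )


def _coverage_mask(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    if cfg.coverage_mode == "independent":
        return rng.random(n) < cfg.coverage
    # block mode: alternate covered/uncovered runs with geometric lengths so
    # the expected covered fraction equals the coverage rate
    mask = np.zeros(n, dtype=bool)
    mean_cov = cfg.coverage_block_cpgs
    mean_gap = mean_cov * (1.0 - cfg.coverage) / cfg.coverage
    pos = int(rng.geometric(1.0 / max(mean_gap, 1.0))) if rng.random() > cfg.coverage else 0
    while pos < n:
        run = int(rng.geometric(1.0 / mean_cov))
        mask[pos : pos + run] = True
        pos += run + int(rng.geometric(1.0 / max(mean_gap, 1.0)))
    return mask


def _sample_cell(
    rng: np.random.Generator,
    cell_id: str,
    condition: str,
    genome: GenomeModel,
    latent: dict[str, np.ndarray],
    cfg: SimConfig,
) -> SingleCellMethylome:
    sites = {}
    jitter = rng.normal(0.0, cfg.cell_noise_sd) if cfg.cell_noise_sd > 0 else 0.0
    for chrom in genome.chrom_names:
        n = len(genome.cpg_positions[chrom])
        mask = _coverage_mask(rng, n, cfg)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        prob = latent[chrom][idx]
        if jitter != 0.0:
            logit = np.log(prob / (1 - prob)) + jitter
            prob = 1.0 / (1.0 + np.exp(-logit))
        states = rng.random(idx.size) < prob
        meth = states.astype(np.int16)
        sites[chrom] = (genome.cpg_positions[chrom][idx], meth, (1 - meth).astype(np.int16))
    return SingleCellMethylome(cell_id, sites, condition=condition)


def simulate_methylomes(
    config: SimConfig,
) -> tuple[GenomeModel, dict[str, list[SingleCellMethylome]], TruthTable]:
    """Simulate two conditions of sparse single-cell methylomes.

    Returns the genome model, a mapping condition name -> list of cells, and
    the :class:`TruthTable` recording which tiles were spiked and by how
    much.  Each cell observes a Binomial(coverage) subset of CpGs with one
    Bernoulli call per observed CpG; condition B's latent probabilities are
    shifted by the configured effect at the spiked tiles (sign chosen towards
    0.5 so the shift stays inside [0, 1]; values are clipped with a warning
    otherwise).
    """
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    tiles = make_tiles(genome, config.tile_size)

    latent_a = {c: genome.latent[c].copy() for c in genome.chrom_names}
    latent_b = {c: genome.latent[c].copy() for c in genome.chrom_names}

    truth_rows = []
    if config.n_spiked_tiles > 0 and config.effect_size != 0.0:
        frame = tiles.to_frame()
        eligible = frame["chrom"] != (genome.x_chrom or "")
        blocked: set[int] = set()
        for reg in genome.annotations:
            blocked.update(tiles.overlapping(reg).tolist())
        eligible &= ~frame["tile_id"].isin(blocked)
        pool = frame.loc[eligible, "tile_id"].to_numpy()
        if len(pool) < config.n_spiked_tiles:
            raise ValueError("not enough eligible tiles to spike")
        chosen = np.sort(rng.choice(pool, size=config.n_spiked_tiles, replace=False))
        clipped = False
        for tid in chosen:
            chrom = tiles.chroms[tid]
            lo = int(tiles.cpg_lo[tid])
            sl = slice(lo, lo + config.tile_size)
            base = latent_a[chrom][sl]
            sign = 1.0 if base.mean() < 0.5 else -1.0
            delta = sign * abs(config.effect_size)
            shifted = base + delta
            if np.any((shifted < 0) | (shifted > 1)):
                clipped = True
                shifted = np.clip(shifted, 0.0, 1.0)
            latent_b[chrom][sl] = shifted
            truth_rows.append((int(tid), float((shifted - base).mean())))
        if clipped:
            warnings.warn(
                "effect size pushed some latent probabilities outside [0, 1]; clipped",
                stacklevel=2,
            )
    truth = TruthTable(
        differential_tiles=pd.DataFrame(truth_rows, columns=["tile_id", "delta"])
    )

    cells: dict[str, list[SingleCellMethylome]] = {}
    for cond, latent in zip(config.condition_names, (latent_a, latent_b)):
        cells[cond] = [
            _sample_cell(rng, f"{cond}_{j:03d}", cond, genome, latent, config)
            for j in range(config.cells_per_condition)
        ]
    return genome, cells, truth


def simulate_ct_experiment(
    rel_expr: dict | None = None,
    paternal_fraction: dict | None = None,
    noise_sd: float = 0.2,
    n_replicates: int = 4,
    n_technical: int = 3,
    housekeepers: tuple[str, ...] = ("Actb", "18S", "Hprt"),
    groups: tuple[str, ...] = ("A", "B"),
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a qPCR Ct table with known expression and allelic truth.

    Parameters
    ----------
    rel_expr
        Mapping gene -> (scalar, or mapping group -> value) true expression
        relative to the housekeeper mean.  Ct(target) is the housekeeper-mean
        Ct minus log2 of that value, plus Gaussian noise per technical
        replicate; a per-sample loading offset shifts all genes of a sample
        together (ΔCt statistics are invariant to it).
    paternal_fraction
        Mapping gene -> true paternal fraction in (0, 1).  Generates a
        maternal/paternal assay pair ``<gene>_mat`` / ``<gene>_pat`` so that
        ΔCt = Ct(mat) - Ct(pat) = log2(f / (1 - f)) exactly when noiseless.
    noise_sd
        Gaussian Ct noise per technical replicate (cycles).
    n_replicates, n_technical
        Biological replicates per group and technical replicates per well.

    Returns ``(table, truth)`` where the table has columns ``sample``,
    ``group``, ``gene``, ``replicate``, ``ct``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_replicates < 1 or n_technical < 1:
        raise ValueError("replicate counts must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rel_expr = rel_expr or {}
    paternal_fraction = paternal_fraction or {}
    for gene, f in paternal_fraction.items():
        if not 0 < f < 1:
            raise ValueError(f"paternal fraction for {gene} must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    hk_base = {hk: float(rng.uniform(14.0, 24.0)) for hk in housekeepers}
    hk_mean = float(np.mean(list(hk_base.values())))

    rows = []

    def _well(sample, group, gene, true_ct):
        for rep in range(1, n_technical + 1):
            rows.append((sample, group, gene, rep, true_ct + rng.normal(0.0, noise_sd)))

    for group in groups:
        for i in range(1, n_replicates + 1):
            sample = f"{group}_{i}"
            offset = float(rng.normal(0.0, 0.5))  # loading/input shift
            for hk in housekeepers:
                _well(sample, group, hk, hk_base[hk] + offset)
            for gene, spec in rel_expr.items():
                value = spec[group] if isinstance(spec, dict) else spec
                if value <= 0:
                    raise ValueError(f"relative expression for {gene} must be positive")
                _well(sample, group, gene, hk_mean + offset - math.log2(value))
            for gene, f in paternal_fraction.items():
                _well(sample, group, f"{gene}_mat", hk_mean + offset - math.log2(1.0 - f))
                _well(sample, group, f"{gene}_pat", hk_mean + offset - math.log2(f))

    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    truth = {
        "rel_expr": rel_expr,
        "paternal_fraction": dict(paternal_fraction),
        "housekeepers": tuple(housekeepers),
    }
    return table, truth


def simulate_clone_sets(
    region_length: int,
    n_clones: int = 24,
    p_meth: float = 0.5,
    region: str = "region",
    label: str = "sample",
    seed: int | None = None,
) -> CloneSet:
    """Simulate one sample's clonal bisulphite patterns for a region.

    Each clone is a full-length binary CpG state vector with independent
    Bernoulli(``p_meth``) states.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if region_length < 1:
        raise ValueError("region_length must be positive")
    if n_clones < 1:
        raise ValueError("n_clones must be positive")
    if not 0 <= p_meth <= 1:
        raise ValueError("p_meth must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = (rng.random((n_clones, region_length)) < p_meth).astype(float)
    return CloneSet(region=region, label=label, states=states)


def simulate_count_matrix(
    n_features: int = 1000,
    samples_per_group: tuple[int, int] = (4, 4),
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    fold_changes: dict[int, float] | None = None,
    group_names: tuple[str, str] = ("A", "B"),
    library_size_cv: float = 0.15,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial count matrix with designated fold-changed features.

    ``fold_changes`` maps feature index -> fold change applied to the second
    group's mean.  Per-sample library scale factors are log-normal with the
    given coefficient of variation.  Returns ``(counts, groups, truth)``:
    counts are features x samples, ``groups`` maps sample -> group name and
    ``truth`` lists each feature's true fold change.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    fold_changes = fold_changes or {}
    for idx, fc in fold_changes.items():
        if not 0 <= idx < n_features:
            raise ValueError(f"fold-change feature index {idx} out of range")
        if fc <= 0:
            raise ValueError("fold changes must be positive")

    rng = np.random.default_rng(seed)
    base = np.full(n_features, baseline_mean)
    fc_vec = np.ones(n_features)
    for idx, fc in fold_changes.items():
        fc_vec[idx] = fc

    n_size = 1.0 / dispersion  # NB shape: var = mu + dispersion * mu^2
    columns = {}
    groups = {}
    sigma = math.sqrt(math.log(1.0 + library_size_cv**2))
    for g, (gname, n_samples) in enumerate(zip(group_names, samples_per_group)):
        mu_group = base * (fc_vec if g == 1 else 1.0)
        for i in range(1, n_samples + 1):
            scale = float(rng.lognormal(-0.5 * sigma**2, sigma))
            mu = mu_group * scale
            p = n_size / (n_size + mu)
            sample = f"{gname}_{i}"
            columns[sample] = rng.negative_binomial(n_size, p)
            groups[sample] = gname
    counts = pd.DataFrame(columns, index=[f"feature_{j}" for j in range(n_features)])
    truth = pd.DataFrame(
        {"feature": counts.index, "fold_change": fc_vec}
    ).set_index("feature")
    return counts, pd.Series(groups, name="group"), truth
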