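"""Shuffled-pseudobulk consensus DMR caller.

Single-oocyte bisulphite data are too sparse for per-cell differential
testing, so cells of each condition are pooled into pseudobulks of (at most)
nine cells and differential methylation is tested per 100-CpG tile with a
weighted logistic regression: one observation per pseudobulk, the binomial
methylated proportion regressed on the condition indicator with prior weight
equal to the pseudobulk's total calls, and a two-sided Wald test on the
condition coefficient.  Because the pseudobulk memberships are arbitrary, the
whole procedure is repeated (default 100 times) with freshly shuffled
groupings; a tile's *support* is the number of shuffles in which its
Benjamini–Hochberg q-value (computed within that shuffle's family of testable
tiles) falls below the FDR threshold.  A consensus DMR is called when the
observed merged-cell methylation difference is at least 10% in absolute value
and the support reaches at least 70 of 100 shuffles.

With a single binary covariate and call-count weights, the binomial-GLM
maximum likelihood depends on the data only through the pooled per-condition
counts, so the Wald statistic is evaluated in closed form (see
``docs/methods.md``); the pseudobulk structure enters through the
per-pseudobulk minimum-calls testability filter and through each shuffle's
FDR family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .methqc import SingleCellMethylome, TileSet, cell_tile_counts
from .multitest import fdr_bh

__all__ = [
    "partition_pseudobulks",
    "test_tile",
    "TileTestResult",
    "shuffle_consensus",
    "call_dmrs",
    "ConsensusDMRCaller",
]


def partition_pseudobulks(
    cell_ids, group_size: int = 9, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Randomly partition cells into pseudobulk groups of near-equal size.

    The number of groups is ``max(2, ceil(n / group_size))`` so that no group
    exceeds ``group_size`` cells and at least two groups exist per condition;
    sizes differ by at most one (e.g. 41 cells -> five groups sized
    9, 8, 8, 8, 8).  Every cell appears in exactly one group.
    """
    ids = np.asarray(cell_ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 cells to form two informative pseudobulks")
    if group_size < 1:
        raise ValueError("group_size must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    g = max(2, math.ceil(n / group_size))
    perm = ids[rng.permutation(n)]
    base, rem = divmod(n, g)
    groups = []
    offset = 0
    for k in range(g):
        size = base + (1 if k < rem else 0)
        groups.append(perm[offset : offset + size])
        offset += size
    return groups


def _logistic_wald(
    ma: np.ndarray, ta: np.ndarray, mb: np.ndarray, tb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-group binomial-logit Wald test on pooled counts.

    Equivalent to a binomial GLM of per-pseudobulk methylated proportions on
    the condition indicator with prior weights equal to total calls: the MLE
    fitted probabilities are the pooled per-condition proportions, the
    condition coefficient is the logit difference, and its Wald variance is
    1/(T_A p_A q_A) + 1/(T_B p_B q_B).  Tiles with a degenerate proportion
    (0 or 1 in either condition — perfect separation on the logit scale)
    fall back to a likelihood-ratio chi-square test and are flagged.

    Returns ``(difference, p, separated)`` with difference = pooled B - A.
    """
    ma = np.asarray(ma, dtype=float)
    ta = np.asarray(ta, dtype=float)
    mb = np.asarray(mb, dtype=float)
    tb = np.asarray(tb, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = ma / ta
        pb = mb / tb
        diff = pb - pa
        separated = (pa <= 0) | (pa >= 1) | (pb <= 0) | (pb >= 1)
        beta = special.logit(pb) - special.logit(pa)
        var = 1.0 / (ta * pa * (1 - pa)) + 1.0 / (tb * pb * (1 - pb))
        p = 2.0 * stats.norm.sf(np.abs(beta) / np.sqrt(var))
        # LRT fallback under separation: deviance of the two-group fit vs the
        # pooled null, 1 df.  xlogy(0, 0) = 0 handles the boundary MLE.
        p0 = (ma + mb) / (ta + tb)

        def _ll(m, t, prob):
            return special.xlogy(m, prob) + special.xlogy(t - m, 1 - prob)

        dev = 2.0 * (
            _ll(ma, ta, pa) + _ll(mb, tb, pb) - _ll(ma, ta, p0) - _ll(mb, tb, p0)
        )
    if np.any(separated):
        p = np.where(separated, stats.chi2.sf(np.maximum(dev, 0.0), 1), p)
    return diff, p, separated


@dataclass(frozen=True)
class TileTestResult:
    difference: float
    p_value: float
    separated: bool


def test_tile(groups_a, groups_b) -> TileTestResult:
    """Weighted logistic test of one tile from per-pseudobulk counts.

    ``groups_a`` / ``groups_b`` are sequences of ``(methylated, total)``
    pairs, one per pseudobulk.  Every contributing group must have calls.
    """
    ga = np.asarray(groups_a, dtype=float)
    gb = np.asarray(groups_b, dtype=float)
    if np.any(ga[:, 1] <= 0) or np.any(gb[:, 1] <= 0):
        raise ValueError("every pseudobulk must have at least one call")
    diff, p, sep = _logistic_wald(
        ga[:, 0].sum(), ga[:, 1].sum(), gb[:, 0].sum(), gb[:, 1].sum()
    )
    return TileTestResult(float(diff), float(p), bool(sep))


def shuffle_consensus(
    cells_a: list[SingleCellMethylome],
    cells_b: list[SingleCellMethylome],
    tiles: TileSet,
    n_shuffles: int = 100,
    seed: int | None = None,
    group_size: int = 9,
    min_calls: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-tile consensus support table over repeated pseudobulk shuffles.

    For each shuffle the cells of each condition are re-partitioned into
    pseudobulks, tiles where any pseudobulk has fewer than ``min_calls``
    calls are dropped from that shuffle's family, the remaining tiles are
    tested and BH-adjusted within the shuffle, and a tile's support counts
    the shuffles with q < ``fdr``.  The observed difference column is the
    deterministic merged-all-cell pooled difference (condition B - A).

    Deterministic given ``seed``: one master seed spawns an independent
    stream per shuffle.
    """
    n_tiles = len(tiles)
    meth_a, tot_a = cell_tile_counts(cells_a, tiles)
    meth_b, tot_b = cell_tile_counts(cells_b, tiles)
    MA, TA = meth_a.sum(axis=0), tot_a.sum(axis=0)
    MB, TB = meth_b.sum(axis=0), tot_b.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(TA > 0, MA / np.maximum(TA, 1), np.nan)
        frac_b = np.where(TB > 0, MB / np.maximum(TB, 1), np.nan)
    diff_obs = frac_b - frac_a

    # The Wald/LRT p-value depends only on pooled per-condition counts, which
    # every shuffle shares (each partition covers all cells); compute once.
    covered = (TA > 0) & (TB > 0)
    p_tile = np.full(n_tiles, np.nan)
    if covered.any():
        _, p_cov, _ = _logistic_wald(MA[covered], TA[covered], MB[covered], TB[covered])
        p_tile[covered] = p_cov

    support = np.zeros(n_tiles, dtype=np.int64)
    n_testable = np.zeros(n_tiles, dtype=np.int64)
    master = np.random.SeedSequence(seed)
    for child in master.spawn(n_shuffles):
        rng = np.random.default_rng(child)
        idx_a = partition_pseudobulks(np.arange(len(cells_a)), group_size, rng)
        idx_b = partition_pseudobulks(np.arange(len(cells_b)), group_size, rng)
        ga = np.stack([tot_a[g].sum(axis=0) for g in idx_a])
        gb = np.stack([tot_b[g].sum(axis=0) for g in idx_b])
        testable = (ga >= min_calls).all(axis=0) & (gb >= min_calls).all(axis=0)
        testable &= ~np.isnan(p_tile)
        n_testable += testable
        if not testable.any():
            continue
        q = fdr_bh(p_tile[testable])
        hits = np.flatnonzero(testable)[q < fdr]
        support[hits] += 1

    frame = tiles.to_frame().set_index("tile_id")
    frame["meth_a"] = MA
    frame["total_a"] = TA
    frame["meth_b"] = MB
    frame["total_b"] = TB
    frame["difference"] = diff_obs
    frame["p_value"] = p_tile
    frame["support"] = support
    frame["n_testable"] = n_testable
    frame["low_testability"] = n_testable < n_shuffles / 2
    frame.attrs["n_shuffles"] = n_shuffles
    frame.attrs["fdr"] = fdr
    return frame


def call_dmrs(
    support_table: pd.DataFrame,
    min_diff: float = 0.10,
    fdr: float = 0.05,
    min_support: int = 70,
) -> pd.DataFrame:
    """Flag consensus DMRs on a support table from :func:`shuffle_consensus`.

    A tile is called iff |observed difference| >= ``min_diff`` and its
    support reaches ``min_support`` shuffles.
    """
    table = support_table.copy()
    diff_ok = table["difference"].abs() >= min_diff
    table["called"] = diff_ok.fillna(False) & (table["support"] >= min_support)
    table.attrs.update(
        {"min_diff": min_diff, "fdr": fdr, "min_support": min_support}
    )
    return table


class ConsensusDMRCaller(BaseEstimator):
    """Consensus DMR caller over repeated random pseudobulk shufflings.

    Parameters
    ----------
    tiles : TileSet
        The 100-CpG windows tested.
    n_shuffles : int, default 100
        Number of independent pseudobulk re-partitions.
    group_size : int, default 9
        Target pseudobulk size (groups never exceed it).
    min_calls : int, default 10
        Minimum calls per pseudobulk for a tile to be testable in a shuffle.
    fdr : float, default 0.05
        Per-shuffle BH threshold contributing to support.
    min_support : int, default 70
        Minimum supporting shuffles for a consensus call.
    min_diff : float, default 0.10
        Minimum absolute merged-cell methylation difference for a call.
    random_state : int or None
        Master seed; every shuffle draws from an independently spawned
        stream, so results are fully reproducible.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-tile table: observed difference, support, testability, called.
    called_ : pandas.DataFrame
        The subset of ``results_`` with ``called``.
    conditions_ : tuple
        The two condition labels, in the (A, B) order used for the sign of
        the difference.
    """

    def __init__(
        self,
        tiles: TileSet | None = None,
        n_shuffles: int = 100,
        group_size: int = 9,
        min_calls: int = 10,
        fdr: float = 0.05,
        min_support: int = 70,
        min_diff: float = 0.10,
        random_state: int | None = None,
    ) -> None:
        self.tiles = tiles
        self.n_shuffles = n_shuffles
        self.group_size = group_size
        self.min_calls = min_calls
        self.fdr = fdr
        self.min_support = min_support
        self.min_diff = min_diff
        self.random_state = random_state

    def fit(self, X: list[SingleCellMethylome], y) -> "ConsensusDMRCaller":
        """Run the consensus procedure on cells ``X`` with condition labels ``y``."""
        if self.tiles is None:
            raise ValueError("a TileSet must be supplied via the `tiles` parameter")
        labels = np.asarray(y)
        if len(labels) != len(X):
            raise ValueError("y must provide one condition label per cell")
        conds = pd.unique(labels)
        if len(conds) != 2:
            raise ValueError(f"exactly two conditions required, got {list(conds)}")
        cells_a = [c for c, lab in zip(X, labels) if lab == conds[0]]
        cells_b = [c for c, lab in zip(X, labels) if lab == conds[1]]
        table = shuffle_consensus(
            cells_a,
            cells_b,
            self.tiles,
            n_shuffles=self.n_shuffles,
            seed=self.random_state,
            group_size=self.group_size,
            min_calls=self.min_calls,
            fdr=self.fdr,
        )
        self.results_ = call_dmrs(
            table, min_diff=self.min_diff, fdr=self.fdr, min_support=self.min_support
        )
        self.called_ = self.results_[self.results_["called"]]
        self.conditions_ = (conds[0], conds[1])
        self.n_cells_ = (len(cells_a), len(cells_b))
        return self
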