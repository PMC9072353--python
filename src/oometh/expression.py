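"""qPCR ΔCt statistics and count-based CPM comparisons.

Quantitative RT-PCR measures a gene as a quantification cycle (Ct); at
perfect primer efficiency each unit of Ct corresponds to a two-fold change in
template.  Technical replicates of a well are averaged per biological
replicate; ΔCt is taken relative to one housekeeper (within-tissue
comparisons) or the arithmetic mean of three housekeepers (multi-tissue),
which on the expression scale is the geometric mean.  Relative expression is
summarised as the geometric mean of 2^-ΔCt with geometric SD, and the ΔCt
values themselves are retained for significance testing.

Allele-specific assays distinguish the maternal and paternal copies: with
ΔCt = Ct(maternal assay) - Ct(paternal assay), the paternal contribution is
the logistic form paternal% = 100 · 2^ΔCt / (1 + 2^ΔCt), the unique
percentage pair consistent with the ΔCt definition that sums to 100.

Small-RNA count matrices are normalised to counts per million and compared
per feature with unpaired two-sided t-tests under Holm–Šídák correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import holm_sidak

__all__ = [
    "collapse_technical",
    "relative_expression",
    "allelic_split",
    "cpm",
    "cpm_and_test",
]

logger = logging.getLogger(__name__)


def collapse_technical(ct_raw: pd.DataFrame, range_flag: float = 1.0) -> pd.DataFrame:
    """Average technical replicates into one Ct per (sample, gene).

    Expects columns ``sample``, ``gene``, ``ct`` and optionally ``group``.
    Wells whose technical replicates span more than ``range_flag`` cycles are
    flagged (``high_range``) as a quality aid; they are never auto-excluded.
    All-missing wells come back as NaN with a flag.
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct_raw.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    keys = ["sample", "gene"] if "group" not in ct_raw.columns else ["sample", "group", "gene"]
    grouped = ct_raw.groupby(keys, sort=False)["ct"]
    out = grouped.agg(ct="mean", n_technical="count", ct_range=lambda x: x.max() - x.min())
    out["ct_range"] = out["ct_range"].fillna(0.0)
    out["high_range"] = out["ct_range"] > range_flag
    out["all_missing"] = out["n_technical"] == 0
    if out["all_missing"].any():
        logger.warning("%d wells had no usable technical replicate", int(out["all_missing"].sum()))
    return out.reset_index()


def relative_expression(
    ct: pd.DataFrame,
    housekeepers,
    targets=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCt-based relative expression with geometric summaries.

    ``ct`` is a collapsed table (one Ct per sample x gene; columns
    ``sample``, ``group``, ``gene``, ``ct``).  ΔCt = Ct(target) - mean of the
    housekeeper Cts of the same sample; samples missing any housekeeper are
    excluded and logged.  Returns ``(summary, delta)``:

    * ``summary`` — per gene x group: n, geometric mean of 2^-ΔCt and the
      geometric SD (= 2^sd(ΔCt), 1 when replicates agree exactly);
    * ``delta`` — the per-replicate ΔCt values, kept for downstream tests.
    """
    housekeepers = [housekeepers] if isinstance(housekeepers, str) else list(housekeepers)
    wide = ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    missing_hk = [h for h in housekeepers if h not in wide.columns]
    if missing_hk:
        raise ValueError(f"housekeeper(s) {missing_hk} absent from the table")
    hk = wide[housekeepers]
    bad = hk.isna().any(axis=1)
    if bad.any():
        logger.warning("excluding %d sample(s) with missing housekeeper Ct", int(bad.sum()))
        wide = wide.loc[~bad]
        hk = hk.loc[~bad]
    hk_mean = hk.mean(axis=1)

    if targets is None:
        targets = [g for g in wide.columns if g not in housekeepers]
    delta = wide[targets].sub(hk_mean, axis=0)
    delta = delta.reset_index().melt(
        id_vars=["sample", "group"], var_name="gene", value_name="delta_ct"
    ).dropna(subset=["delta_ct"])

    def _summarise(x: pd.Series) -> pd.Series:
        mean_d = x.mean()
        sd_d = x.std(ddof=1)
        return pd.Series(
            {
                "n": len(x),
                "geo_mean": 2.0 ** (-mean_d),
                "geo_sd": 2.0**sd_d if np.isfinite(sd_d) else np.nan,
                "mean_delta_ct": mean_d,
            }
        )

    summary = delta.groupby(["gene", "group"])["delta_ct"].apply(_summarise).unstack()
    summary["n"] = summary["n"].astype(int)
    return summary.reset_index(), delta


def allelic_split(ct_mat, ct_pat) -> pd.DataFrame:
    """Maternal/paternal percentage contributions from allele-specific Cts.

    ΔCt = Ct(maternal assay) - Ct(paternal assay); the paternal share is
    paternal% = 100 · 2^ΔCt / (1 + 2^ΔCt) and maternal% = 100 - paternal%.
    Defined for every finite ΔCt; strictly increasing in ΔCt with limits 0
    and 100 approached but never attained.  Accepts scalars or arrays.
    """
    ct_mat = np.asarray(ct_mat, dtype=float)
    ct_pat = np.asarray(ct_pat, dtype=float)
    if not (np.all(np.isfinite(ct_mat)) and np.all(np.isfinite(ct_pat))):
        raise ValueError("Ct values must be finite")
    delta = ct_mat - ct_pat
    paternal = 100.0 / (1.0 + np.exp2(-delta))
    return pd.DataFrame(
        {
            "delta_ct": np.atleast_1d(delta),
            "paternal_pct": np.atleast_1d(paternal),
            "maternal_pct": np.atleast_1d(100.0 - paternal),
        }
    )


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each sample (column) scaled by its library total."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for sample(s) {bad}")
    return counts / totals * 1e6


def cpm_and_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature CPM group comparison with Holm–Šídák-corrected t-tests.

    ``groups`` maps sample name -> group label (exactly two groups, at least
    two samples each).  The test is the unpaired two-sided Student t-test on
    CPM values (Welch with ``equal_var=False``); identical groups yield
    t = 0, p = 1.  Returns per-feature group means ± SD, t, raw p and
    adjusted p.
    """
    groups = pd.Series(groups)
    labels = pd.unique(groups.loc[counts.columns])
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {list(labels)}")
    cols_a = [c for c in counts.columns if groups[c] == labels[0]]
    cols_b = [c for c in counts.columns if groups[c] == labels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    mat = cpm(counts)
    a = mat[cols_a].to_numpy()
    b = mat[cols_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_diff = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(np.isnan(t) & zero_diff, 0.0, t)
    p = np.where(np.isnan(p) & zero_diff, 1.0, p)
    if np.any(np.isnan(p)):  # zero variance but non-zero difference
        t = np.where(np.isnan(p), np.inf * np.sign(a.mean(axis=1) - b.mean(axis=1)), t)
        p = np.where(np.isnan(p), 0.0, p)
    out = pd.DataFrame(
        {
            f"mean_cpm_{labels[0]}": a.mean(axis=1),
            f"sd_cpm_{labels[0]}": a.std(axis=1, ddof=1),
            f"mean_cpm_{labels[1]}": b.mean(axis=1),
            f"sd_cpm_{labels[1]}": b.std(axis=1, ddof=1),
            "t": t,
            "p_value": p,
        },
        index=counts.index,
    )
    out["p_adjusted"] = holm_sidak(out["p_value"].to_numpy())
    return out
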