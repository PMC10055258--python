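"""Hit calling for the all-by-all nucleating-interaction ("seedability") screen.

Each record of the screen is one DFD (mEos3-fused query) measured in the
presence of one seed, summarised by its log10 C50 and its fraction of
FRET-positive cells (fgate).  A nucleating interaction lowers C50 and raises
fgate.  The pipeline is:

1. standardize log10 C50 and fgate to mean 0 / variance 1 within each
   experimental batch;
2. per DFD, across all of its seeds (negative controls included), compute
   directional outlier degrees: how many interquartile ranges the value lies
   below (C50) or above (fgate) the DFD's median, clipped at zero;
3. seedability = mean of the two degrees;
4. a record is a hit when its seedability is at least 3 standard deviations
   above the mean of all seedability values in the screen.

Replicated screens are compared by Pearson correlation of seedability (with
and without double-negative pairs) and by the hit-call consistency rate with
a Wald binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .netstats import wald_ci

__all__ = [
    "standardize_batch",
    "outlier_degree",
    "seedability_score",
    "ScreenResult",
    "call_hits",
    "ReplicateComparison",
    "replicate_consistency",
]


def standardize_batch(
    df: pd.DataFrame,
    columns=("log10_c50", "fgate"),
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Within-batch z-scores (population SD, ddof=0) of the given columns.

    Adds ``<col>_std`` columns.  Batches with fewer than 2 records or zero
    variance in a column are flagged in ``batch_excluded`` and left NaN.
    """
    out = df.copy()
    out["batch_excluded"] = False
    for col in columns:
        out[f"{col}_std"] = np.nan
    for batch, grp in out.groupby(batch_col):
        if len(grp) < 2:
            out.loc[grp.index, "batch_excluded"] = True
            continue
        for col in columns:
            v = grp[col].to_numpy(float)
            sd = v.std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                out.loc[grp.index, "batch_excluded"] = True
                continue
            out.loc[grp.index, f"{col}_std"] = (v - v.mean()) / sd
    return out


def outlier_degree(values, direction: str) -> np.ndarray:
    """Directional IQR outlier degree of each value within its group.

    ``below``: max(0, (median - x) / IQR); ``above``: max(0, (x - median) /
    IQR).  Requires at least 4 values; an IQR of 0 leaves the degrees
    undefined (NaN) so the group can be flagged upstream.
    """
    v = np.asarray(values, float)
    if v.size < 4:
        raise ValueError("outlier degree requires >= 4 values per DFD")
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.full(v.shape, np.nan)
    if direction == "below":
        deg = (med - v) / iqr
    elif direction == "above":
        deg = (v - med) / iqr
    else:
        raise ValueError("direction must be 'below' or 'above'")
    return np.maximum(deg, 0.0)


def seedability_score(c50_degree, fgate_degree):
    """Seedability = arithmetic mean of the C50-below and fgate-above
    outlier degrees (NaN if either is undefined)."""
    return (np.asarray(c50_degree, float) + np.asarray(fgate_degree, float)) / 2.0


@dataclass
class ScreenResult:
    records: pd.DataFrame
    hit_threshold: float
    n_hits: int
    hit_fraction: float
    negative_control_summary: pd.DataFrame | None


def call_hits(
    df: pd.DataFrame,
    sd_ddof: int = 1,
    dfd_col: str = "dfd",
    seed_col: str = "seed",
    batch_col: str = "batch",
) -> ScreenResult:
    """Standardize, score and call hits on a screen summary table.

    ``df`` needs columns ``dfd, seed, batch, log10_c50, fgate`` and
    optionally ``is_negative_control``.  The hit threshold is mean + 3 SD
    (sample SD by default) of all defined seedability values; a hit has
    seedability at or above it.  A per-DFD diagnostic comparing negative
    controls to other seeds is attached when controls are marked.
    """
    if len(df) < 10:
        raise ValueError("hit calling needs at least 10 screen records")
    rec = standardize_batch(df, batch_col=batch_col)
    rec["c50_outlier_degree"] = np.nan
    rec["fgate_outlier_degree"] = np.nan
    for _, grp in rec.groupby(dfd_col):
        ok = grp.index[~grp["batch_excluded"]]
        if len(ok) < 4:
            continue
        rec.loc[ok, "c50_outlier_degree"] = outlier_degree(
            rec.loc[ok, "log10_c50_std"], "below"
        )
        rec.loc[ok, "fgate_outlier_degree"] = outlier_degree(
            rec.loc[ok, "fgate_std"], "above"
        )
    rec["seedability"] = seedability_score(
        rec["c50_outlier_degree"], rec["fgate_outlier_degree"]
    )
    scores = rec["seedability"].to_numpy(float)
    defined = scores[np.isfinite(scores)]
    if len(defined) < 10:
        raise ValueError("fewer than 10 defined seedability values")
    sd = defined.std(ddof=sd_ddof)
    if sd == 0:
        raise ValueError("seedability has zero variance; threshold undefined")
    threshold = float(defined.mean() + 3.0 * sd)
    rec["is_hit"] = rec["seedability"] >= threshold
    diag = None
    if "is_negative_control" in rec.columns:
        diag = (
            rec.groupby([dfd_col, "is_negative_control"])["seedability"]
            .agg(["median", "max", "count"])
            .reset_index()
        )
    n_hits = int(rec["is_hit"].sum())
    return ScreenResult(
        records=rec,
        hit_threshold=threshold,
        n_hits=n_hits,
        hit_fraction=n_hits / len(rec),
        negative_control_summary=diag,
    )


@dataclass(frozen=True)
class ReplicateComparison:
    pearson_r: float
    pearson_p: float
    pearson_r_no_double_negative: float
    consistency_rate: float
    ci95: tuple[float, float]
    n_matched: int
    n_inconsistent: int


def replicate_consistency(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    dfd_col: str = "dfd",
    seed_col: str = "seed",
) -> ReplicateComparison:
    """Agreement between two replicate screens matched on (DFD, seed).

    Consistency = 1 - inconsistent hit calls / matched pairs, with a Wald
    95% binomial confidence interval.  Pearson correlation of seedability is
    reported for all matched pairs and with double-negative pairs (non-hit in
    both replicates) omitted.  Inputs are `ScreenResult.records` tables (or
    any table with seedability and is_hit columns).
    """
    cols = [dfd_col, seed_col, "seedability", "is_hit"]
    merged = rep1[cols].merge(
        rep2[cols], on=[dfd_col, seed_col], suffixes=("_1", "_2")
    )
    merged = merged.dropna(subset=["seedability_1", "seedability_2"])
    n = len(merged)
    if n == 0:
        raise ValueError("no matched (DFD, seed) records between replicates")
    n_bad = int((merged["is_hit_1"] != merged["is_hit_2"]).sum())
    rate = 1.0 - n_bad / n
    ci = wald_ci(n - n_bad, n)
    r, p = pearsonr(merged["seedability_1"], merged["seedability_2"])
    keep = merged["is_hit_1"] | merged["is_hit_2"]
    if keep.sum() >= 3:
        r_nd, _ = pearsonr(
            merged.loc[keep, "seedability_1"], merged.loc[keep, "seedability_2"]
        )
    else:
        r_nd = np.nan
    return ReplicateComparison(
        pearson_r=float(r),
        pearson_p=float(p),
        pearson_r_no_double_negative=float(r_nd),
        consistency_rate=rate,
        ci95=ci,
        n_matched=n,
        n_inconsistent=n_bad,
    )
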