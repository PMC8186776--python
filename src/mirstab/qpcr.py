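"""qPCR Ct-table analysis: raw-Ct stability, dCt normalization, paired tests.

A Ct table holds one threshold-cycle value per (sample, assay); undetected
reactions are missing (NaN), never imputed.  The standard deviation of raw
Ct values across samples measures an assay's stability as an internal
control.  dCt = Ct(target) - Ct(internal control) normalizes away
sample-level input variation; lower dCt means higher relative expression,
so tumor up-regulation shows as a *negative* tumor-minus-normal dCt shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataError, complete_pairs


def read_ct(path) -> pd.DataFrame:
    """Read a long Ct TSV (sample_id, assay, ct; empty ct = undetected)."""
    long = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay": str})
    for col in ("sample_id", "assay", "ct"):
        if col not in long.columns:
            raise DataError(f"Ct table missing column {col!r}")
    return ct_table_from_long(long)


def ct_table_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (sample_id, assay, ct) frame to samples x assays."""
    if long.duplicated(["sample_id", "assay"]).any():
        raise DataError("duplicate (sample, assay) Ct entries; collapse replicates first")
    wide = long.pivot(index="sample_id", columns="assay", values="ct")
    return wide.astype(float)


def collapse_replicates(long: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Cts per (sample, assay); records the replicate SD."""
    g = long.groupby(["sample_id", "assay"])["ct"]
    out = g.agg(ct="mean", ct_sd=lambda v: v.std(ddof=1), n_replicates="count")
    return out.reset_index()


@dataclass(frozen=True)
class CtStability:
    assay: str
    sd: float
    median: float
    n_detected: int
    n_undetected: int


def ct_stability(ct: pd.DataFrame, assay: str) -> CtStability:
    """Sample SD (n-1) and median of detected raw Cts for one assay."""
    if assay not in ct.columns:
        raise DataError(f"assay {assay!r} not in Ct table")
    vals = ct[assay].dropna()
    if len(vals) < 2:
        raise DataError(f"assay {assay!r} detected in fewer than 2 samples")
    return CtStability(
        assay=assay,
        sd=float(vals.std(ddof=1)),
        median=float(vals.median()),
        n_detected=int(len(vals)),
        n_undetected=int(ct[assay].isna().sum()),
    )


@dataclass(frozen=True)
class DeltaCtResult:
    target: str
    ic: str
    delta_ct: pd.Series  # per sample, only samples with both Cts
    n_dropped: int
    group_summary: pd.DataFrame | None  # per tissue: n, mean, sd, median


def delta_ct(
    ct: pd.DataFrame, target: str, ic: str, meta: pd.DataFrame | None = None
) -> DeltaCtResult:
    """Per-sample dCt = Ct(target) - Ct(internal control).

    Samples where either assay is undetected are dropped and counted
    (never imputed).  With metadata, tumor/normal group summaries are
    attached.
    """
    for assay in (target, ic):
        if assay not in ct.columns:
            raise DataError(f"assay {assay!r} not in Ct table")
    both = ct[[target, ic]].dropna()
    if both.empty:
        raise DataError(f"no samples detected for both {target!r} and {ic!r}")
    d = (both[target] - both[ic]).rename("delta_ct")
    summary = None
    if meta is not None:
        tissue = meta.set_index("sample_id")["tissue"].reindex(d.index)
        summary = (
            d.groupby(tissue)
            .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1), median="median")
            .rename_axis("tissue")
        )
    return DeltaCtResult(
        target=target,
        ic=ic,
        delta_ct=d,
        n_dropped=int(len(ct) - len(both)),
        group_summary=summary,
    )


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p: float
    direction: str  # "up" (higher expression in tumor), "down" or "none"
    n_pairs: int
    method: str


def paired_expression_test(
    d: DeltaCtResult, meta: pd.DataFrame, method: str = "wilcoxon"
) -> PairedTestResult:
    """Two-sided paired test of tumor vs matched-normal dCt.

    Default Wilcoxon signed-rank (exact for small pair counts without
    ties); ``method="ttest"`` switches to the paired t-test.  Direction
    "up" means lower dCt in tumor, i.e. target up-regulated relative to
    the internal control.
    """
    pairs = [
        (t, n)
        for t, n in complete_pairs(meta)
        if t in d.delta_ct.index and n in d.delta_ct.index
    ]
    if len(pairs) < 3:
        raise DataError("paired test needs at least 3 complete pairs with dCt")
    dt = d.delta_ct[[t for t, _ in pairs]].to_numpy()
    dn = d.delta_ct[[n for _, n in pairs]].to_numpy()
    diff = dt - dn
    if np.allclose(diff, 0.0):
        return PairedTestResult(0.0, 1.0, "none", len(pairs), method)
    if method == "wilcoxon":
        res = stats.wilcoxon(dt, dn, alternative="two-sided")
    elif method == "ttest":
        res = stats.ttest_rel(dt, dn)
    else:
        raise ValueError(f"unknown test method {method!r}")
    mean_shift = float(diff.mean())
    direction = "up" if mean_shift < 0 else "down"
    return PairedTestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        direction=direction,
        n_pairs=len(pairs),
        method=method,
    )
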