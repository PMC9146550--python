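"""Relative qPCR quantification by the comparative-Ct (ddCt) method.

Cycle thresholds are averaged over technical replicates, normalized
within each sample against the housekeeping reference (dCt = Ct_target -
Ct_HK, where the reference is the mean housekeeping Ct — for several
housekeeping genes this equals the geometric mean of their linear-scale
expression), then referenced to the vehicle-control condition (ddCt =
dCt_treated - mean dCt_control).  Fold change is 2^-ddCt, so log2 fold
change is -ddCt; amplification efficiency is fixed at 2.

Biological replicates are the statistical unit: technical replicates are
averaged first so they never inflate n.  Group differences are assessed
with a two-sided Welch two-sample t-test on the replicate dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionResult",
    "aggregate_technical",
    "delta_ct",
    "ddct_foldchange",
    "test_expression",
    "ddct_analysis",
]

DEFAULT_HOUSEKEEPING = frozenset({"GAPDH"})

REQUIRED_COLUMNS = ("sample", "condition", "gene", "ct")


def _validate(ct: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise KeyError(f"Ct table lacks column(s) {missing}")
    vals = ct["ct"].astype(float)
    if not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValueError("Ct values must be finite and positive")


def aggregate_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one Ct per (sample, gene).

    Returns the collapsed table with a ``ct_tech_sd`` column reporting
    the technical spread.  Tables without a ``tech_rep`` column pass
    through unchanged apart from the added (zero-spread) column.
    """
    _validate(ct)
    keys = ["sample", "condition", "gene"]
    if "bio_rep" in ct.columns:
        keys.append("bio_rep")
    grouped = ct.groupby(keys, sort=True)["ct"].agg(["mean", "std", "count"]).reset_index()
    grouped = grouped.rename(columns={"mean": "ct", "std": "ct_tech_sd", "count": "n_tech"})
    grouped["ct_tech_sd"] = grouped["ct_tech_sd"].fillna(0.0)
    return grouped


def delta_ct(
    ct: pd.DataFrame, housekeeping: frozenset[str] | set[str] = DEFAULT_HOUSEKEEPING
) -> pd.DataFrame:
    """Normalize target Cts against the within-sample housekeeping reference.

    ``dCt = Ct_target - HK_ref`` with ``HK_ref`` the arithmetic mean of
    the housekeeping genes' Cts in that sample (equivalently the log2 of
    the geometric mean of their linear-scale signals).  dCt is invariant
    to any constant added to every Ct of a sample, which removes global
    per-sample efficiency offsets.
    """
    _validate(ct)
    hk = {g for g in housekeeping}
    is_hk = ct["gene"].isin(hk)
    refs = ct[is_hk].groupby("sample")["ct"].mean()
    targets = ct[~is_hk]
    missing = sorted(set(targets["sample"]) - set(refs.index))
    if missing:
        raise ValueError(f"sample(s) missing housekeeping measurements: {missing[:5]}")
    out = targets.copy()
    out["dct"] = out["ct"].astype(float) - out["sample"].map(refs).astype(float)
    return out.reset_index(drop=True)


@dataclass
class ExpressionResult:
    """Per-condition fold changes with replicate-level detail.

    ``per_replicate`` holds one row per (sample, gene) with ddCt, log2
    fold change and fold change; ``summary`` one row per (condition,
    gene) with the mean log2FC, 2^mean fold change, n and (after
    :func:`test_expression`) the p-value.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    control_label: str
    test_method: str | None = None
    housekeeping: list[str] = field(default_factory=lambda: sorted(DEFAULT_HOUSEKEEPING))

    def write(self, path: str | Path) -> None:
        self.summary.to_csv(path, index=False)

    def write_replicates(self, path: str | Path) -> None:
        self.per_replicate.to_csv(path, index=False)


def ddct_foldchange(dcts: pd.DataFrame, control_label: str) -> ExpressionResult:
    """Reference dCts to the control condition and compute fold changes.

    Per gene, ``ddCt = dCt - mean(dCt over control samples)``; per
    replicate ``log2FC = -ddCt`` and ``FC = 2^-ddCt``; the condition
    summary is the mean of replicate log2FCs.  The control condition's
    own mean log2FC is 0 by construction.
    """
    if "dct" not in dcts.columns:
        raise KeyError("expected a 'dct' column; run delta_ct first")
    if not (dcts["condition"] == control_label).any():
        raise ValueError(f"no control condition {control_label!r} in the dCt table")
    parts = []
    for gene, group in dcts.groupby("gene", sort=True):
        ctrl = group.loc[group["condition"] == control_label, "dct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control replicates")
        g = group.copy()
        g["ddct"] = g["dct"] - float(ctrl.mean())
        parts.append(g)
    rep = pd.concat(parts, ignore_index=True)
    rep["log2fc"] = -rep["ddct"]
    rep["fold_change"] = 2.0 ** rep["log2fc"]
    summary = (
        rep.groupby(["condition", "gene"], sort=True)["log2fc"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_log2fc", "count": "n"})
    )
    summary["fold_change"] = 2.0 ** summary["mean_log2fc"]
    return ExpressionResult(rep, summary, control_label)


def test_expression(result: ExpressionResult, method: str = "welch") -> ExpressionResult:
    """Attach two-sided p-values for treated-vs-control expression shifts.

    The test runs on the per-replicate dCt values (equivalently on
    log2FC, which differs by a constant): Welch's unequal-variance
    two-sample t-test by default, or Student's with ``method="student"``.
    Conditions with fewer than two replicates in either group get no
    p-value and an ``insufficient_n`` flag.
    """
    if method not in {"welch", "student"}:
        raise ValueError(f"unknown test method {method!r}")
    rep = result.per_replicate
    pvals: list[float] = []
    flags: list[bool] = []
    for _, row in result.summary.iterrows():
        cond, gene = row["condition"], row["gene"]
        if cond == result.control_label:
            pvals.append(np.nan)
            flags.append(False)
            continue
        treated = rep.loc[(rep["condition"] == cond) & (rep["gene"] == gene), "dct"]
        control = rep.loc[
            (rep["condition"] == result.control_label) & (rep["gene"] == gene), "dct"
        ]
        if len(treated) < 2 or len(control) < 2:
            pvals.append(np.nan)
            flags.append(True)
            continue
        res = stats.ttest_ind(treated, control, equal_var=(method == "student"))
        pvals.append(float(res.pvalue))
        flags.append(False)
    summary = result.summary.copy()
    summary["p_value"] = pvals
    summary["insufficient_n"] = flags
    return ExpressionResult(rep, summary, result.control_label, test_method=method,
                            housekeeping=result.housekeeping)


def ddct_analysis(
    ct: pd.DataFrame,
    control_label: str,
    housekeeping: frozenset[str] | set[str] = DEFAULT_HOUSEKEEPING,
    test_method: str = "welch",
) -> ExpressionResult:
    """Full pipeline: technical averaging -> dCt -> ddCt -> significance test."""
    agg = aggregate_technical(ct)
    dcts = delta_ct(agg, housekeeping=housekeeping)
    result = ddct_foldchange(dcts, control_label)
    result.housekeeping = sorted(housekeeping)
    return test_expression(result, method=test_method)
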