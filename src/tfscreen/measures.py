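"""Raw readouts -> measured parameters, fold changes and significance calls.

Three parameters are derived per culture: growth (OD600), total reporter
protein (FU) and biomass-normalized reporter protein (RFU = FU / OD600).
Per (strain, condition variant) the replicate values are summarized, and each
TF-overexpression strain is compared against the control strain measured under
the identical condition: the fold change FC = mean(TF) / mean(control), with a
per-condition two-group one-way ANOVA significance call at alpha = 0.05.

Aggregation convention: FC is the ratio of per-variant replicate means (not
the mean of per-replicate ratios); RFU is computed per replicate first, then
averaged.  No multiple-testing correction is applied by default, matching the
per-condition reporting this pipeline emulates; Benjamini-Hochberg can be
switched on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .design import RunPlan, plan_frame
from .errors import MeasureError

__all__ = [
    "MEASURES",
    "normalized_rprot",
    "summarize_measures",
    "fold_change",
    "significance_test",
    "fold_change_table",
]

log = logging.getLogger(__name__)

MEASURES = ("growth", "total_rprot", "normalized_rprot")

DEFAULT_ALPHA = 0.05


def normalized_rprot(fu: float, od600: float) -> float:
    """Specific (biomass-normalized) fluorescence: RFU = FU / OD600."""
    if od600 <= 0:
        raise MeasureError(f"degenerate culture: od600={od600} (must be > 0)")
    return fu / od600


def _measure_frame(readouts: pd.DataFrame, plan: RunPlan) -> pd.DataFrame:
    """Per-culture long table with the three measures; degenerate wells
    (od600 <= 0) are flagged, logged and excluded rather than imputed."""
    bad = readouts["od600"] <= 0
    if bad.any():
        log.warning("excluding %d degenerate wells (od600 <= 0)", int(bad.sum()))
    clean = readouts.loc[~bad].copy()
    if clean.empty:
        raise MeasureError("no usable readouts after excluding degenerate wells")
    run_to_variant = plan_frame(plan).set_index("run_id")["variant_id"]
    clean["variant_id"] = clean["run_id"].map(run_to_variant)
    if clean["variant_id"].isna().any():
        raise MeasureError("readouts reference run ids absent from the plan")
    long = clean.melt(
        id_vars=["strain_id", "variant_id"],
        value_vars=["od600", "fu"],
        var_name="measure", value_name="value",
    )
    long["measure"] = long["measure"].map({"od600": "growth", "fu": "total_rprot"})
    rfu = clean[["strain_id", "variant_id"]].copy()
    rfu["measure"] = "normalized_rprot"
    rfu["value"] = clean["fu"].to_numpy() / clean["od600"].to_numpy()
    return pd.concat([long, rfu], ignore_index=True)


def summarize_measures(readouts: pd.DataFrame, plan: RunPlan) -> pd.DataFrame:
    """Per (strain, variant, measure): replicate mean, SD (n >= 2 only) and n."""
    long = _measure_frame(readouts, plan)
    g = long.groupby(["strain_id", "variant_id", "measure"], sort=True)["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def fold_change(tf_mean: float, control_mean: float) -> float:
    """FC = TF mean over control mean at the identical condition."""
    if not control_mean > 0:
        raise MeasureError(f"control mean must be > 0, got {control_mean}")
    return tf_mean / control_mean


def significance_test(tf_replicates, control_replicates, alpha: float = DEFAULT_ALPHA):
    """Two-group one-way ANOVA; returns (p_value, significant).

    With fewer than two replicates in either group the comparison is
    insufficiently replicated: p is missing and the call is non-significant.
    Zero between-group variance yields p = 1 (no evidence of a difference).
    """
    a = np.asarray(tf_replicates, dtype=float)
    b = np.asarray(control_replicates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return np.nan, False
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(a, b)
    if np.isnan(p):
        # constant groups: identical means carry no evidence, distinct means are
        # separated with zero within-group variance
        p = 1.0 if a.mean() == b.mean() else 0.0
    return float(p), bool(p < alpha)


def fold_change_table(
    readouts: pd.DataFrame,
    plan: RunPlan,
    control: str,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per (strain, variant, measure) fold changes vs the control strain.

    Columns: strain_id, variant_id, measure, fc, p_value, significant.  The
    control is matched on the identical variant; rows for the control strain
    itself are included (FC exactly 1, a self-normalization check).  With
    ``fdr=True`` Benjamini-Hochberg adjusted p-values replace the raw ones
    within each strain x measure family.
    """
    long = _measure_frame(readouts, plan)
    if control not in set(long["strain_id"]):
        raise MeasureError(f"control strain {control!r} absent from readouts")

    ctrl = long[long["strain_id"] == control]
    ctrl_groups = {k: v["value"].to_numpy() for k, v in ctrl.groupby(["variant_id", "measure"])}

    records = []
    for (strain, variant, measure), sub in long.groupby(["strain_id", "variant_id", "measure"], sort=True):
        key = (variant, measure)
        if key not in ctrl_groups:
            raise MeasureError(f"control has no data for variant {variant}, measure {measure}")
        cvals = ctrl_groups[key]
        cmean = cvals.mean()
        fc = fold_change(sub["value"].mean(), cmean)
        if strain == control:
            p, sig = 1.0, False
        else:
            p, sig = significance_test(sub["value"].to_numpy(), cvals, alpha)
        records.append((strain, variant, measure, fc, p, sig))
    out = pd.DataFrame(records, columns=["strain_id", "variant_id", "measure", "fc", "p_value", "significant"])

    if fdr:
        from statsmodels.stats.multitest import multipletests
        for (_, _), idx in out.groupby(["strain_id", "measure"]).groups.items():
            pvals = out.loc[idx, "p_value"]
            ok = pvals.notna()
            if ok.any():
                adj = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[1]
                out.loc[pvals[ok].index, "p_value"] = adj
        out["significant"] = out["p_value"] < alpha
    return out
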