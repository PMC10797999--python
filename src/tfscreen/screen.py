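"""Database-style condition-responsive queries and phenotype classification.

Queries mirror the semantics of a condition-responsive screen search: a hit
must be statistically significant AND clear a 10% fold-change margin around
the null FC of 1 (up: FC >= 1.1, down: FC <= 0.9 by default).  The "inverted
phenotype" search finds strains responding in opposite directions at the two
extreme levels of a single variable, with every other variable held at
matched settings.  Results are ranked by the highest FC (up), lowest FC
(down) or largest FC delta between the extremes (inverted); ties break on
strain id so output is deterministic.

The classifier condenses a strain's full fold-change profile into a phenotype
call (global r-Prot enhancer / silencer, growth enhancement or sensitivity
under oxygen limitation, or none), using thresholds generalized from the
descriptive ranges such phenotypes show in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Factor
from .errors import QueryError, MeasureError
from .rsm import factor_contribution, fit_rsm, signed_level_contribution

__all__ = [
    "QueryConstraint",
    "PhenotypeCall",
    "ClassifierThresholds",
    "query",
    "correlate_fc",
    "classify",
]


@dataclass(frozen=True)
class QueryConstraint:
    """A database-style search constraint on one measure and one variable."""

    measure: str  # growth | total_rprot | normalized_rprot
    direction: str  # up | down | inverted
    variable: str  # factor name
    level: float | None = None  # constraining coded level (up/down)
    alpha: float = 0.05
    fc_margin: float = 0.10

    def __post_init__(self):
        if self.direction not in ("up", "down", "inverted"):
            raise QueryError(f"unknown direction {self.direction!r}")
        if self.fc_margin < 0:
            raise QueryError("fc_margin must be >= 0")
        if self.direction != "inverted" and self.level not in (-1, 0, 1):
            raise QueryError(f"level must be a coded level in {{-1, 0, +1}}, got {self.level}")


@dataclass(frozen=True)
class PhenotypeCall:
    """Classifier output for one strain, with the evidence behind the label."""

    strain: str
    label: str
    evidence: dict = field(default_factory=dict)


def _joined(fc_records: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    return fc_records.merge(design, on="variant_id", validate="m:1")


def query(fc_records: pd.DataFrame, design: pd.DataFrame,
          constraint: QueryConstraint) -> pd.DataFrame:
    """Run one condition-responsive search over a fold-change table.

    ``fc_records`` is the measures-module FC table; ``design`` the design
    frame (variant_id + coded columns).  Returns one row per hit strain with
    its sort key and the list of qualifying condition combinations, ranked
    per the direction's sort rule.
    """
    col = f"coded_{constraint.variable}"
    if col not in design.columns:
        raise QueryError(f"unknown variable {constraint.variable!r}")
    sub = _joined(fc_records, design)
    sub = sub[sub["measure"] == constraint.measure]
    if sub.empty:
        raise QueryError(f"no records for measure {constraint.measure!r}")
    hi = 1.0 + constraint.fc_margin
    lo = 1.0 - constraint.fc_margin

    if constraint.direction in ("up", "down"):
        if constraint.level not in set(sub[col]):
            raise QueryError(f"level {constraint.level} not screened for {constraint.variable!r}")
        at = sub[sub[col] == constraint.level]
        sig = at["significant"].fillna(False).astype(bool)
        if constraint.direction == "up":
            hits = at[sig & (at["fc"] >= hi)]
        else:
            hits = at[sig & (at["fc"] <= lo)]
        rows = []
        coded_cols = [c for c in design.columns if c.startswith("coded_")]
        for strain, grp in hits.groupby("strain_id"):
            key = grp["fc"].max() if constraint.direction == "up" else grp["fc"].min()
            conds = grp.sort_values("variant_id")[["variant_id"] + coded_cols].to_dict("records")
            rows.append({"strain_id": strain, "sort_key": float(key), "conditions": conds})
        asc = constraint.direction == "down"
        out = pd.DataFrame(rows, columns=["strain_id", "sort_key", "conditions"])
        return out.sort_values(["sort_key", "strain_id"], ascending=[asc, True],
                               ignore_index=True)

    # inverted: pair extreme levels of the variable at matched other settings
    other = [c for c in design.columns if c.startswith("coded_") and c != col]
    lo_lvl, hi_lvl = -1.0, 1.0
    a = sub[sub[col] == lo_lvl]
    b = sub[sub[col] == hi_lvl]
    pair = a.merge(b, on=["strain_id"] + other, suffixes=("_lo", "_hi"))
    sig = pair["significant_lo"].astype(bool) & pair["significant_hi"].astype(bool)
    up_lo = (pair["fc_lo"] >= hi) & (pair["fc_hi"] <= lo)
    up_hi = (pair["fc_hi"] >= hi) & (pair["fc_lo"] <= lo)
    hits = pair[sig & (up_lo | up_hi)].copy()
    hits["delta"] = (hits["fc_lo"] - hits["fc_hi"]).abs()
    rows = []
    for strain, grp in hits.groupby("strain_id"):
        conds = grp.sort_values("variant_id_lo")[
            ["variant_id_lo", "variant_id_hi", "fc_lo", "fc_hi", "delta"] + other
        ].to_dict("records")
        rows.append({"strain_id": strain, "sort_key": float(grp["delta"].max()),
                     "conditions": conds})
    out = pd.DataFrame(rows, columns=["strain_id", "sort_key", "conditions"])
    return out.sort_values(["sort_key", "strain_id"], ascending=[False, True],
                           ignore_index=True)


def correlate_fc(growth_fc, rprot_fc) -> float:
    """Pearson correlation between two condition-matched FC vectors.

    Used to diagnose whether growth and reporter-protein synthesis respond
    synergistically (r high) or compete (r low) in a strain.  Returns NaN when
    either vector has zero variance.
    """
    a = np.asarray(growth_fc, dtype=float)
    b = np.asarray(rprot_fc, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise QueryError("FC vectors must be condition-matched with length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


@dataclass(frozen=True)
class ClassifierThresholds:
    """Rule thresholds for the phenotype classifier (see :func:`classify`)."""

    growth_neutral_band: float = 0.05     # |mean growth FC - 1| for "growth unaffected"
    silencer_max_fc: float = 0.50         # mean normalized r-Prot FC ceiling
    enhancer_min_fc: float = 1.25         # mean normalized r-Prot FC floor
    min_significant_frac: float = 0.50    # share of conditions that must be significant
    oa_enhancer_min_growth_fc: float = 1.05   # mean growth FC under low oxygen
    oa_sensitive_max_growth_fc: float = 0.95


def classify(
    strain_fc: pd.DataFrame,
    design: pd.DataFrame,
    factors: list[Factor],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    control_growth_contribution: pd.DataFrame | None = None,
) -> PhenotypeCall:
    """Rule-based phenotype call for one strain's full FC profile.

    Rules, applied in precedence order (first match wins):

    1. global_rprot_silencer — growth unaffected (|mean growth FC - 1| within
       the neutral band) and mean normalized r-Prot FC <= 0.5 with at least
       half the conditions significant.
    2. global_rprot_enhancer — mean normalized r-Prot FC >= 1.25 with at least
       half the conditions significant.
    3. oa_growth_enhancer — mean growth FC under low oxygen >= 1.05 and a
       positive low-oxygen growth-contribution delta vs the control (fitted on
       FC values).
    4. oa_sensitive — mean growth FC under low oxygen <= 0.95 and a negative
       low-oxygen delta.
    5. none.

    The low-oxygen contribution delta comes from an FC-mode response-surface
    fit of the strain's growth FC; ``control_growth_contribution`` is the
    control's table (all-zero when the control is normalized against itself).
    """
    missing = set(("growth", "total_rprot", "normalized_rprot")) - set(strain_fc["measure"])
    if missing:
        raise MeasureError(f"strain FC profile missing measures: {sorted(missing)}")
    strain = strain_fc["strain_id"].iloc[0]
    joined = _joined(strain_fc, design)

    growth = joined[joined["measure"] == "growth"]
    nrp = joined[joined["measure"] == "normalized_rprot"]
    mean_growth = float(growth["fc"].mean())
    mean_nrp = float(nrp["fc"].mean())
    sig_frac = float(nrp["significant"].mean())
    low_oa_growth = float(growth.loc[growth["coded_oxygen"] == -1, "fc"].mean())

    # FC-mode growth surface for the oxygen-contribution rules
    gfit = fit_rsm(growth, response="fc", factors=factors, mode="fc",
                   strain=strain, measure="growth")
    gtable = factor_contribution(gfit)
    signed_low_oa = signed_level_contribution(gtable, "oxygen", toward=-1)
    if control_growth_contribution is not None:
        signed_low_oa -= signed_level_contribution(control_growth_contribution, "oxygen", toward=-1)

    r = correlate_fc(growth["fc"], joined.loc[joined["measure"] == "total_rprot", "fc"])
    evidence = {
        "mean_growth_fc": mean_growth,
        "mean_normalized_rprot_fc": mean_nrp,
        "significant_fraction": sig_frac,
        "mean_low_oa_growth_fc": low_oa_growth,
        "low_oa_growth_delta": signed_low_oa,
        "growth_rprot_pearson_r": r,
    }

    t = thresholds
    if (abs(mean_growth - 1.0) <= t.growth_neutral_band
            and mean_nrp <= t.silencer_max_fc
            and sig_frac >= t.min_significant_frac):
        label = "global_rprot_silencer"
    elif mean_nrp >= t.enhancer_min_fc and sig_frac >= t.min_significant_frac:
        label = "global_rprot_enhancer"
    elif low_oa_growth >= t.oa_enhancer_min_growth_fc and signed_low_oa > 0:
        label = "oa_growth_enhancer"
    elif low_oa_growth <= t.oa_sensitive_max_growth_fc and signed_low_oa < 0:
        label = "oa_sensitive"
    else:
        label = "none"
    return PhenotypeCall(strain=strain, label=label, evidence=evidence)
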