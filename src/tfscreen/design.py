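"""Face-centered central composite designs over mixed numeric/categoric factors.

A face-centered CCD places its axial ("star") points on the +/-1 faces of the
coded cube, so every numeric factor is screened at exactly three levels
(-1, 0, +1).  Categoric factors are restricted to two levels and the numeric
point set is crossed with every categoric level combination.  The design is
then expanded into a replicated, seed-randomized run plan: condition variants
whose numeric factors all sit at the center ("central variants") are replicated
more heavily than the outer variants, giving a pure-error estimate at the
center of the response surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

__all__ = [
    "Factor",
    "ConditionVariant",
    "RunPlan",
    "default_screen_factors",
    "build_fcccd",
    "replicate_plan",
    "coded_to_actual",
    "actual_to_coded",
    "design_frame",
    "plan_frame",
]


@dataclass(frozen=True)
class Factor:
    """One screened experimental variable with its coded <-> actual mapping.

    Numeric factors map code -1 to ``low``, +1 to ``high`` and 0 to ``center``
    (midpoint by default).  Categoric factors have exactly the two levels
    ``low`` (code -1) and ``high`` (code +1).
    """

    name: str
    kind: str  # "numeric" | "categoric"
    low: object
    high: object
    center: object | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categoric"):
            raise DesignError(f"factor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "numeric":
            lo, hi = float(self.low), float(self.high)
            if not lo < hi:
                raise DesignError(f"factor {self.name!r}: low must be < high")
            center = (lo + hi) / 2.0 if self.center is None else float(self.center)
            if not lo < center < hi:
                raise DesignError(f"factor {self.name!r}: center outside (low, high)")
            object.__setattr__(self, "low", lo)
            object.__setattr__(self, "high", hi)
            object.__setattr__(self, "center", center)
        else:
            if self.center is not None:
                raise DesignError(f"categoric factor {self.name!r} cannot have a center level")
            if self.low == self.high:
                raise DesignError(f"categoric factor {self.name!r} needs two distinct levels")


@dataclass(frozen=True)
class ConditionVariant:
    """One fully specified environmental condition of the design."""

    variant_id: int
    coded: tuple[float, ...]
    actual: tuple[object, ...]
    role: str  # "central" | "outer"


@dataclass
class RunPlan:
    """Replicated, randomized execution schedule for one screening campaign.

    ``runs`` holds (run_id, variant_id, technical_rep_index, execution_order)
    tuples; ``bio_reps`` is recorded for downstream expansion into cultures.
    """

    runs: list[tuple[int, int, int, int]]
    variants: list[ConditionVariant]
    factors: list[Factor]
    central_reps: int
    outer_reps: int
    bio_reps: int
    seed: int = field(repr=False, default=0)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_cultures(self) -> int:
        """Total cultures per strain: runs x biological replicates."""
        return self.n_runs * self.bio_reps


def default_screen_factors() -> list[Factor]:
    """The five-variable screening setup: three binary categoric factors
    (oxygen availability, carbon source, nitrogen source) and two numeric
    factors (pH 3-7, temperature 22-34 degC)."""
    return [
        Factor("oxygen", "categoric", low="low", high="high", unit="headspace exchange"),
        Factor("carbon", "categoric", low="glucose", high="glycerol", unit="carbon source"),
        Factor("nitrogen", "categoric", low="ammonium sulfate", high="casamino acids",
               unit="nitrogen source"),
        Factor("pH", "numeric", low=3.0, high=7.0, unit="pH"),
        Factor("temperature", "numeric", low=22.0, high=34.0, unit="degC"),
    ]


def coded_to_actual(factor: Factor, code: float):
    """Map a coded level to the actual factor value.

    Numeric factors interpolate linearly between ``low`` (-1) and ``high``
    (+1); categoric factors accept only the codes -1 and +1.
    """
    if factor.kind == "numeric":
        if not -1.0 <= code <= 1.0:
            raise DesignError(f"factor {factor.name!r}: code {code} outside [-1, +1]")
        if code == 0:
            return factor.center
        if code < 0:
            return factor.center + (factor.center - factor.low) * code
        return factor.center + (factor.high - factor.center) * code
    if code == -1:
        return factor.low
    if code == 1:
        return factor.high
    raise DesignError(f"categoric factor {factor.name!r}: code must be -1 or +1, got {code}")


def actual_to_coded(factor: Factor, actual) -> float:
    """Inverse of :func:`coded_to_actual` (exact roundtrip)."""
    if factor.kind == "numeric":
        x = float(actual)
        if not factor.low <= x <= factor.high:
            raise DesignError(f"factor {factor.name!r}: value {x} outside [{factor.low}, {factor.high}]")
        if x == factor.center:
            return 0.0
        if x < factor.center:
            return (x - factor.center) / (factor.center - factor.low)
        return (x - factor.center) / (factor.high - factor.center)
    if actual == factor.low:
        return -1.0
    if actual == factor.high:
        return 1.0
    raise DesignError(f"categoric factor {factor.name!r}: unknown level {actual!r}")


def _ccd_numeric_points(k: int) -> list[tuple[float, ...]]:
    """Face-centered CCD point set for k numeric factors: 2^k factorial
    corners, 2k face-axial points (alpha = 1) and the center, deduplicated."""
    points: dict[tuple[float, ...], None] = {}
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        points[corner] = None
    for axis in range(k):
        for sign in (-1.0, 1.0):
            pt = [0.0] * k
            pt[axis] = sign
            points[tuple(pt)] = None
    points[tuple([0.0] * k)] = None
    return list(points)


def build_fcccd(factors: list[Factor]) -> list[ConditionVariant]:
    """Build the face-centered CCD crossed with all categoric combinations.

    Returns condition variants with dense 1-based ids; a variant is ``central``
    iff all its numeric codes are 0.  With k=2 numeric factors the deduplicated
    point set is the full 3x3 grid, so three binary categoric factors give
    9 * 2^3 = 72 variants, 8 of them central.
    """
    if not factors:
        raise DesignError("empty factor list: cannot build a design")
    numeric = [f for f in factors if f.kind == "numeric"]
    categoric = [f for f in factors if f.kind == "categoric"]
    if not numeric:
        raise DesignError("need at least one numeric factor for a central composite design")

    num_points = _ccd_numeric_points(len(numeric))
    cat_combos = list(itertools.product((-1.0, 1.0), repeat=len(categoric))) or [()]

    num_idx = {f.name: i for i, f in enumerate(numeric)}
    cat_idx = {f.name: i for i, f in enumerate(categoric)}

    variants: list[ConditionVariant] = []
    vid = 1
    for cat in cat_combos:
        for pt in num_points:
            coded = tuple(
                pt[num_idx[f.name]] if f.kind == "numeric" else cat[cat_idx[f.name]]
                for f in factors
            )
            actual = tuple(coded_to_actual(f, c) for f, c in zip(factors, coded))
            role = "central" if all(c == 0 for c in pt) else "outer"
            variants.append(ConditionVariant(vid, coded, actual, role))
            vid += 1
    return variants


def replicate_plan(
    variants: list[ConditionVariant],
    factors: list[Factor],
    central_reps: int = 5,
    outer_reps: int = 1,
    bio_reps: int = 2,
    seed: int | None = None,
) -> RunPlan:
    """Expand variants into a replicated run plan with randomized execution order.

    Central variants are scheduled ``central_reps`` times, outer variants
    ``outer_reps`` times.  The execution order is a uniform random permutation
    drawn from ``numpy.random.default_rng(seed)``; the seed is mandatory so the
    schedule is reproducible.
    """
    if seed is None:
        raise DesignError("replicate_plan requires an explicit seed (reproducibility contract)")
    if min(central_reps, outer_reps, bio_reps) < 1:
        raise DesignError("replication counts must be >= 1")

    runs: list[tuple[int, int, int, int]] = []
    run_id = 1
    for v in variants:
        reps = central_reps if v.role == "central" else outer_reps
        for rep in range(1, reps + 1):
            runs.append((run_id, v.variant_id, rep, 0))
            run_id += 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(runs)) + 1
    runs = [(rid, vid, rep, int(o)) for (rid, vid, rep, _), o in zip(runs, order)]
    return RunPlan(runs, list(variants), list(factors), central_reps, outer_reps, bio_reps, seed)


def design_frame(variants: list[ConditionVariant], factors: list[Factor]) -> pd.DataFrame:
    """Tabulate the design: variant_id, role, one coded and one actual column
    per factor (``coded_<name>`` / ``actual_<name>``)."""
    rows = []
    for v in variants:
        row: dict[str, object] = {"variant_id": v.variant_id, "role": v.role}
        for f, c, a in zip(factors, v.coded, v.actual):
            row[f"coded_{f.name}"] = c
            row[f"actual_{f.name}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def plan_frame(plan: RunPlan) -> pd.DataFrame:
    """Tabulate the run plan joined with its design (one row per run)."""
    runs = pd.DataFrame(plan.runs, columns=["run_id", "variant_id", "technical_rep", "execution_order"])
    return runs.merge(design_frame(plan.variants, plan.factors), on="variant_id", validate="m:1")
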