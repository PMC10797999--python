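"""Synthetic plate-reader data with the statistical structure the analysis assumes.

The generator draws per-culture OD600 and fluorescence readouts from smooth
ground-truth response surfaces over the coded design space, perturbed by
multiplicative lognormal noise (plate-reader error is scale-proportional).
Transcription-factor overexpression phenotypes are injected as condition-
dependent multiplicative fold-change profiles on top of the control strain's
surfaces ("archetypes"), so every downstream stage — fold changes, response
surface models, contribution rankings, query and classification — can be
exercised against a known truth.

Ground-truth archetype labels are returned out-of-band (a separate mapping,
never a readout column), so analysis code cannot accidentally read them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .design import RunPlan, plan_frame
from .errors import SimulationError

__all__ = [
    "GroundTruthSurface",
    "StrainArchetype",
    "ARCHETYPE_LABELS",
    "default_control_surfaces",
    "make_archetype",
    "simulate_readouts",
    "simulate_screen",
]

#: multiplicative noise coefficient of variation used throughout unless overridden
DEFAULT_NOISE_CV = 0.08

ARCHETYPE_LABELS = (
    "control",
    "null_tf",
    "global_enhancer",
    "global_silencer",
    "inverted",
    "oa_growth_enhancer",
    "oa_sensitive",
)


@dataclass
class GroundTruthSurface:
    """A quadratic-response truth surface over coded factors.

    ``coefficients`` maps term names to values: ``"1"`` (intercept), factor
    names for linear/main effects, ``"<name>^2"`` for quadratics of numeric
    factors and ``"<a>:<b>"`` for two-factor interactions.  An optional
    ``multiplier`` rescales the mean response condition-by-condition (this is
    how phenotype archetypes deform the control surface).  The predicted mean
    must stay positive wherever the surface is evaluated.
    """

    coefficients: dict[str, float]
    noise_cv: float = DEFAULT_NOISE_CV
    floor: float = 0.0
    multiplier: Callable[[Mapping[str, float]], float] | None = None

    def mean(self, coded: Mapping[str, float]) -> float:
        """Predicted mean response at one coded condition."""
        total = 0.0
        for term, coef in self.coefficients.items():
            if term == "1":
                total += coef
            elif term.endswith("^2"):
                total += coef * coded[term[:-2]] ** 2
            elif ":" in term:
                a, b = term.split(":")
                total += coef * coded[a] * coded[b]
            else:
                total += coef * coded[term]
        if self.multiplier is not None:
            total *= self.multiplier(coded)
        return total

    def scaled(self, multiplier: Callable[[Mapping[str, float]], float]) -> "GroundTruthSurface":
        """New surface whose mean is this one's times ``multiplier(coded)``."""
        base = self.multiplier
        if base is None:
            combined = multiplier
        else:
            def combined(coded, _base=base, _m=multiplier):
                return _base(coded) * _m(coded)
        return GroundTruthSurface(dict(self.coefficients), self.noise_cv, self.floor, combined)


@dataclass(frozen=True)
class StrainArchetype:
    """A named phenotype: per-measure multiplicative FC profiles over conditions."""

    label: str
    growth: GroundTruthSurface = field(repr=False, default=None)
    fluorescence: GroundTruthSurface = field(repr=False, default=None)


def default_control_surfaces(noise_cv: float = DEFAULT_NOISE_CV) -> tuple[GroundTruthSurface, GroundTruthSurface]:
    """Control-strain growth (OD600) and fluorescence (FU) truth surfaces.

    Growth peaks near the center of the pH/temperature range (negative
    curvature in both) and is mildly promoted by high oxygen availability;
    fluorescence carries a strong positive high-oxygen main effect, the
    dominant driver of reporter-protein synthesis in the emulated screen.
    """
    growth = GroundTruthSurface(
        coefficients={
            "1": 5.0, "oxygen": 0.8, "carbon": 0.2, "nitrogen": 0.3,
            "pH": 0.2, "temperature": -0.1, "pH^2": -0.8, "temperature^2": -0.6,
        },
        noise_cv=noise_cv, floor=1e-6,
    )
    fluorescence = GroundTruthSurface(
        coefficients={
            "1": 1000.0, "oxygen": 350.0, "carbon": 30.0, "nitrogen": 120.0,
            "pH": -60.0, "temperature": 40.0, "pH^2": -150.0, "temperature^2": -100.0,
            "oxygen:nitrogen": 40.0,
        },
        noise_cv=noise_cv, floor=0.0,
    )
    return growth, fluorescence


def _flat(x: float) -> Callable:
    return lambda coded: x


def make_archetype(
    label: str,
    params: Mapping[str, float] | None = None,
    base_growth: GroundTruthSurface | None = None,
    base_fluorescence: GroundTruthSurface | None = None,
) -> StrainArchetype:
    """Build the (growth, fluorescence) truth pair for one phenotype archetype.

    Archetypes scale the control surfaces by noise-free fold-change profiles:

    - ``control`` / ``null_tf``: all multipliers 1.
    - ``global_enhancer``: fluorescence times ``fl_multiplier`` (default 2.0)
      everywhere, growth unchanged.
    - ``global_silencer``: fluorescence times ``fl_multiplier`` (default 0.45,
      within the 0.4-0.5 band typical of dedicated r-Prot silencers), growth
      unchanged.
    - ``inverted``: fluorescence FC varies linearly along one numeric variable
      (default pH) from ``fc_low`` at code -1 to ``fc_high`` at +1
      (defaults 1.4 / 0.6) — opposite responses at the two extremes.
    - ``oa_growth_enhancer``: growth times ``growth_multiplier`` (default 1.10)
      under low oxygen only; fluorescence times ``fl_multiplier`` (default 0.95).
    - ``oa_sensitive``: growth times ``growth_multiplier`` (default 0.85) under
      low oxygen only.
    """
    p = dict(params or {})
    if base_growth is None or base_fluorescence is None:
        g, f = default_control_surfaces()
        base_growth = base_growth or g
        base_fluorescence = base_fluorescence or f

    if label in ("control", "null_tf"):
        return StrainArchetype(label, base_growth, base_fluorescence)
    if label == "global_enhancer":
        m = p.get("fl_multiplier", 2.0)
        return StrainArchetype(label, base_growth, base_fluorescence.scaled(_flat(m)))
    if label == "global_silencer":
        m = p.get("fl_multiplier", 0.45)
        return StrainArchetype(label, base_growth, base_fluorescence.scaled(_flat(m)))
    if label == "inverted":
        var = p.get("variable", "pH")
        lo, hi = p.get("fc_low", 1.4), p.get("fc_high", 0.6)
        center, half = (lo + hi) / 2.0, (hi - lo) / 2.0

        def ramp(coded, _v=var, _c=center, _h=half):
            return _c + _h * coded[_v]

        return StrainArchetype(label, base_growth, base_fluorescence.scaled(ramp))
    if label == "oa_growth_enhancer":
        gm = p.get("growth_multiplier", 1.10)
        fm = p.get("fl_multiplier", 0.95)

        def low_oa_boost(coded, _m=gm):
            return _m if coded["oxygen"] < 0 else 1.0

        return StrainArchetype(label, base_growth.scaled(low_oa_boost),
                               base_fluorescence.scaled(_flat(fm)))
    if label == "oa_sensitive":
        gm = p.get("growth_multiplier", 0.85)

        def low_oa_drop(coded, _m=gm):
            return _m if coded["oxygen"] < 0 else 1.0

        return StrainArchetype(label, base_growth.scaled(low_oa_drop), base_fluorescence)
    raise SimulationError(f"unknown archetype label {label!r}")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def simulate_readouts(
    growth_surface: GroundTruthSurface,
    fl_surface: GroundTruthSurface,
    plan: RunPlan,
    seed: int,
    strain_id: str = "strain",
) -> pd.DataFrame:
    """Draw one strain's readouts: one row per (run x biological replicate).

    Columns: strain_id, run_id, bio_rep, od600, fu.  Each culture's OD600 and
    fluorescence are the surface means at the run's coded condition times
    independent unit-mean lognormal factors, clipped at the surface floor.
    """
    rng = np.random.default_rng(seed)
    frame = plan_frame(plan)
    coded_cols = {f.name: f"coded_{f.name}" for f in plan.factors}

    means_g = np.empty(len(frame))
    means_f = np.empty(len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        coded = {name: getattr(row, col) for name, col in coded_cols.items()}
        means_g[i] = growth_surface.mean(coded)
        means_f[i] = fl_surface.mean(coded)
    if (means_g <= 0).any() or (means_f < 0).any():
        raise SimulationError("ground-truth surface predicts a non-positive mean on the plan")

    rows = []
    for rep in range(1, plan.bio_reps + 1):
        od = np.maximum(means_g * _lognormal_factors(rng, growth_surface.noise_cv, len(frame)),
                        growth_surface.floor)
        fu = np.maximum(means_f * _lognormal_factors(rng, fl_surface.noise_cv, len(frame)),
                        fl_surface.floor)
        rows.append(pd.DataFrame({
            "strain_id": strain_id,
            "run_id": frame["run_id"],
            "bio_rep": rep,
            "od600": od,
            "fu": fu,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["run_id", "bio_rep"], ignore_index=True)


def simulate_screen(
    archetype_assignment: Mapping[str, StrainArchetype | str],
    plan: RunPlan,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a whole screen: every strain over the full replicated plan.

    ``archetype_assignment`` maps strain ids to archetypes (or archetype
    labels, resolved with default parameters); exactly one strain must carry
    the ``control`` archetype.  Returns the concatenated readout table
    (n_strains x n_runs x bio_reps rows) and the strain -> truth-label mapping,
    kept out-of-band for classifier-recovery tests.
    """
    if not archetype_assignment:
        raise SimulationError("empty archetype assignment")
    resolved: dict[str, StrainArchetype] = {
        s: (make_archetype(a) if isinstance(a, str) else a)
        for s, a in archetype_assignment.items()
    }
    controls = [s for s, a in resolved.items() if a.label == "control"]
    if len(controls) != 1:
        raise SimulationError(f"exactly one control strain required, found {len(controls)}")

    rng = np.random.default_rng(seed)
    tables = []
    for strain in sorted(resolved):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        arch = resolved[strain]
        tables.append(simulate_readouts(arch.growth, arch.fluorescence, plan,
                                        seed=sub_seed, strain_id=strain))
    readouts = pd.concat(tables, ignore_index=True)
    truth = {s: a.label for s, a in resolved.items()}
    return readouts, truth
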