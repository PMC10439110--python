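"""Geochemical "hot spot" models for transiently elevated ion concentrations.

Two mechanisms can locally raise ion concentrations above the thresholds
lytic phages need:

* **Cell lysis** — a lysed bacterium (a sphere of radius ``r0``, ~1 µm)
  releases its cytoplasmic ions, which dilute evenly into a growing sphere
  of radius ``r``:  ``C(r) = C_cyto * (r0 / r)**3``.  The model conserves
  the ion mass released by the cell; it is an even-mixing picture, not a
  steady-state diffusion profile.
* **Evaporative concentration** — as porewater dries, conservative solutes
  (Na+, K+) scale linearly with the concentration factor
  ``cf = V_initial / V_remaining``, while Ca2+ and Mg2+ are capped by
  carbonate/silicate solubility ceilings: ``c(cf) = min(c0 * cf, ceiling)``.

Each model has a threshold-crossing solver with an exact closed form; the
test suite checks the closed forms against brute-force grid/bisection
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MissingIonError, OutOfDomainError
from .ions import IonProfile

__all__ = [
    "LysisModel",
    "EvaporationScenario",
    "lysis_concentration",
    "lysis_crossing_distance",
    "evaporate",
    "evaporation_crossing_factor",
    "lysis_profile_curves",
    "evaporation_curves",
    "crossing_table",
]


@dataclass
class LysisModel:
    """Even dilution of cytoplasmic ions from a lysed spherical cell."""

    cytoplasm: IonProfile
    r0: float = 1.0  # cell radius, microns

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise InvalidConfigError("cell radius must be positive")
        for ion in ("Na+", "K+", "Ca2+", "Mg2+"):
            if ion not in self.cytoplasm.concentrations:
                raise InvalidConfigError(f"cytoplasm profile lacks {ion}")


@dataclass
class EvaporationScenario:
    """Evaporation of a dilute water along a concentration-factor grid."""

    initial: IonProfile
    cf_grid: np.ndarray
    ceilings: dict[str, float] = field(default_factory=dict)
    conservative_ions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.cf_grid = np.asarray(self.cf_grid, dtype=float)
        if self.cf_grid.size == 0 or self.cf_grid[0] != 1.0:
            raise InvalidConfigError("cf grid must start at exactly 1")
        if np.any(np.diff(self.cf_grid) <= 0):
            raise InvalidConfigError("cf grid must be strictly ascending")
        if any(v <= 0 for v in self.ceilings.values()):
            raise InvalidConfigError("solubility ceilings must be positive")


def lysis_concentration(model: LysisModel, ion: str, r: float) -> float:
    """Ion concentration (mM) after even dilution into a sphere of radius
    ``r`` µm centred on the lysed cell."""
    if r < model.r0:
        raise OutOfDomainError(f"r={r} below cell radius r0={model.r0}")
    return model.cytoplasm.concentration(ion) * (model.r0 / r) ** 3


def lysis_crossing_distance(model: LysisModel, ion: str, threshold: float) -> float:
    """Smallest radius r >= r0 (µm) at which the diluted concentration has
    fallen to the threshold: ``r0 * (C_cyto / threshold)**(1/3)``, or ``r0``
    when the cytoplasm is already at or below the threshold."""
    if threshold <= 0:
        raise OutOfDomainError("threshold must be positive")
    c0 = model.cytoplasm.concentration(ion)
    if c0 <= threshold:
        return model.r0
    return model.r0 * (c0 / threshold) ** (1.0 / 3.0)


def evaporate(scenario: EvaporationScenario, cf: float) -> IonProfile:
    """Profile after concentrating by factor ``cf``: conservative ions scale
    linearly, ceiling-limited ions are capped at their solubility ceiling."""
    if cf < 1:
        raise OutOfDomainError(f"concentration factor {cf} < 1")
    conc = {}
    for ion, c0 in scenario.initial.concentrations.items():
        c = c0 * cf
        if ion in scenario.ceilings:
            c = min(c, scenario.ceilings[ion])
        conc[ion] = c
    return IonProfile(
        name=f"{scenario.initial.name} (cf={cf:g})",
        concentrations=conc,
        charges=dict(scenario.initial.charges),
        category=scenario.initial.category,
    )


def evaporation_crossing_factor(
    scenario: EvaporationScenario, ion: str, threshold: float
) -> float | None:
    """Smallest concentration factor at which ``ion`` reaches ``threshold``
    mM, or ``None`` when its solubility ceiling sits below the threshold."""
    if threshold <= 0:
        raise OutOfDomainError("threshold must be positive")
    c0 = scenario.initial.concentration(ion)
    ceiling = scenario.ceilings.get(ion)
    if ceiling is not None and ceiling < threshold:
        return None
    if c0 >= threshold:
        return 1.0
    if c0 == 0:
        return None
    return threshold / c0


# ---------------------------------------------------------------------------
# curve tables for plotting / reporting

def lysis_profile_curves(
    model: LysisModel, r_max: float = 10.0, n: int = 200
) -> pd.DataFrame:
    """Long-format (ion, r_um, conc_mM) dilution curves out to ``r_max`` µm."""
    if r_max <= model.r0:
        raise InvalidConfigError("r_max must exceed the cell radius")
    radii = np.geomspace(model.r0, r_max, n)
    rows = [
        (ion, r, lysis_concentration(model, ion, r))
        for ion in sorted(model.cytoplasm.concentrations)
        for r in radii
    ]
    return pd.DataFrame(rows, columns=["ion", "r_um", "conc_mM"])


def evaporation_curves(scenario: EvaporationScenario) -> pd.DataFrame:
    """Long-format (ion, cf, conc_mM) curves along the scenario's cf grid."""
    rows = []
    for cf in scenario.cf_grid:
        prof = evaporate(scenario, cf)
        rows.extend(
            (ion, cf, prof.concentrations[ion])
            for ion in sorted(prof.concentrations)
        )
    return pd.DataFrame(rows, columns=["ion", "cf", "conc_mM"])


def crossing_table(
    thresholds: dict[tuple[str, str], float],
    lysis: LysisModel | None = None,
    evaporation: EvaporationScenario | None = None,
) -> pd.DataFrame:
    """Crossing distances/factors for a table of (phage, ion) -> threshold mM.

    Ions absent from a model's profile are skipped for that model.
    """
    rows = []
    for (phage, ion), thr in sorted(thresholds.items()):
        if lysis is not None and ion in lysis.cytoplasm.concentrations:
            rows.append(
                (phage, ion, thr, "lysis_dilution",
                 lysis_crossing_distance(lysis, ion, thr), "crossing_r_um")
            )
        if evaporation is not None and ion in evaporation.initial.concentrations:
            cf = evaporation_crossing_factor(evaporation, ion, thr)
            rows.append(
                (phage, ion, thr, "evaporation",
                 np.nan if cf is None else cf, "crossing_cf")
            )
    return pd.DataFrame(
        rows,
        columns=["phage", "ion", "threshold_mM", "model", "crossing", "crossing_unit"],
    )
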