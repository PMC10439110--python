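"""Ion species, ion profiles and ionic-strength arithmetic.

Ionic strength is computed on a concentration basis,

    I = 1/2 * sum_i c_i * z_i**2   [mM],

summing over every dissolved ion *i* with molar concentration ``c_i`` and
integer charge ``z_i``.  Activity coefficients are deliberately not applied:
dose-response thresholds and environmental profiles are compared on the same
concentration scale throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidConfigError, MissingIonError, SchemaError

__all__ = [
    "IonSpecies",
    "IonProfile",
    "chloride_salt",
    "ionic_strength",
    "salt_to_profile",
    "ec50_to_ionic_strength",
]


@dataclass(frozen=True)
class IonSpecies:
    """A dosed inorganic salt, described by its dissociation stoichiometry.

    ``name`` is the cation of interest (e.g. ``"Ca2+"``); ``counter_anion``
    is the anion it is paired with in the dosing solution.  Electroneutrality
    of the formula unit is enforced:
    ``cation_per_formula * cation_charge + anion_per_formula * anion_charge == 0``.
    """

    name: str
    cation_charge: int
    counter_anion: str = "Cl-"
    anion_charge: int = -1
    cation_per_formula: int = 1
    anion_per_formula: int = field(default=0)

    def __post_init__(self) -> None:
        if self.cation_charge == 0 or self.anion_charge == 0:
            raise InvalidConfigError("ion charges must be nonzero")
        if self.anion_per_formula == 0:
            # infer the anion count needed to neutralize the formula unit
            balance = -self.cation_per_formula * self.cation_charge / self.anion_charge
            if balance != int(balance):
                raise InvalidConfigError(
                    f"{self.name}: no integer anion count balances charge"
                )
            object.__setattr__(self, "anion_per_formula", int(balance))
        net = (
            self.cation_per_formula * self.cation_charge
            + self.anion_per_formula * self.anion_charge
        )
        if net != 0:
            raise InvalidConfigError(
                f"{self.name}{self.counter_anion}: formula unit not electroneutral "
                f"(net charge {net})"
            )

    @property
    def formula(self) -> str:
        a = "" if self.anion_per_formula == 1 else str(self.anion_per_formula)
        c = "" if self.cation_per_formula == 1 else str(self.cation_per_formula)
        return f"{self.name}{c}({self.counter_anion}){a}"


def chloride_salt(cation: str, charge: int) -> IonSpecies:
    """Convenience constructor for the default MCl_z dosing salts."""
    return IonSpecies(name=cation, cation_charge=charge)


@dataclass
class IonProfile:
    """A named solution composition: per-ion concentration (mM) and charge."""

    name: str
    concentrations: dict[str, float]
    charges: dict[str, int]
    category: str = "uncategorized"

    def __post_init__(self) -> None:
        for ion, conc in self.concentrations.items():
            if conc < 0:
                raise SchemaError(f"{self.name}: negative concentration for {ion}")
            if ion not in self.charges:
                raise SchemaError(f"{self.name}: no charge recorded for {ion}")

    def concentration(self, ion: str) -> float:
        try:
            return self.concentrations[ion]
        except KeyError:
            raise MissingIonError(f"{self.name!r} has no ion {ion!r}") from None

    def union(self, other: "IonProfile", name: str | None = None) -> "IonProfile":
        """Pool two solutions: concentrations add, charges must agree."""
        conc = dict(self.concentrations)
        charges = dict(self.charges)
        for ion, c in other.concentrations.items():
            conc[ion] = conc.get(ion, 0.0) + c
            z = other.charges[ion]
            if charges.setdefault(ion, z) != z:
                raise SchemaError(f"conflicting charges for {ion}")
        return IonProfile(
            name=name or f"{self.name}+{other.name}",
            concentrations=conc,
            charges=charges,
            category=self.category,
        )

    def scaled(self, factor: float, name: str | None = None) -> "IonProfile":
        if factor < 0:
            raise InvalidConfigError("scale factor must be nonnegative")
        return IonProfile(
            name=name or self.name,
            concentrations={i: c * factor for i, c in self.concentrations.items()},
            charges=dict(self.charges),
            category=self.category,
        )


def ionic_strength(profile: IonProfile) -> float:
    """Concentration-based ionic strength of a profile, in mM."""
    return 0.5 * sum(
        conc * profile.charges[ion] ** 2
        for ion, conc in profile.concentrations.items()
    )


def salt_to_profile(salt: IonSpecies, conc_mm: float) -> IonProfile:
    """Fully dissociate ``conc_mm`` of a salt into its constituent ions."""
    if conc_mm < 0:
        raise InvalidConfigError("salt concentration must be nonnegative")
    if conc_mm == 0:
        return IonProfile(name=f"{salt.formula}@0mM", concentrations={}, charges={})
    return IonProfile(
        name=f"{salt.formula}@{conc_mm:g}mM",
        concentrations={
            salt.name: conc_mm * salt.cation_per_formula,
            salt.counter_anion: conc_mm * salt.anion_per_formula,
        },
        charges={salt.name: salt.cation_charge, salt.counter_anion: salt.anion_charge},
    )


def ec50_to_ionic_strength(fit, salt: IonSpecies, background: IonProfile | None = None) -> float:
    """Ionic strength (mM) contributed by the dosing salt at its half-maximal
    concentration, optionally plus the ionic strength of a background medium.

    ``fit`` is a :class:`~phagegeo.dose_response.FourPLFit`; a no-inhibition
    sentinel carries no threshold and raises.
    """
    from .errors import UndefinedThresholdError

    if getattr(fit, "no_inhibition", False) or not fit.converged:
        raise UndefinedThresholdError(
            "fit has no defined half-maximal concentration"
        )
    total = ionic_strength(salt_to_profile(salt, fit.half_max))
    if background is not None:
        total += ionic_strength(background)
    return total
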