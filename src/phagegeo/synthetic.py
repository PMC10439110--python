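"""Synthetic inputs with known ground truth.

Three experiment families are emulated:

1. **Ion-array microplates** — hosts grown across serial dilutions of single
   inorganic salts, with and without phage, OD600 read at the endpoint.
   Responses follow a 4PL curve per (ion, phage condition) plus Gaussian
   plate noise on the normalized scale, clipped at zero (an optical density
   cannot be negative).  Serial dilution is 2-fold over 10 steps by default.
2. **Nitrate-reducing enrichment microbiomes** — per carbon source, a fixed
   base community; adding a lytic phage cocktail multiplies the abundance of
   its target taxa by a depletion factor before renormalization.  Ammonium
   accumulation is the yield-weighted sum over the depleted (pre-
   renormalization) biomass, plus noise, floored at zero.
3. **Environmental ion profiles** — bundled compartments (freshwaters,
   bacterial cytoplasm, human gut, seawater) and a configurable dilute
   springwater evaporation scenario.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import fourpl
from .errors import InvalidConfigError, MissingIonError
from .hotspots import EvaporationScenario
from .ions import IonProfile, IonSpecies, chloride_salt

__all__ = [
    "CurveTruth",
    "PlateTruth",
    "CommunityTruth",
    "default_ion_panel",
    "gen_ion_array_plate",
    "gen_fn_microbiome",
    "gen_environment_profiles",
    "gen_springwater_scenario",
    "default_community_truth",
    "PLATE_CONTROL_OD",
]

#: nominal OD600 of an uninhibited phage-free control culture at the endpoint
PLATE_CONTROL_OD = 0.6


@dataclass(frozen=True)
class CurveTruth:
    """True 4PL parameters for one (ion, phage condition) curve, on the
    normalized-response scale (control == 1)."""

    ec50: float
    hill: float = 2.0
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise InvalidConfigError("true EC50 must be positive")
        if self.top <= self.bottom:
            raise InvalidConfigError("true top must exceed true bottom")


@dataclass
class PlateTruth:
    """Ground truth for a whole plate: one curve per (ion, phage)."""

    curves: dict[tuple[str, str], CurveTruth]
    noise_sd: float = 0.05  # fraction of each curve's dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")

    def curve(self, ion: str, phage: str) -> CurveTruth:
        try:
            return self.curves[(ion, phage)]
        except KeyError:
            raise MissingIonError(f"no truth for ({ion!r}, {phage!r})") from None


def default_ion_panel(n: int = 80) -> list[IonSpecies]:
    """A panel of chloride salts spanning charges +1..+3, padded with
    synthetic cations ("M01+", ...) up to ``n`` entries.

    The named leading entries are the biologically central cations of the
    assay; the padded tail exercises panel-scale bookkeeping.
    """
    named = [
        chloride_salt("Na+", 1),
        chloride_salt("K+", 1),
        chloride_salt("Li+", 1),
        chloride_salt("Rb+", 1),
        chloride_salt("Cs+", 1),
        chloride_salt("Ca2+", 2),
        chloride_salt("Mg2+", 2),
        chloride_salt("Sr2+", 2),
        chloride_salt("Be2+", 2),
        chloride_salt("Al3+", 3),
    ]
    if n <= len(named):
        return named[:n]
    pad = [
        chloride_salt(f"M{i:02d}{'+' * (i % 3 + 1)}", i % 3 + 1)
        for i in range(n - len(named))
    ]
    return named + pad


def gen_ion_array_plate(
    panel: list[IonSpecies],
    truth: PlateTruth,
    n_dilutions: int = 10,
    dilution_factor: float = 2.0,
    top_conc: float = 100.0,
    n_replicates: int = 2,
    phage_conditions: tuple[str, ...] = ("none", "T4"),
    control_od: float = PLATE_CONTROL_OD,
) -> pd.DataFrame:
    """Simulate a long-format ion-array plate.

    One row per (ion, phage condition, concentration, replicate), plus
    zero-concentration control wells per (phage condition, replicate).
    ``od600`` is ``control_od`` times the noisy normalized response.
    ``top_conc`` may be a scalar or a per-ion mapping (mM).
    """
    if n_dilutions < 4:
        raise InvalidConfigError("need at least 4 dilution steps")
    if dilution_factor <= 1:
        raise InvalidConfigError("dilution factor must exceed 1")
    if n_replicates < 1:
        raise InvalidConfigError("need at least one replicate")
    top_by_ion = (
        dict(top_conc) if isinstance(top_conc, dict) else {s.name: float(top_conc) for s in panel}
    )
    if any(v <= 0 for v in top_by_ion.values()):
        raise InvalidConfigError("top concentration must be positive")

    rng = np.random.default_rng(truth.seed)
    rows = []
    well = 0
    for salt in panel:
        concs = top_by_ion[salt.name] / dilution_factor ** np.arange(n_dilutions)
        for phage in phage_conditions:
            ct = truth.curve(salt.name, phage)
            sd = truth.noise_sd * (ct.top - ct.bottom)
            for conc in concs:
                mean = float(fourpl(conc, ct.top, ct.bottom, ct.ec50, ct.hill))
                for rep in range(1, n_replicates + 1):
                    resp = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    rows.append(
                        (f"W{well:05d}", salt.name, salt.formula, conc, phage,
                         rep, control_od * max(resp, 0.0))
                    )
                    well += 1
    # zero-ion control wells: uninhibited growth (normalized response 1)
    sd0 = truth.noise_sd
    for phage in phage_conditions:
        for rep in range(1, n_replicates + 1):
            resp = 1.0 + (rng.normal(0.0, sd0) if sd0 > 0 else 0.0)
            rows.append(
                (f"W{well:05d}", "none", "none", 0.0, phage, rep,
                 control_od * max(resp, 0.0))
            )
            well += 1
    return pd.DataFrame(
        rows,
        columns=["well", "ion", "salt_formula", "conc_mM", "phage", "replicate", "od600"],
    )


# ---------------------------------------------------------------------------
# microbiome generator

@dataclass
class CommunityTruth:
    """Ground truth for the enrichment-culture experiment.

    ``base_abundances`` maps carbon source -> {taxon: fraction} (each summing
    to 1); ``phage_target_taxa`` are depleted by ``depletion_factor`` in
    +cocktail samples; ``ammonium_yield`` maps taxon -> mM ammonium produced
    per unit (pre-renormalization) abundance.
    """

    base_abundances: dict[str, dict[str, float]]
    phage_target_taxa: frozenset[str]
    depletion_factor: float = 1.0
    ammonium_yield: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.depletion_factor <= 1:
            raise InvalidConfigError("depletion factor must lie in (0, 1]")
        for cs, ab in self.base_abundances.items():
            total = sum(ab.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"{cs}: base abundances sum to {total}, expected 1"
                )
            if any(v < 0 for v in ab.values()):
                raise InvalidConfigError(f"{cs}: negative base abundance")

    def dominant_taxon(self, carbon_source: str) -> str:
        ab = self.base_abundances[carbon_source]
        return min(ab, key=lambda t: (-ab[t], t))


def default_community_truth(depletion_factor: float = 0.1) -> CommunityTruth:
    """A three-guild enrichment mirroring the study system: a phage-targeted
    DNRA Escherichia dominating on glucose, a nitrate-to-nitrite-only
    Klebsiella on cellobiose, and an untargeted DNRA Sulfurospirillum on
    ethanol."""
    return CommunityTruth(
        base_abundances={
            "D-glucose": {"Escherichia": 0.70, "Klebsiella": 0.10,
                          "Sulfurospirillum": 0.05, "other": 0.15},
            # the targeted DNRA strain cannot use cellobiose or ethanol,
            # so those communities are unaffected by the cocktail
            "D-cellobiose": {"Escherichia": 0.0, "Klebsiella": 0.82,
                             "Sulfurospirillum": 0.03, "other": 0.15},
            "ethanol": {"Escherichia": 0.0, "Klebsiella": 0.05,
                        "Sulfurospirillum": 0.80, "other": 0.15},
        },
        phage_target_taxa=frozenset({"Escherichia"}),
        depletion_factor=depletion_factor,
        ammonium_yield={"Escherichia": 10.0, "Klebsiella": 0.0,
                        "Sulfurospirillum": 10.0, "other": 0.0},
    )


def gen_fn_microbiome(
    truth: CommunityTruth,
    carbon_sources: list[str],
    n_replicates: int = 4,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the ±cocktail enrichment experiment.

    Returns ``(community, metadata)``: a taxa x samples relative-abundance
    table and a per-sample metadata table with carbon source, phage
    condition, replicate and ammonium (mM).  In +cocktail samples the target
    taxa are multiplied by the depletion factor, ammonium is computed from
    the depleted pre-renormalization biomass, then abundances are
    renormalized to sum to 1.
    """
    if n_replicates < 1:
        raise InvalidConfigError("need at least one replicate")
    unknown = [cs for cs in carbon_sources if cs not in truth.base_abundances]
    if unknown:
        raise MissingIonError(f"carbon sources not in truth: {unknown}")
    rng = np.random.default_rng(seed)
    taxa = sorted({t for ab in truth.base_abundances.values() for t in ab})
    columns: dict[str, list[float]] = {}
    meta_rows = []
    for cs in carbon_sources:
        base = truth.base_abundances[cs]
        for phage in ("none", "cocktail"):
            for rep in range(1, n_replicates + 1):
                depleted = {
                    t: base.get(t, 0.0)
                    * (truth.depletion_factor
                       if phage == "cocktail" and t in truth.phage_target_taxa
                       else 1.0)
                    for t in taxa
                }
                ammonium = sum(
                    depleted[t] * truth.ammonium_yield.get(t, 0.0) for t in taxa
                )
                if noise_sd > 0:
                    ammonium += rng.normal(0.0, noise_sd)
                total = sum(depleted.values())
                sample = f"{cs}|{phage}|r{rep}"
                columns[sample] = [depleted[t] / total for t in taxa]
                meta_rows.append((sample, cs, phage, rep, max(ammonium, 0.0)))
    community = pd.DataFrame(columns, index=taxa)
    community.index.name = "taxon"
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "carbon_source", "phage", "replicate", "ammonium_mM"]
    ).set_index("sample")
    return community, metadata


# ---------------------------------------------------------------------------
# environmental profiles

_CHARGES = {"Na+": 1, "K+": 1, "Ca2+": 2, "Mg2+": 2, "Cl-": -1, "SO42-": -2}


def _profile(name: str, category: str, conc: dict[str, float]) -> IonProfile:
    return IonProfile(
        name=name,
        category=category,
        concentrations=conc,
        charges={i: _CHARGES[i] for i in conc},
    )


def gen_environment_profiles() -> list[IonProfile]:
    """Bundled environment/compartment major-ion profiles (mM).

    Cytoplasmic concentrations and the global-mean freshwater Ca2+ are the
    standard literature values; the remaining freshwater, gut and seawater
    entries are representative compositions for each compartment.
    """
    return [
        _profile("bacterial cytoplasm", "cytoplasm",
                 {"Na+": 212.0, "K+": 38.0, "Ca2+": 0.5, "Mg2+": 1.0}),
        _profile("global mean freshwater", "freshwater",
                 {"Na+": 0.23, "K+": 0.03, "Ca2+": 0.1, "Mg2+": 0.14}),
        _profile("dilute mountain springwater", "freshwater",
                 {"Na+": 0.134, "K+": 0.028, "Ca2+": 0.1, "Mg2+": 0.029}),
        _profile("human gut lumen", "gut",
                 {"Na+": 140.0, "K+": 10.0, "Ca2+": 5.0, "Mg2+": 5.0}),
        _profile("seawater", "seawater",
                 {"Na+": 470.0, "K+": 10.0, "Ca2+": 10.0, "Mg2+": 53.0,
                  "Cl-": 550.0, "SO42-": 28.0}),
    ]


#: illustrative solubility caps for the ceiling-limited divalents (mM):
#: calcium carbonate and magnesium silicate formation during evaporation
DEFAULT_CEILINGS = {"Ca2+": 0.5, "Mg2+": 1.0}


def gen_springwater_scenario(
    na0: float = 0.134,
    k0: float = 0.028,
    ca0: float = 0.1,
    mg0: float = 0.029,
    ceilings: dict[str, float] | None = None,
    cf_max: float = 10_000.0,
    n_grid: int = 200,
) -> EvaporationScenario:
    """A dilute-springwater evaporation scenario.

    Initial concentrations are configurable (defaults are illustrative
    dilute-mountain-spring values, not measurements); Na+ and K+ are
    conservative, Ca2+ and Mg2+ are capped by their solubility ceilings.
    The concentration-factor grid is logarithmic from exactly 1 to
    ``cf_max``.
    """
    for label, v in (("na0", na0), ("k0", k0), ("ca0", ca0), ("mg0", mg0)):
        if v <= 0:
            raise InvalidConfigError(f"{label} must be positive, got {v}")
    if cf_max < 1:
        raise InvalidConfigError("cf_max must be >= 1")
    grid = np.geomspace(1.0, cf_max, n_grid)
    grid[0] = 1.0
    return EvaporationScenario(
        initial=_profile(
            "dilute springwater", "freshwater",
            {"Na+": na0, "K+": k0, "Ca2+": ca0, "Mg2+": mg0},
        ),
        cf_grid=grid,
        ceilings=dict(ceilings if ceilings is not None else DEFAULT_CEILINGS),
        conservative_ions=frozenset({"Na+", "K+"}),
    )
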