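"""Phage-cocktail effects on the nitrate-reducing enrichment culture.

The enrichment's end-product split between denitrification and DNRA
(dissimilatory nitrate reduction to ammonium) depends on which strains
dominate, which in turn depends on the supplied carbon source.  A lytic
cocktail formulated against the dominant DNRA strains suppresses ammonium
accumulation — but only on carbon sources where those strains grow.  This
module quantifies that interaction:

* community-weighted DNRA genetic potential (the abundance-weighted fraction
  of the community carrying both the nitrate->nitrite and nitrite->ammonium
  reduction steps);
* per-carbon-source ±cocktail ammonium contrasts (Welch's t-test);
* the nitrogen-assimilation correction converting OD600 into biomass
  nitrogen (0.3 g/L dry weight per OD unit, 12% N by weight);
* ion dose-response of cocktail efficacy, reusing the 4PL machinery with
  ammonium (or OD600) as the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import FourPLFit, ThresholdCall, analyze_plate
from .errors import (
    InsufficientReplicationError,
    MissingTaxonError,
    OutOfDomainError,
    SchemaError,
)

__all__ = [
    "CommunityFunctionSample",
    "CapabilityTable",
    "TaxonCapability",
    "NitrogenAssimilation",
    "dnra_potential",
    "phage_effect_by_carbon",
    "nitrogen_assimilated",
    "cocktail_ion_dose_response",
    "samples_from_tables",
    "DRY_WEIGHT_G_PER_L_PER_OD",
    "BIOMASS_NITROGEN_FRACTION",
    "NITROGEN_MOLAR_MASS",
]

# biomass conversion constants: dry weight per unit OD600 and the nitrogen
# mass fraction of microbial biomass
DRY_WEIGHT_G_PER_L_PER_OD = 0.3
BIOMASS_NITROGEN_FRACTION = 0.12
NITROGEN_MOLAR_MASS = 14.007  # g/mol


@dataclass(frozen=True)
class TaxonCapability:
    can_nitrate_to_nitrite: bool
    can_nitrite_to_ammonium: bool
    phage_targeted: bool = False

    @property
    def dnra_capable(self) -> bool:
        # DNRA requires the full reduction chain: nitrate -> nitrite -> ammonium
        return self.can_nitrate_to_nitrite and self.can_nitrite_to_ammonium


@dataclass
class CapabilityTable:
    """Per-taxon respiratory capability and phage-target flags."""

    taxa: dict[str, TaxonCapability]

    def capability(self, taxon: str) -> TaxonCapability:
        try:
            return self.taxa[taxon]
        except KeyError:
            raise MissingTaxonError(
                f"taxon {taxon!r} absent from capability table"
            ) from None


@dataclass
class CommunityFunctionSample:
    """One enrichment culture: composition, function and condition labels."""

    carbon_source: str
    phage: str  # "none" or "cocktail"
    replicate: int
    abundances: dict[str, float]
    ammonium_mM: float
    od600: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-6:
            raise SchemaError(f"abundances sum to {total}, expected 1")
        if self.ammonium_mM < 0 or self.od600 < 0:
            raise SchemaError("ammonium and OD600 must be nonnegative")


def dnra_potential(sample: CommunityFunctionSample, caps: CapabilityTable) -> float:
    """Abundance-weighted fraction of the community capable of full DNRA."""
    missing = [
        t for t, a in sample.abundances.items() if a > 0 and t not in caps.taxa
    ]
    if missing:
        raise MissingTaxonError(
            f"abundant taxa missing from capability table: {sorted(missing)}"
        )
    return float(
        sum(
            a
            for t, a in sample.abundances.items()
            if a > 0 and caps.capability(t).dnra_capable
        )
    )


def _dominant_taxon(samples: list[CommunityFunctionSample]) -> str:
    pooled: dict[str, list[float]] = {}
    for s in samples:
        for t, a in s.abundances.items():
            pooled.setdefault(t, []).append(a)
    means = {t: float(np.mean(v)) for t, v in pooled.items()}
    return min(means, key=lambda t: (-means[t], t))  # ties break lexicographically


def phage_effect_by_carbon(
    samples: list[CommunityFunctionSample],
    caps: CapabilityTable | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-carbon-source ±cocktail ammonium contrast.

    For each carbon source: the mean ammonium difference (phage-free minus
    cocktail), a Welch two-sample p-value, a significance flag at ``alpha``
    (optionally Benjamini–Hochberg adjusted across carbon sources), the
    dominant taxon of the phage-free condition, and — when a capability
    table is supplied — the mean DNRA potential per condition.
    """
    groups: dict[tuple[str, str], list[CommunityFunctionSample]] = {}
    for s in samples:
        groups.setdefault((s.carbon_source, s.phage), []).append(s)
    carbon_sources = sorted({cs for cs, _ in groups})
    rows = []
    for cs in carbon_sources:
        minus = groups.get((cs, "none"), [])
        plus = groups.get((cs, "cocktail"), [])
        if len(minus) < 2 or len(plus) < 2:
            raise InsufficientReplicationError(
                f"{cs}: need >= 2 replicates per phage condition "
                f"(got {len(minus)} phage-free, {len(plus)} cocktail)"
            )
        a = np.array([s.ammonium_mM for s in minus])
        b = np.array([s.ammonium_mM for s in plus])
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            pval = 1.0  # identical constant groups: no evidence of an effect
        else:
            pval = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        row = {
            "carbon_source": cs,
            "mean_diff_mM": float(a.mean() - b.mean()),
            "p_value": pval,
            "dominant_taxon": _dominant_taxon(minus),
        }
        if caps is not None:
            row["dnra_potential_minus"] = float(
                np.mean([dnra_potential(s, caps) for s in minus])
            )
            row["dnra_potential_plus"] = float(
                np.mean([dnra_potential(s, caps) for s in plus])
            )
            row["dominant_targeted"] = caps.capability(
                row["dominant_taxon"]
            ).phage_targeted
        rows.append(row)
    out = pd.DataFrame(rows)
    pvals = out["p_value"].to_numpy()
    if bh_correct and len(pvals) > 1:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(pvals)
        adjusted[order] = np.clip(adj, 0, 1)
        out["p_adjusted"] = adjusted
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out["significant"] = out["p_value"] <= alpha
    return out


@dataclass(frozen=True)
class NitrogenAssimilation:
    g_per_l: float
    mM: float


def nitrogen_assimilated(od600: float) -> NitrogenAssimilation:
    """Nitrogen assimilated into biomass at a given culture OD600.

    ``N = OD600 * 0.3 g/L dry weight * 0.12 gN/g``, also expressed in mM via
    the molar mass of nitrogen.
    """
    if od600 < 0:
        raise OutOfDomainError("OD600 must be nonnegative")
    g_per_l = od600 * DRY_WEIGHT_G_PER_L_PER_OD * BIOMASS_NITROGEN_FRACTION
    return NitrogenAssimilation(g_per_l=g_per_l, mM=g_per_l / NITROGEN_MOLAR_MASS * 1e3)


def cocktail_ion_dose_response(
    plate: pd.DataFrame,
    response_col: str = "ammonium_mM",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[list[FourPLFit], list[ThresholdCall]]:
    """Ion requirement of the cocktail for suppressing community function.

    A thin wrapper over :func:`phagegeo.dose_response.analyze_plate` with
    ammonium (or OD600) as the response: the fitted half-max in the
    +cocktail condition is the ion EC50 for cocktail-mediated suppression.
    """
    if response_col not in plate.columns:
        raise SchemaError(f"plate table lacks response column {response_col!r}")
    return analyze_plate(
        plate,
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
        response_col=response_col,
    )


def samples_from_tables(
    community: pd.DataFrame, metadata: pd.DataFrame
) -> list[CommunityFunctionSample]:
    """Assemble samples from a taxa x samples table and its metadata.

    ``metadata`` is indexed by sample id with columns carbon_source, phage,
    replicate, ammonium_mM and optionally od600.
    """
    missing = set(community.columns) - set(metadata.index)
    if missing:
        raise SchemaError(f"samples without metadata: {sorted(missing)}")
    samples = []
    for sample_id in community.columns:
        meta = metadata.loc[sample_id]
        samples.append(
            CommunityFunctionSample(
                carbon_source=str(meta["carbon_source"]),
                phage=str(meta["phage"]),
                replicate=int(meta["replicate"]),
                abundances=community[sample_id].to_dict(),
                ammonium_mM=float(meta["ammonium_mM"]),
                od600=float(meta.get("od600", 0.0)),
            )
        )
    return samples
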