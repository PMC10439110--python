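"""DNRA potential, ±cocktail contrasts and the nitrogen correction."""

import numpy as np
import pytest

from phagegeo import (
    CapabilityTable,
    CommunityFunctionSample,
    CommunityTruth,
    CurveTruth,
    PlateTruth,
    TaxonCapability,
    chloride_salt,
    cocktail_ion_dose_response,
    default_community_truth,
    dnra_potential,
    gen_fn_microbiome,
    gen_ion_array_plate,
    nitrogen_assimilated,
    phage_effect_by_carbon,
    samples_from_tables,
)
from phagegeo.community import (
    BIOMASS_NITROGEN_FRACTION,
    DRY_WEIGHT_G_PER_L_PER_OD,
)
from phagegeo.errors import (
    InsufficientReplicationError,
    MissingTaxonError,
    OutOfDomainError,
)

CAPS = CapabilityTable(
    taxa={
        "Escherichia": TaxonCapability(True, True, phage_targeted=True),
        "Klebsiella": TaxonCapability(True, False),
        "Sulfurospirillum": TaxonCapability(True, True),
        "other": TaxonCapability(False, False),
    }
)


def sample(abundances, carbon="D-glucose", phage="none", rep=1, ammonium=1.0):
    return CommunityFunctionSample(
        carbon_source=carbon,
        phage=phage,
        replicate=rep,
        abundances=abundances,
        ammonium_mM=ammonium,
    )


class TestDnraPotential:
    def test_single_capable_taxon(self):
        assert dnra_potential(sample({"Escherichia": 1.0}), CAPS) == 1.0

    def test_weighted_sum(self):
        """Half DNRA-capable, half nitrate-to-nitrite only: potential 0.5."""
        s = sample({"Escherichia": 0.5, "Klebsiella": 0.5})
        assert dnra_potential(s, CAPS) == pytest.approx(0.5)

    def test_no_capable_taxa(self):
        s = sample({"Klebsiella": 0.6, "other": 0.4})
        assert dnra_potential(s, CAPS) == 0.0

    def test_missing_taxon_named_in_error(self):
        s = sample({"Vibrio": 1.0})
        with pytest.raises(MissingTaxonError, match="Vibrio"):
            dnra_potential(s, CAPS)

    def test_invariant_under_merging_equivalent_taxa(self):
        """Splitting a guild across taxa with identical flags is neutral."""
        split = sample({"Escherichia": 0.3, "Sulfurospirillum": 0.4, "other": 0.3})
        merged = sample({"Escherichia": 0.7, "other": 0.3})
        assert dnra_potential(split, CAPS) == pytest.approx(
            dnra_potential(merged, CAPS)
        )


class TestPhageEffectByCarbon:
    def test_identical_groups_not_significant(self):
        samples = [
            sample({"Escherichia": 1.0}, phage=p, rep=r, ammonium=5.0)
            for p in ("none", "cocktail")
            for r in (1, 2, 3)
        ]
        eff = phage_effect_by_carbon(samples)
        assert eff["mean_diff_mM"].iloc[0] == 0.0
        assert not eff["significant"].iloc[0]

    def test_depletion_detected_and_untargeted_source_untouched(self):
        """The targeted-dominant carbon source shows a significant positive
        ammonium difference; the untargeted-dominant sources do not."""
        truth = default_community_truth(depletion_factor=0.1)
        comm, meta = gen_fn_microbiome(
            truth, ["D-glucose", "ethanol"], n_replicates=4, noise_sd=0.05, seed=3
        )
        eff = phage_effect_by_carbon(
            samples_from_tables(comm, meta), caps=CAPS
        ).set_index("carbon_source")
        assert eff.loc["D-glucose", "significant"]
        assert eff.loc["D-glucose", "mean_diff_mM"] > 0
        assert eff.loc["D-glucose", "dominant_taxon"] == "Escherichia"
        assert eff.loc["D-glucose", "dominant_targeted"]
        assert eff.loc["ethanol", "dominant_taxon"] == "Sulfurospirillum"
        assert not eff.loc["ethanol", "dominant_targeted"]
        assert abs(eff.loc["ethanol", "mean_diff_mM"]) < 0.2

    def test_dnra_potential_drops_under_depletion(self):
        truth = default_community_truth(depletion_factor=0.1)
        comm, meta = gen_fn_microbiome(
            truth, ["D-glucose"], n_replicates=3, noise_sd=0.0, seed=5
        )
        eff = phage_effect_by_carbon(samples_from_tables(comm, meta), caps=CAPS)
        assert eff["dnra_potential_plus"].iloc[0] < eff["dnra_potential_minus"].iloc[0]

    def test_insufficient_replication_rejected(self):
        samples = [
            sample({"Escherichia": 1.0}, phage="none", rep=1),
            sample({"Escherichia": 1.0}, phage="cocktail", rep=1),
            sample({"Escherichia": 1.0}, phage="cocktail", rep=2),
        ]
        with pytest.raises(InsufficientReplicationError):
            phage_effect_by_carbon(samples)

    def test_bh_correction_only_reduces_flags(self):
        truth = default_community_truth(depletion_factor=0.1)
        comm, meta = gen_fn_microbiome(
            truth, list(truth.base_abundances), n_replicates=4, noise_sd=0.05, seed=8
        )
        samples = samples_from_tables(comm, meta)
        raw = phage_effect_by_carbon(samples)
        adj = phage_effect_by_carbon(samples, bh_correct=True)
        assert (adj["significant"] <= raw["significant"]).all()

    def test_dominant_taxon_tie_breaks_lexicographically(self):
        samples = [
            sample({"B_taxon": 0.5, "A_taxon": 0.5}, phage=p, rep=r)
            for p in ("none", "cocktail")
            for r in (1, 2)
        ]
        eff = phage_effect_by_carbon(samples)
        assert eff["dominant_taxon"].iloc[0] == "A_taxon"


class TestNitrogenAssimilated:
    def test_zero_od(self):
        n = nitrogen_assimilated(0.0)
        assert n.g_per_l == 0.0 and n.mM == 0.0

    def test_unit_od_product_of_constants(self):
        n = nitrogen_assimilated(1.0)
        assert n.g_per_l == pytest.approx(0.036, abs=1e-15)
        assert n.g_per_l == DRY_WEIGHT_G_PER_L_PER_OD * BIOMASS_NITROGEN_FRACTION
        assert n.mM == pytest.approx(0.036 / 14.007 * 1e3)

    @pytest.mark.parametrize("od", [0.25, 0.5, 2.0])
    def test_linearity(self, od):
        assert nitrogen_assimilated(od).g_per_l == pytest.approx(od * 0.036)

    def test_negative_od_rejected(self):
        with pytest.raises(OutOfDomainError):
            nitrogen_assimilated(-0.1)


class TestCocktailDoseResponse:
    def test_ammonium_ec50_recovered_and_called(self):
        """Noiseless ammonium dose-response: the +cocktail half-max is
        recovered to the truth and the pair is called enables_infection
        when the cocktail threshold sits far below direct toxicity."""
        truth = PlateTruth(
            curves={
                ("Na+", "none"): CurveTruth(ec50=500.0),
                ("Na+", "cocktail"): CurveTruth(ec50=50.0),
            },
            noise_sd=0.0,
            seed=0,
        )
        plate = gen_ion_array_plate(
            [chloride_salt("Na+", 1)],
            truth,
            top_conc=1600.0,
            phage_conditions=("none", "cocktail"),
        )
        # the community assay reads ammonium rather than OD
        plate = plate.rename(columns={"od600": "ammonium_mM"})
        fits, calls = cocktail_ion_dose_response(
            plate, response_col="ammonium_mM", n_boot=100, seed=1
        )
        by_cond = {f.phage: f for f in fits}
        assert by_cond["cocktail"].half_max == pytest.approx(50.0, rel=1e-4)
        assert by_cond["none"].half_max == pytest.approx(500.0, rel=1e-4)
        assert calls[0].classification == "enables_infection"

    def test_flat_minus_cocktail_series_is_no_inhibition(self):
        truth = PlateTruth(
            curves={
                ("Na+", "none"): CurveTruth(ec50=1e9),  # flat within range
                ("Na+", "cocktail"): CurveTruth(ec50=50.0),
            },
            noise_sd=0.0,
        )
        plate = gen_ion_array_plate(
            [chloride_salt("Na+", 1)],
            truth,
            top_conc=1600.0,
            phage_conditions=("none", "cocktail"),
        ).rename(columns={"od600": "ammonium_mM"})
        fits, calls = cocktail_ion_dose_response(
            plate, response_col="ammonium_mM", n_boot=100, seed=1
        )
        assert {f.phage: f for f in fits}["none"].no_inhibition
        assert calls[0].classification == "no_inhibition"
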