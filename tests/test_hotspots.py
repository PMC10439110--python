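"""Lysis-dilution and evaporative-concentration models vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from phagegeo import (
    EvaporationScenario,
    IonProfile,
    LysisModel,
    crossing_table,
    evaporate,
    evaporation_crossing_factor,
    evaporation_curves,
    gen_environment_profiles,
    gen_springwater_scenario,
    lysis_concentration,
    lysis_crossing_distance,
    lysis_profile_curves,
)
from phagegeo.errors import InvalidConfigError, MissingIonError, OutOfDomainError


@pytest.fixture(scope="module")
def lysis():
    cyto = next(p for p in gen_environment_profiles() if p.category == "cytoplasm")
    return LysisModel(cytoplasm=cyto, r0=1.0)


def bisection_crossing(model, ion, threshold, r_hi=1e6):
    """Independent oracle: root of C(r) - threshold by scalar bisection."""
    c0 = model.cytoplasm.concentration(ion)
    if c0 <= threshold:
        return model.r0
    return brentq(
        lambda r: lysis_concentration(model, ion, r) - threshold,
        model.r0,
        r_hi,
        xtol=1e-12,
    )


class TestLysisModel:
    def test_concentration_at_cell_surface(self, lysis):
        assert lysis_concentration(lysis, "Na+", 1.0) == 212.0

    def test_double_radius_dilutes_eightfold(self, lysis):
        assert lysis_concentration(lysis, "Na+", 2.0) == pytest.approx(26.5)

    def test_monotone_nonincreasing(self, lysis):
        radii = np.linspace(1.0, 50.0, 200)
        for ion in lysis.cytoplasm.concentrations:
            c = [lysis_concentration(lysis, ion, r) for r in radii]
            assert np.all(np.diff(c) <= 0)

    @given(r=st.floats(1.0, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_mass_conserved(self, lysis, r):
        """C(r) * r^3 is constant: the released ion mass never changes."""
        left = lysis_concentration(lysis, "K+", r) * r**3
        right = 38.0 * lysis.r0**3
        assert left == pytest.approx(right, rel=1e-12)

    def test_inside_cell_out_of_domain(self, lysis):
        with pytest.raises(OutOfDomainError):
            lysis_concentration(lysis, "Na+", 0.5)

    def test_unknown_ion(self, lysis):
        with pytest.raises(MissingIonError):
            lysis_concentration(lysis, "Fe3+", 2.0)


class TestLysisCrossing:
    def test_sodium_infection_threshold(self, lysis):
        """212 mM cytoplasmic Na+ falls to the ~100 mM requirement at
        (212/100)^(1/3) ~ 1.285 cell radii."""
        d = lysis_crossing_distance(lysis, "Na+", 100.0)
        assert d == pytest.approx((212.0 / 100.0) ** (1 / 3), rel=1e-12)
        assert d == pytest.approx(1.285, abs=5e-4)
        assert d == pytest.approx(bisection_crossing(lysis, "Na+", 100.0), abs=1e-9)

    def test_threshold_above_cytoplasm_returns_cell_radius(self, lysis):
        assert lysis_crossing_distance(lysis, "Na+", 300.0) == lysis.r0

    @pytest.mark.parametrize("r0", [0.5, 1.0, 2.5])
    def test_scales_linearly_with_cell_radius(self, lysis, r0):
        scaled = LysisModel(cytoplasm=lysis.cytoplasm, r0=r0)
        assert lysis_crossing_distance(scaled, "K+", 10.0) == pytest.approx(
            r0 * lysis_crossing_distance(lysis, "K+", 10.0)
        )

    def test_matches_bisection_over_random_thresholds(self, lysis):
        rng = np.random.default_rng(42)
        for _ in range(50):
            thr = 10.0 ** rng.uniform(-2, 2.5)
            ion = rng.choice(list(lysis.cytoplasm.concentrations))
            assert lysis_crossing_distance(lysis, ion, thr) == pytest.approx(
                bisection_crossing(lysis, ion, thr), abs=1e-9
            )


class TestEvaporate:
    def test_cf_one_is_identity(self):
        sc = gen_springwater_scenario()
        assert evaporate(sc, 1.0).concentrations == sc.initial.concentrations

    def test_conservative_linear(self):
        sc = gen_springwater_scenario(na0=0.1)
        assert evaporate(sc, 1000.0).concentrations["Na+"] == pytest.approx(100.0)

    def test_ceiling_caps_divalent(self):
        sc = gen_springwater_scenario(ca0=0.1, ceilings={"Ca2+": 0.5, "Mg2+": 1.0})
        assert evaporate(sc, 10.0).concentrations["Ca2+"] == pytest.approx(0.5)

    def test_monotone_and_sequentially_consistent(self):
        sc = gen_springwater_scenario()
        curves = evaporation_curves(sc)
        for _, grp in curves.groupby("ion"):
            assert np.all(np.diff(grp.sort_values("cf")["conc_mM"]) >= 0)
        # conservative ions: concentrating by cf1 then cf2 equals cf1*cf2
        a = evaporate(sc, 12.0).concentrations["Na+"]
        b = evaporate(sc, 3.0).concentrations["Na+"] * 4.0
        assert a == pytest.approx(b)

    def test_cf_below_one_out_of_domain(self):
        with pytest.raises(OutOfDomainError):
            evaporate(gen_springwater_scenario(), 0.9)


class TestEvaporationCrossing:
    def test_threshold_already_met(self):
        sc = gen_springwater_scenario(na0=0.2)
        assert evaporation_crossing_factor(sc, "Na+", 0.1) == 1.0

    def test_conservative_closed_form(self):
        sc = gen_springwater_scenario(na0=0.1)
        assert evaporation_crossing_factor(sc, "Na+", 100.0) == pytest.approx(1000.0)

    def test_capped_ion_never_crosses(self):
        sc = gen_springwater_scenario(ceilings={"Ca2+": 0.5, "Mg2+": 1.0})
        assert evaporation_crossing_factor(sc, "Ca2+", 2.38) is None

    def test_matches_grid_scan_oracle(self):
        """Closed form vs a dense log-spaced grid scan, within one step."""
        rng = np.random.default_rng(7)
        grid = np.geomspace(1.0, 1e5, 10_000)
        step = np.log(grid[1] / grid[0])
        for _ in range(50):
            sc = gen_springwater_scenario(
                na0=10.0 ** rng.uniform(-2, 0), ca0=10.0 ** rng.uniform(-2, 0)
            )
            for ion in ("Na+", "Ca2+"):
                thr = 10.0 ** rng.uniform(-1, 2.5)
                closed = evaporation_crossing_factor(sc, ion, thr)
                scan = next(
                    (cf for cf in grid
                     if evaporate(sc, cf).concentrations[ion] >= thr),
                    None,
                )
                if closed is None or closed > grid[-1]:
                    assert scan is None or scan == grid[-1]
                else:
                    assert scan is not None
                    assert abs(np.log(scan) - np.log(closed)) <= step + 1e-12


class TestScenarioValidation:
    def test_grid_must_start_at_one(self):
        prof = IonProfile("w", {"Na+": 1.0}, {"Na+": 1})
        with pytest.raises(InvalidConfigError):
            EvaporationScenario(initial=prof, cf_grid=np.array([2.0, 3.0]))

    def test_nonpositive_ceiling_rejected(self):
        prof = IonProfile("w", {"Na+": 1.0}, {"Na+": 1})
        with pytest.raises(InvalidConfigError):
            EvaporationScenario(
                initial=prof, cf_grid=np.array([1.0, 2.0]), ceilings={"Na+": 0.0}
            )


def test_crossing_table_combines_models(lysis):
    sc = gen_springwater_scenario(na0=0.1)
    thresholds = {("T4", "Na+"): 100.0, ("T4", "Ca2+"): 2.38}
    table = crossing_table(thresholds, lysis=lysis, evaporation=sc)
    na_lysis = table.query("ion == 'Na+' and model == 'lysis_dilution'")
    na_evap = table.query("ion == 'Na+' and model == 'evaporation'")
    ca_evap = table.query("ion == 'Ca2+' and model == 'evaporation'")
    assert na_lysis["crossing"].iloc[0] == pytest.approx(2.12 ** (1 / 3))
    assert na_evap["crossing"].iloc[0] == pytest.approx(1000.0)
    assert np.isnan(ca_evap["crossing"].iloc[0])  # solubility-capped


def test_lysis_profile_curves_span_radius_range(lysis):
    curves = lysis_profile_curves(lysis, r_max=10.0, n=50)
    assert curves["r_um"].min() == 1.0
    assert curves["r_um"].max() == pytest.approx(10.0)
    assert set(curves["ion"]) == set(lysis.cytoplasm.concentrations)
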