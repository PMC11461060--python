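"""Isotope transfer functions, locality aggregation, seasonality."""

import math

import numpy as np
import pandas as pd
import pytest

from paleodent import isotopes as iso
from paleodent import synthetic
from paleodent.datamodel import ValidationError


class TestUnitOperations:
    def test_enrichment_factor(self):
        assert iso.enrichment_factor(1.0) == pytest.approx(math.e ** 2.42, rel=1e-12)
        assert iso.enrichment_factor(1000.0) == pytest.approx(14.03, abs=0.01)
        assert iso.enrichment_factor(670.0) == pytest.approx(13.85, abs=0.01)
        with pytest.raises(ValidationError):
            iso.enrichment_factor(0.0)

    def test_carbon_diet_arithmetic(self):
        atm = iso.AtmosphereContext(d13c_atm_past=-6.1)
        assert atm.corr == pytest.approx(1.9)
        assert iso.carbon_diet(-9.0, 13.85, atm) == pytest.approx(-24.75, abs=1e-9)
        # identity when both corrections vanish
        zero = iso.AtmosphereContext(d13c_atm_past=-8.0)
        assert iso.carbon_diet(-7.3, 0.0, zero) == pytest.approx(-7.3)

    @pytest.mark.parametrize("diet,c3,biome", [
        (-26.0, True, "woodland-mesic"),
        (-24.0, True, "open-xeric"),
        (-21.0, False, None),
    ])
    def test_classify_carbon_thresholds(self, diet, c3, biome):
        out = iso.classify_carbon(diet)
        assert out["c3"] is c3
        assert out["biome"] == biome

    def test_map_kohn_solved_form(self):
        assert iso.map_kohn(-24.75, 40.0, 0.0) == pytest.approx(8.4, abs=0.5)
        # root of the transfer function: exponent equals log10(300)
        root_diet = -(5.61 * math.log10(300.0) + 10.29)
        assert iso.map_kohn(root_diet, 0.0, 0.0) == pytest.approx(0.0, abs=1e-9)
        # decreasing the diet value by 1‰ multiplies (MAP + 300) by 10^(1/5.61)
        m0 = iso.map_kohn(-25.0, 0, 0) + 300
        m1 = iso.map_kohn(-26.0, 0, 0) + 300
        assert m1 / m0 == pytest.approx(10 ** (1 / 5.61), rel=1e-12)

    def test_map_rey_leaf_discrimination(self):
        mapv, leaf = iso.map_rey(-24.75, -6.1)
        assert leaf == pytest.approx(19.12, abs=0.01)
        assert mapv == pytest.approx(508.0, abs=2.0)
        # zero-discrimination limit is negative and flagged by sign
        zero = 10 ** 1.148 - 300
        mv, lf = iso.map_rey(-6.1, -6.1)
        assert lf == pytest.approx(0.0)
        assert mv == pytest.approx(zero) and mv < 0

    def test_map_rey_monotone_in_leaf_discrimination(self):
        diets = np.linspace(-30, -20, 50)
        maps = [iso.map_rey(d)[0] for d in diets]
        assert all(a > b for a, b in zip(maps, maps[1:]))

    def test_pdb_to_smow_affine(self):
        assert iso.pdb_to_smow(0.0) == pytest.approx(30.91)
        assert iso.pdb_to_smow(-3.4) == pytest.approx(27.405, abs=1e-3)
        assert iso.pdb_to_smow(-5.6) == pytest.approx(25.137, abs=1e-3)

    def test_precip_from_carbonate_rounded_and_exact_variants(self):
        assert iso.precip_from_carbonate(27.405) == pytest.approx(-5.347, abs=1e-3)
        assert iso.precip_from_carbonate(33.3 / 1.02) == pytest.approx(0.0, abs=1e-12)
        # rounded composition tracks the exact two-step form within 0.06‰
        for x in np.linspace(24, 30, 25):
            diff = abs(iso.precip_from_carbonate(x)
                       - iso.precip_from_carbonate(x, rounded=False))
            assert diff < 0.06

    def test_mat_calibrations(self):
        assert iso.mat_tutken(-14.178) == pytest.approx(0.0, abs=1e-12)
        assert iso.mat_tutken(-5.347) == pytest.approx(19.98, abs=0.01)
        assert iso.mat_tutken(-8.186) == pytest.approx(13.6, abs=0.1)
        assert iso.mat_skrzypek(0.0) == pytest.approx(23.63)
        assert iso.mat_skrzypek(-5.347) == pytest.approx(16.09, abs=0.01)
        assert iso.mat_skrzypek(-5.032) == pytest.approx(16.54, abs=0.01)

    def test_monotonicity_by_finite_differences(self):
        d18o = np.linspace(-10, 2, 40)
        mats = [iso.mat_tutken(iso.precip_from_carbonate(iso.pdb_to_smow(x)))
                for x in d18o]
        assert all(b > a for a, b in zip(mats, mats[1:]))


class TestLocalityClimate:
    def _samples(self, rows):
        return pd.DataFrame(rows)

    def test_single_sample_equals_unit_composition(self):
        df = self._samples([{
            "specimen_id": "S", "species": "T t", "locality": "L",
            "biozone": "MN2", "sampling": "bulk",
            "d13c_co3_pdb": -9.0, "d18o_co3_pdb": -3.1}])
        (est,) = iso.locality_climate(df, {"T t": 670.0})
        chain = iso.specimen_chain(-9.0, -3.1, 670.0)
        assert est.mat_tutken == pytest.approx(chain["mat_tutken"], rel=1e-12)
        assert est.map_rey == pytest.approx(chain["map_rey"], rel=1e-12)

    def test_specimen_weighted_mat_between_species_mats(self):
        rows = []
        for i in range(5):
            rows.append({"specimen_id": f"A{i}", "species": "A a", "locality": "L",
                         "biozone": "MN2", "sampling": "bulk",
                         "d13c_co3_pdb": -10.6, "d18o_co3_pdb": -5.3})
        for i in range(3):
            rows.append({"specimen_id": f"B{i}", "species": "B b", "locality": "L",
                         "biozone": "MN2", "sampling": "bulk",
                         "d13c_co3_pdb": -8.1, "d18o_co3_pdb": -5.1})
        (est,) = iso.locality_climate(self._samples(rows),
                                      {"A a": 1880.0, "B b": 500.0})
        mat_a = iso.specimen_chain(-10.6, -5.3, 1880.0)["mat_tutken"]
        mat_b = iso.specimen_chain(-8.1, -5.1, 500.0)["mat_tutken"]
        lo, hi = sorted([mat_a, mat_b])
        assert lo <= est.mat_tutken <= hi

    def test_kohn_negatives_excluded_and_flagged(self):
        # an enriched enamel value puts the latitude/altitude MAP below
        # zero for every specimen (diet near the C3/C4 boundary)
        rows = [{"specimen_id": f"S{i}", "species": "T t", "locality": "L",
                 "biozone": "MN2", "sampling": "bulk",
                 "d13c_co3_pdb": -6.0, "d18o_co3_pdb": -5.0} for i in range(3)]
        (est,) = iso.locality_climate(self._samples(rows), {"T t": 1000.0})
        assert est.map_kohn is None
        assert est.n_kohn_excluded == 3

    def test_missing_mass_is_an_error(self):
        df = self._samples([{"specimen_id": "S", "species": "X x", "locality": "L",
                             "biozone": "MN2", "sampling": "bulk",
                             "d13c_co3_pdb": -9.0, "d18o_co3_pdb": -3.1}])
        with pytest.raises(ValidationError):
            iso.locality_climate(df, {})

    def test_mat_recovered_within_half_degree_on_synthetic_locality(self, design):
        samples = synthetic.gen_isotopes(design)
        th = samples[samples["locality"] == "Thézels"]
        masses = {f"{r.species}@{r.locality}": r.body_mass_kg
                  for r in design.rows if r.body_mass_kg}
        (est,) = iso.locality_climate(th, masses)
        truth = iso.mat_tutken(iso.precip_from_carbonate(iso.pdb_to_smow(-3.4)))
        assert est.mat_tutken == pytest.approx(truth, abs=0.5)


class TestUncertainty:
    def test_analytical_precision_bounds_mat(self):
        assert iso.mat_uncertainty(0.3, "tutken") == pytest.approx(0.71, abs=0.02)
        assert iso.mat_uncertainty(0.3, "skrzypek") < iso.mat_uncertainty(0.3, "tutken")


class TestSeasonality:
    def test_noiseless_sinusoid_recovered_exactly(self):
        ser = synthetic.gen_serial_series(amplitude_d13c=0.5, amplitude_d18o=0.5,
                                          period_mm=30.0, n_points=12,
                                          noise_sd=0.0, phase=0.3)
        prof = iso.seasonality_profile(ser["serial_position_mm"],
                                       ser["d13c_co3_pdb"], ser["d18o_co3_pdb"])
        assert prof.fit["d13c"]["amplitude"] == pytest.approx(0.5, abs=1e-6)
        assert prof.d13c_range <= 1.0 + 1e-9

    def test_constant_series_flat_profile(self):
        pos = [0.0, 5.0, 10.0, 15.0]
        prof = iso.seasonality_profile(pos, [1.0] * 4, [2.0] * 4)
        assert prof.d13c_range == 0.0
        assert prof.fit["d13c"]["amplitude"] == pytest.approx(0.0, abs=1e-9)
        assert prof.spearman_rho is None  # rank correlation undefined

    def test_short_series_gives_ranges_only(self):
        prof = iso.seasonality_profile([0, 1, 2], [1, 2, 3], [2, 3, 4])
        assert prof.fit is None
        assert prof.d13c_range == 2.0

    def test_noisy_amplitude_recovery_and_correlation(self):
        amps_c, amps_o, rhos = [], [], []
        for seed in range(20):
            ser = synthetic.gen_serial_series(
                amplitude_d13c=0.5, amplitude_d18o=1.25, period_mm=30.0,
                n_points=12, noise_sd=0.1, phase=0.7, seed=seed)
            prof = iso.seasonality_profile(ser["serial_position_mm"],
                                           ser["d13c_co3_pdb"],
                                           ser["d18o_co3_pdb"])
            amps_c.append(prof.fit["d13c"]["amplitude"])
            amps_o.append(prof.fit["d18o"]["amplitude"])
            rhos.append(prof.spearman_rho)
        assert np.mean(amps_c) == pytest.approx(0.5, rel=0.15)
        assert np.mean(amps_o) == pytest.approx(1.25, rel=0.15)
        assert np.mean(rhos) > 0.5
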