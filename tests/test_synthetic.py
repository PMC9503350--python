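import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from adipoquant import (
    BloodCurveParams,
    CohortConfig,
    MioConfig,
    Tac,
    VolumeGeometry,
    blood_curve,
    extract_hu,
    extract_tac,
    generate_cohort,
    tissue_tac,
)
from adipoquant.synthetic import rasterize_animal


class TestBloodCurve:
    def test_zero_at_injection(self):
        params = BloodCurveParams(1.0, 0.1, 1.0)
        assert blood_curve(params, [0.0])[0] == 0.0

    def test_peak_location_and_value(self):
        # d/dt of the two-exponential vanishes at ln(a/c)/(a-c)
        params = BloodCurveParams(1.0, 0.1, 1.0)
        t = np.linspace(0, 20, 200001)
        values = blood_curve(params, t)
        assert t[np.argmax(values)] == pytest.approx(np.log(10) / 0.9, abs=1e-3)
        assert values.max() == pytest.approx(1.0, rel=1e-9)

    def test_linear_in_amplitude(self):
        t = np.linspace(0, 60, 61)
        one = blood_curve(BloodCurveParams(0.3, 0.05, 10.0), t)
        two = blood_curve(BloodCurveParams(0.3, 0.05, 20.0), t)
        assert np.allclose(two, 2 * one)

    def test_nonnegative_and_clearing(self):
        params = BloodCurveParams(0.3, 0.05, 150.0)
        values = blood_curve(params, np.linspace(0, 600, 1000))
        assert np.all(values >= 0)
        assert values[-1] < 1e-8 * values.max()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BloodCurveParams(0.3, 0.3, 1.0)
        with pytest.raises(ValueError):
            BloodCurveParams(-0.3, 0.05, 1.0)
        with pytest.raises(ValueError):
            blood_curve(BloodCurveParams(0.3, 0.05, 1.0), [-1.0])


class TestTissueTac:
    def test_zero_extraction_zero_spill_gives_zero_curve(self, default_blood_tac):
        tac = tissue_tac(default_blood_tac, 0.0, 0.0, 0.0)
        assert np.allclose(tac.activity, 0.0)

    def test_constant_blood_integrates_linearly(self):
        # with blood fixed at 1 kBq/mL, tissue(t) = ge * t
        from adipoquant import FrameSchedule

        starts = np.arange(0.0, 60.0, 0.05)
        sched = FrameSchedule(starts, np.full(starts.size, 0.05))
        blood = Tac(sched, np.ones(starts.size), "blood")
        tac = tissue_tac(blood, 0.01)
        # constant absolute offset ge*dt/4 from the prepended (0, 0) origin
        assert np.allclose(tac.activity, 0.01 * sched.mid, atol=2e-4)

    def test_negative_noise_rejected(self, default_blood_tac):
        with pytest.raises(ValueError):
            tissue_tac(default_blood_tac, 0.01, noise_sd=-0.1)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = dataclasses.replace(CohortConfig(), n_per_cell=3, seed=11)
        b1, b2 = generate_cohort(cfg), generate_cohort(cfg)
        assert b1.animals.equals(b2.animals)
        for roi in b1.tac_activity:
            assert np.array_equal(b1.tac_activity[roi], b2.tac_activity[roi])
        for key in b1.abundances:
            assert b1.abundances[key].data.equals(b2.abundances[key].data)

    def test_zero_mio_fraction_means_no_mio(self):
        cfg = dataclasses.replace(
            CohortConfig(),
            n_per_cell=4,
            seed=5,
            mio=MioConfig(fraction_male=0.0, fraction_female=0.0),
        )
        bundle = generate_cohort(cfg)
        assert not (bundle.animals["latent_class"] == "MIO").any()

    def test_latent_class_only_in_adult_hfd(self, small_bundle):
        animals = small_bundle.animals
        classed = animals[animals["latent_class"] != "none"]
        assert (classed["age_group"] == "6mo").all()
        assert (classed["maternal_diet"] == "HFD").all()

    def test_mio_and_mior_weights_separate(self, small_bundle):
        animals = small_bundle.animals
        mio = animals.loc[animals["latent_class"] == "MIO", "body_weight"]
        mior = animals.loc[animals["latent_class"] == "MIOR", "body_weight"]
        assert len(mio) and len(mior)
        assert mio.min() > mior.max()

    def test_abundance_rows_sum_to_one(self, small_bundle):
        for table in small_bundle.abundances.values():
            sums = table.data.to_numpy().sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_adult_male_hfd_cell_mean_weight(self, cohort500):
        # MIO/MIOR mixture reproduces the reported 38 g cell mean within 2%
        animals = cohort500.animals
        cell = animals[
            (animals.age_group == "6mo")
            & (animals.maternal_diet == "HFD")
            & (animals.sex == "M")
        ]
        assert cell["body_weight"].mean() == pytest.approx(38.0, rel=0.02)

    def test_copula_hits_target_rho_at_large_n(self, cohort500):
        truth = cohort500.truth.set_index("animal_id")
        age = cohort500.animals.set_index("animal_id")["age_group"]
        for taxon in cohort500.config.taxa:
            if taxon.assoc is None:
                continue
            param, rho_target, age_group = taxon.assoc
            ids = age.index[age == age_group]
            observed = spearmanr(
                truth.loc[ids, param],
                cohort500.abundances[(taxon.site, taxon.level)].data.loc[ids, taxon.name],
            ).statistic
            assert observed == pytest.approx(rho_target, abs=0.05), taxon.name

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_per_cell"):
            generate_cohort(dataclasses.replace(CohortConfig(), n_per_cell=1))
        with pytest.raises(ValueError, match="correlation structure"):
            generate_cohort(dataclasses.replace(CohortConfig(), n_per_cell=2))

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = dataclasses.replace(CohortConfig(), n_per_cell=3, seed=9)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        loaded = CohortConfig.from_yaml(path)
        assert loaded.content_hash() == cfg.content_hash()
        assert generate_cohort(loaded).animals.equals(generate_cohort(cfg).animals)


class TestRasterize:
    def test_noise_free_round_trip_is_exact(self, small_bundle):
        animal = small_bundle.animal_ids[0]
        tacs = {roi: small_bundle.tac(animal, roi) for roi in ("SAT", "BAT", "blood")}
        pet, ct, mask = rasterize_animal(tacs, sat_hu=-94.0, bat_hu=-50.0)
        extracted = extract_tac(pet, mask, 1, small_bundle.schedule)
        # uniform boxes: the ROI mean is the painted value (to accumulation ulps)
        assert np.allclose(extracted.activity, tacs["SAT"].activity, rtol=1e-13)
        assert extract_hu(ct, mask, 1).mean_hu == pytest.approx(-94.0, abs=1e-10)
        assert extract_hu(ct, mask, 2).mean_hu == pytest.approx(-50.0, abs=1e-10)

    def test_painted_hu_recovered_within_one_hu_under_noise(self, small_bundle):
        animal = small_bundle.animal_ids[0]
        tacs = {roi: small_bundle.tac(animal, roi) for roi in ("SAT", "BAT", "blood")}
        geometry = VolumeGeometry(ct_noise_sd=5.0)
        pet, ct, mask = rasterize_animal(
            tacs, -94.0, -50.0, geometry, np.random.default_rng(0)
        )
        density = extract_hu(ct, mask, 1)
        assert density.voxel_count >= 125
        assert density.mean_hu == pytest.approx(-94.0, abs=1.0)

    def test_overlapping_boxes_rejected(self):
        geometry = VolumeGeometry(
            boxes={"SAT": ((0, 5), (0, 5), (0, 5)), "BAT": ((3, 8), (0, 5), (0, 5))}
        , labels={"SAT": 1, "BAT": 2})
        with pytest.raises(ValueError, match="overlap"):
            geometry.mask()

    def test_missing_label_fails_downstream(self):
        geometry = VolumeGeometry()
        mask = geometry.mask()
        with pytest.raises(ValueError, match="empty ROI"):
            extract_hu(np.zeros(geometry.shape), mask, 9)
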