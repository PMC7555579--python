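"""Phantom rendering, response scenarios, cohort generation, noise model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rice

from wbdwi import (
    CMR_SCENARIO,
    PMR_SCENARIO,
    CohortParams,
    LesionSpec,
    PhantomSpec,
    ResponseScenario,
    apply_scenario,
    default_torso_spec,
    load_manifest,
    make_cohort,
    render_phantom,
)
from wbdwi.errors import EmptyCohortError, ParameterError


def single_lesion_spec(noise=0.0, seed=0, radius=16.0, adc_sd=150.0):
    return default_torso_spec(
        shape=(32, 32, 48), spacing=(4.0, 4.0, 8.0),
        lesions=(LesionSpec((40.0, 50.0, 120.0), (radius,) * 3, adc_sd=adc_sd),),
        noise_sigma=noise, seed=seed, include_organs=False,
    )


class TestRendering:
    def test_same_seed_bit_identical(self):
        a, _ = render_phantom(single_lesion_spec(noise=5.0, seed=42))
        b, _ = render_phantom(single_lesion_spec(noise=5.0, seed=42))
        for bval in (50, 800):
            assert np.array_equal(a.volumes[bval].data, b.volumes[bval].data)

    def test_different_seeds_differ(self):
        a, _ = render_phantom(single_lesion_spec(noise=5.0, seed=1))
        b, _ = render_phantom(single_lesion_spec(noise=5.0, seed=2))
        assert not np.array_equal(a.volumes[800].data, b.volumes[800].data)

    def test_ellipsoid_ground_truth_volume(self):
        # (10, 10, 10) mm ellipsoid at 2 mm spacing vs analytic 4.18879 cm^3
        spec = PhantomSpec(
            shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
            lesions=(LesionSpec((31.0, 31.0, 31.0), (10.0, 10.0, 10.0)),),  # voxel-center aligned
            noise_sigma=0.0, seed=0,
        )
        _, truth = render_phantom(spec)
        analytic = 4.0 / 3.0 * math.pi  # cm^3
        assert truth.lesion_volumes_cm3[0] == pytest.approx(analytic, rel=0.05)

    def test_lesion_out_of_grid_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec(shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0),
                        lesions=(LesionSpec((2.0, 16.0, 16.0), (10.0, 10.0, 10.0)),))

    def test_lesion_precedence_over_organ_warns(self):
        spec = default_torso_spec(
            shape=(32, 32, 48), spacing=(4.0, 4.0, 8.0),
            lesions=(LesionSpec((64.0, 64.0, 190.0), (18.0, 18.0, 18.0)),),
            noise_sigma=0.0, seed=0,
        )
        with pytest.warns(UserWarning, match="lesion takes precedence"):
            _, truth = render_phantom(spec)
        assert truth.lesion_mask().sum() > 0

    def test_rician_mean_matches_analytic(self):
        """Magnitude-noise bias of the rendered b800 signal: at lesion SNR >= 5
        the sample mean matches the analytic Rician mean and is < 3% above
        the true signal."""
        clean, truth = render_phantom(single_lesion_spec(noise=0.0, seed=3, radius=24.0, adc_sd=0.0))
        noisy, _ = render_phantom(single_lesion_spec(noise=90.0, seed=3, radius=24.0, adc_sd=0.0))
        lesion = truth.lesion_mask()
        nu = float(clean.volumes[800].data[lesion].mean())  # ~487 a.u. -> SNR ~5.4
        sigma = 90.0
        assert nu / sigma > 5
        observed = float(noisy.volumes[800].data[lesion].mean())
        analytic = rice.mean(b=nu / sigma, scale=sigma)
        assert observed == pytest.approx(analytic, rel=0.02)
        assert (observed - nu) / nu < 0.03


class TestScenarios:
    def test_cube_root_radius_scaling(self):
        spec = single_lesion_spec()
        sc = ResponseScenario("CMR", volume_factors=(0.125, 0.125), adc_factors=(1.0, 1.0))
        t1 = apply_scenario(spec, sc)[1]
        assert t1.lesions[0].radii == pytest.approx(tuple(r / 2 for r in spec.lesions[0].radii))

    def test_identity_scenario_changes_only_seed(self):
        spec = single_lesion_spec(seed=9)
        sc = ResponseScenario("PMR", volume_factors=(1.0, 1.0), adc_factors=(1.0, 1.0),
                              marrow_activation=False)
        specs = apply_scenario(spec, sc)
        assert specs[0] is spec
        assert specs[1].lesions == spec.lesions
        assert specs[1].organs == spec.organs
        assert specs[1].seed != spec.seed

    def test_cmr_t2_volume_is_five_percent(self):
        spec = PhantomSpec(
            shape=(32, 32, 32), spacing=(2.0, 2.0, 2.0),
            lesions=(LesionSpec((32.0, 32.0, 32.0), (20.0, 20.0, 20.0)),),
            noise_sigma=0.0, seed=0,
        )
        specs = apply_scenario(spec, CMR_SCENARIO)
        _, truth0 = render_phantom(specs[0])
        _, truth2 = render_phantom(specs[2])
        ratio = truth2.total_lesion_volume_cm3 / truth0.total_lesion_volume_cm3
        assert ratio == pytest.approx(0.05, rel=0.15)  # voxelization at small radii

    def test_adc_factor_applied(self):
        spec = single_lesion_spec()
        specs = apply_scenario(spec, CMR_SCENARIO)
        assert specs[1].lesions[0].adc_mean == pytest.approx(900.0 * 1.30)
        assert specs[2].lesions[0].adc_mean == pytest.approx(900.0 * 1.45)

    def test_marrow_activation_raises_s0(self):
        spec = default_torso_spec(shape=(24, 24, 32), spacing=(4, 4, 8))
        specs = apply_scenario(spec, CMR_SCENARIO)
        s0 = {o.name: o.tissue.s0 for o in specs[1].organs}
        base = {o.name: o.tissue.s0 for o in spec.organs}
        assert s0["bone_marrow"] == pytest.approx(base["bone_marrow"] * 1.6)
        assert s0["brain"] == base["brain"]

    def test_scenario_validation(self):
        with pytest.raises(ParameterError):
            ResponseScenario("CMR", volume_factors=(0.0, 0.5), adc_factors=(1.0, 1.0))
        # default scenarios: CMR shrinks at least as much as PMR at each timepoint
        assert all(c <= p for c, p in zip(CMR_SCENARIO.volume_factors, PMR_SCENARIO.volume_factors))


class TestCohort:
    def test_make_cohort_writes_everything(self, tmp_path):
        manifest, truth = make_cohort(
            2, 2, tmp_path, seed=5, shape=(24, 24, 32), spacing=(4.0, 4.0, 8.0),
            noise_sigma=5.0,
        )
        assert len(manifest) == 4
        assert manifest.label_counts(1) == {"CMR": 2, "PMR": 2, "SMD": 0, "PMD": 0}
        loaded = load_manifest(tmp_path / "manifest.yaml", check_files=True)
        assert [p.patient_id for p in loaded] == [p.patient_id for p in manifest]
        gt = pd.read_csv(tmp_path / "ground_truth.csv")
        assert len(gt) == 4 * 3  # patient x timepoint
        # responders shrink more: T2/T0 volume ratio lower for CMR
        by = gt.pivot_table(index=["patient_id", "label"], columns="timepoint",
                            values="true_lesion_volume_cm3").reset_index("label")
        ratios = by[2] / by[0]
        assert ratios[by.label == "CMR"].max() < ratios[by.label == "PMR"].min()

    def test_reproducible_from_seed(self, tmp_path):
        import nibabel as nib

        make_cohort(1, 1, tmp_path / "a", seed=3, shape=(16, 16, 24),
                    spacing=(4.0, 4.0, 8.0))
        make_cohort(1, 1, tmp_path / "b", seed=3, shape=(16, 16, 24),
                    spacing=(4.0, 4.0, 8.0))
        for f in sorted((tmp_path / "a").glob("*.nii.gz")):
            a = np.asarray(nib.load(f).dataobj)
            b = np.asarray(nib.load(tmp_path / "b" / f.name).dataobj)
            assert np.array_equal(a, b), f.name

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(EmptyCohortError):
            make_cohort(0, 0, tmp_path)

    def test_responder_effect_direction_at_lesion_dominated_threshold(self, tmp_path):
        """Across replicate cohorts, complete responders show a larger T0->T1
        rise in masked ADC spread (ADCsd) and upper tail (ADC95p) than partial
        responders at the 40% threshold, where lesions dominate the mask."""
        from wbdwi import delta_table, extract_cohort_features

        wins_sd = wins_95 = 0
        n_rep = 8
        for rep in range(n_rep):
            out = tmp_path / f"rep{rep}"
            manifest, _ = make_cohort(3, 3, out, seed=3000 + rep, shape=(48, 48, 80),
                                      spacing=(4.0, 4.0, 8.0), noise_sigma=8.0)
            feats, _, _ = extract_cohort_features(manifest)
            deltas = delta_table(feats)
            labels = manifest.labels(1)
            d01 = deltas[(deltas.pair == "01") & (deltas.threshold_percent == 40.0)].copy()
            d01["lab"] = d01.patient_id.map(labels)
            for name, counter in (("ADCsd", "sd"), ("ADC95p", "95")):
                s = d01[d01.feature_name == name]
                cmr = s[s.lab == "CMR"]["value"].mean()
                pmr = s[s.lab == "PMR"]["value"].mean()
                if name == "ADCsd":
                    wins_sd += cmr > pmr
                else:
                    wins_95 += cmr > pmr
        assert wins_sd / n_rep >= 0.8
        assert wins_95 / n_rep >= 0.8

    def test_pmr_baseline_load_higher_on_average(self, tmp_path):
        _, truth = make_cohort(3, 3, tmp_path, seed=11, shape=(32, 32, 40),
                               spacing=(4.0, 4.0, 8.0), noise_sigma=0.0,
                               params=CohortParams(pmr_baseline_volume_factor=2.5))
        t0 = truth[truth.timepoint == 0]
        assert (t0[t0.label == "PMR"].true_lesion_volume_cm3.mean()
                > t0[t0.label == "CMR"].true_lesion_volume_cm3.mean())
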