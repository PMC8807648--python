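"""Generator tests: panels, profiles, rendering, cohort bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from mnalci.constants import BIOMARKERS, CLASSES, MATRICES
from mnalci.synth_cohort import (
    AcquisitionConfig,
    CohortConfig,
    CohortConfigError,
    MetabolitePanel,
    PanelEntry,
    build_panel,
    calibrant_panel,
    default_profiles,
    gns_profile,
    render_spectrum,
    simulate_cohort,
    simulate_feature_cohort,
    simulate_profile,
    sinw_profile,
)


def small_acq(**kw) -> AcquisitionConfig:
    defaults = dict(
        spots_per_sample=2,
        shots_per_spot=2,
        mz_grid=np.arange(100.0, 1000.0 + 0.25, 0.5),
        noise_sd=0.0,
        baseline_amplitude=0.0,
        shot_scale_sd=0.0,
    )
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


class TestPanel:
    def test_minimal_panel_is_the_eight_biomarkers(self):
        panel = build_panel(size=8, rng_seed=0)
        assert panel.names == [name for name, _ in BIOMARKERS]
        assert (panel.effect_table.to_numpy() == 0).all()
        fixed = dict(BIOMARKERS)
        assert panel.entries[3].mz == pytest.approx(fixed["5-hydroxymethyluracil"])

    def test_seed_determinism(self):
        a = build_panel(size=50, rng_seed=1)
        b = build_panel(size=50, rng_seed=1)
        assert a.entries == b.entries
        pd.testing.assert_frame_equal(a.effect_table, b.effect_table)

    def test_effect_table_nonzero_count(self):
        effects = {"HCC": {f"bg_{i:03d}": 1.0 for i in range(5)}}
        panel = build_panel(size=50, rng_seed=2, effects=effects)
        assert int((panel.effect_table.loc["HCC"] != 0).sum()) == 5

    def test_size_below_eight_rejected(self):
        with pytest.raises(CohortConfigError, match="8"):
            build_panel(size=7)

    def test_invalid_entries_rejected(self):
        with pytest.raises(CohortConfigError):
            MetabolitePanel(
                entries=[PanelEntry("x", 50.0, 1.0)],
                effect_table=pd.DataFrame(0.0, index=["HC"], columns=["x"]),
            )
        with pytest.raises(CohortConfigError):
            MetabolitePanel(
                entries=[PanelEntry("x", 500.0, -1.0)],
                effect_table=pd.DataFrame(0.0, index=["HC"], columns=["x"]),
            )

    def test_band_quota_places_background(self):
        panel = build_panel(size=48, rng_seed=3, band_quota=((210, 290, 6), (110, 190, 6)))
        mz = dict(zip(panel.names, panel.mzs))
        assert all(210 <= mz[f"bg_{i:03d}"] <= 290 for i in range(6))
        assert all(110 <= mz[f"bg_{i:03d}"] <= 190 for i in range(6, 12))


class TestMatrixProfiles:
    def test_band_enhancement_invariants(self):
        gns, sinw = gns_profile(), sinw_profile()
        assert gns.mean_gain(200, 300) > gns.mean_gain(300, 1000)
        assert gns.mean_gain(200, 300) > gns.mean_gain(100, 200)
        assert sinw.mean_gain(100, 200) > sinw.mean_gain(200, 1000)

    def test_gain_nonnegative(self):
        mz = np.linspace(100, 1000, 500)
        for prof in default_profiles().values():
            assert (prof.gain(mz) >= 0).all()


class TestProfileSimulation:
    def test_healthy_no_noise_is_identity(self):
        panel = build_panel(size=10, rng_seed=0)
        out = simulate_profile(panel, "HC", np.random.default_rng(0), bio_sd=0.0)
        np.testing.assert_allclose(out, panel.base_abundances)

    def test_planted_log2_effect_doubles_target(self):
        effects = {"HCC": {"glucose": float(np.log(2.0))}}
        panel = build_panel(size=10, rng_seed=0, effects=effects)
        out = simulate_profile(panel, "HCC", np.random.default_rng(0), bio_sd=0.0)
        ratio = out / panel.base_abundances
        target = panel.names.index("glucose")
        assert ratio[target] == pytest.approx(2.0)
        others = np.delete(ratio, target)
        np.testing.assert_allclose(others, 1.0)

    def test_lognormal_noise_sd_recovered(self):
        panel = build_panel(size=8, rng_seed=0)
        rng = np.random.default_rng(7)
        draws = np.array([simulate_profile(panel, "HC", rng, bio_sd=0.3) for _ in range(1000)])
        log_sd = np.log(draws / panel.base_abundances).std(axis=0).mean()
        assert abs(log_sd - 0.3) < 0.03

    def test_unknown_class_rejected(self):
        panel = build_panel(size=8, rng_seed=0)
        panel.effect_table = panel.effect_table.drop(index="PTC")
        with pytest.raises(CohortConfigError, match="PTC"):
            simulate_profile(panel, "PTC", np.random.default_rng(0))


class TestRendering:
    def test_default_acquisition_yields_500_shots(self):
        panel = build_panel(size=8, rng_seed=0)
        acq = small_acq(spots_per_sample=20, shots_per_spot=25)
        shots = render_spectrum(
            panel.base_abundances, panel, gns_profile(), acq, np.random.default_rng(0)
        )
        assert len(shots) == 500 == acq.accumulated_shots

    def test_single_metabolite_renders_gaussian(self):
        entries = [PanelEntry("glucose", 180.16, 5.0)]
        panel = MetabolitePanel(entries, pd.DataFrame(0.0, index=["HC"], columns=["glucose"]))
        acq = small_acq(spots_per_sample=1, shots_per_spot=1, mz_grid=np.arange(175, 185, 0.02))
        from mnalci.synth_cohort import MatrixProfile

        unit = MatrixProfile("GNS", lambda mz: np.ones_like(mz))
        (shot,) = render_spectrum(np.array([5.0]), panel, unit, acq, np.random.default_rng(0))
        sigma = acq.fwhm / (2 * np.sqrt(2 * np.log(2)))
        expected = 5.0 * np.exp(-0.5 * ((acq.mz_grid - 180.16) / sigma) ** 2)
        # peaks render with compact +/-6 sigma support, hence the atol floor
        np.testing.assert_allclose(shot.intensity, expected, atol=1e-7)

    def test_band_contrast_between_matrices(self):
        panel = build_panel(size=40, rng_seed=1)
        acq = small_acq(spots_per_sample=1, shots_per_spot=1)
        rng = np.random.default_rng(0)
        gns_shot = render_spectrum(panel.base_abundances, panel, gns_profile(), acq, rng)[0]
        sinw_shot = render_spectrum(panel.base_abundances, panel, sinw_profile(), acq, rng)[0]

        def band_sum(spec, lo, hi):
            mask = (spec.mz >= lo) & (spec.mz < hi)
            return spec.intensity[mask].sum()

        assert band_sum(gns_shot, 200, 300) > band_sum(sinw_shot, 200, 300)
        assert band_sum(sinw_shot, 100, 200) > band_sum(gns_shot, 100, 200)
        # ratio form of the invariant
        ratio_band = band_sum(gns_shot, 200, 300) / band_sum(sinw_shot, 200, 300)
        ratio_low = band_sum(gns_shot, 100, 200) / band_sum(sinw_shot, 100, 200)
        assert ratio_band > ratio_low

    def test_planted_effect_monotone_in_peak_height(self):
        acq = small_acq(spots_per_sample=1, shots_per_spot=1)
        heights = []
        for logfc in (0.0, 0.5, 1.0, 1.5):
            effects = {"HCC": {"glucose": logfc}} if logfc else None
            panel = build_panel(size=8, rng_seed=0, effects=effects)
            abund = simulate_profile(panel, "HCC" if logfc else "HC", np.random.default_rng(0), 0.0)
            shot = render_spectrum(abund, panel, sinw_profile(), acq, np.random.default_rng(0))[0]
            apex = np.argmin(np.abs(shot.mz - 180.16))
            heights.append(shot.intensity[apex])
        assert all(b > a for a, b in zip(heights, heights[1:]))


class TestCohorts:
    def test_cohort_determinism_is_bitwise(self):
        panel = build_panel(size=10, rng_seed=0)
        config = CohortConfig(
            class_counts={"HC": 3, "HCC": 3}, panel=panel, acquisition=small_acq()
        )
        store1, meta1, truth1 = simulate_cohort(config, rng_seed=5)
        store2, meta2, truth2 = simulate_cohort(config, rng_seed=5)
        pd.testing.assert_frame_equal(meta1, meta2)
        for key in store1:
            for a, b in zip(store1[key], store2[key]):
                np.testing.assert_array_equal(a.intensity, b.intensity)
        for sid in truth1.abundances:
            np.testing.assert_array_equal(truth1.abundances[sid], truth2.abundances[sid])

    def test_cohort_counts_and_spectrum_sets(self):
        panel = build_panel(size=8, rng_seed=0)
        config = CohortConfig(
            class_counts={cls: 20 for cls in CLASSES},
            panel=panel,
            acquisition=small_acq(spots_per_sample=1, shots_per_spot=1),
        )
        store, meta, _ = simulate_cohort(config, rng_seed=0)
        assert len(meta) == 140
        assert len(store) == 280  # every sample under both matrices
        assert set(m for _, m in store) == set(MATRICES)

    def test_split_is_80_20_per_class(self):
        panel = build_panel(size=8, rng_seed=0)
        config = CohortConfig(class_counts={"HC": 100, "HCC": 100}, panel=panel)
        _, meta, _ = simulate_feature_cohort(config, rng_seed=0)
        for cls in ("HC", "HCC"):
            sub = meta[meta["class_label"] == cls]
            assert (sub["split"] == "train").sum() == 80
            assert (sub["split"] == "internal_validation").sum() == 20

    def test_degenerate_configs_rejected(self):
        panel = build_panel(size=8, rng_seed=0)
        with pytest.raises(CohortConfigError):
            CohortConfig(class_counts={"HC": 0, "HCC": 3}, panel=panel)
        with pytest.raises(CohortConfigError):
            CohortConfig(class_counts={"HC": 5}, panel=panel)

    def test_feature_cohort_determinism_and_shape(self):
        panel = build_panel(size=12, rng_seed=0)
        config = CohortConfig(class_counts={"HC": 4, "CRC": 4}, panel=panel)
        f1, meta1, _ = simulate_feature_cohort(config, rng_seed=3)
        f2, _, _ = simulate_feature_cohort(config, rng_seed=3)
        for tag in MATRICES:
            pd.testing.assert_frame_equal(f1[tag], f2[tag])
            assert f1[tag].shape == (8, 1800)
            np.testing.assert_allclose(f1[tag].sum(axis=1), 1.0)

    def test_ground_truth_roundtrip(self, tmp_path):
        panel = build_panel(size=8, rng_seed=0)
        config = CohortConfig(class_counts={"HC": 2, "GC": 2}, panel=panel)
        _, _, truth = simulate_feature_cohort(config, rng_seed=1)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        from mnalci.synth_cohort import GroundTruth

        back = GroundTruth.from_json(path)
        assert back.seed == truth.seed
        assert back.panel_entries == truth.panel_entries
        np.testing.assert_allclose(
            back.abundances["HC000"], truth.abundances["HC000"]
        )
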