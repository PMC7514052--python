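import math

import numpy as np
import pandas as pd
import pytest

from fociq import (CrowdedFieldError, FieldGeometry, GeneModel, SceneConfig,
                   example_scene, generate_exposure_series, generate_field,
                   generate_steady_state_counts)
from conftest import clean_scene


def roi_mean(img, x_um, y_um, r_um, geometry):
    s = geometry.px_per_um
    yy, xx = np.ogrid[:img.shape[0], :img.shape[1]]
    mask = (xx - x_um * s) ** 2 + (yy - y_um * s) ** 2 <= (r_um * s) ** 2
    return float(img[mask].mean())


# An inter-probe transcription time of exactly 11 h at the default
# 16 h / 2.3 Mbp rate corresponds to 1,581,250 bp of separation.
GENE_11H = GeneModel(regions={"5p": (0, 100_000),
                              "3p": (1_600_000, 1_681_250)})


class TestGenerateField:
    def test_empty_scene_is_background_only(self, quarter_geom):
        cfg = SceneConfig(geometry=quarter_geom, n_nuclei=0, n_pairs=0,
                          n_orphan_5p=0, n_orphan_3p=0, n_large_foci=0,
                          background_au=(2.0, 0.0), photons_per_au=None,
                          seed=5)
        sim = generate_field(cfg)
        assert sim.truth.empty
        for img in sim.images.values():
            assert img.shape == (quarter_geom.height_px, quarter_geom.width_px)
            np.testing.assert_allclose(img, 2.0)

    def test_identical_seed_is_bit_identical(self, quarter_geom):
        a = generate_field(example_scene("wt", geometry=quarter_geom, seed=9))
        b = generate_field(example_scene("wt", geometry=quarter_geom, seed=9))
        for c in a.images:
            np.testing.assert_array_equal(a.images[c], b.images[c])
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self, quarter_geom):
        a = generate_field(example_scene("wt", geometry=quarter_geom, seed=9))
        b = generate_field(example_scene("wt", geometry=quarter_geom, seed=10))
        assert not np.array_equal(a.images["5p"], b.images["5p"])

    def test_planted_counts_are_poisson_around_means(self):
        # healthy-animal configuration: per-channel small-focus means
        # 585 (5') and 710 (3'); a single draw stays within 3 sqrt(lam)
        cfg = SceneConfig(n_pairs=250, n_orphan_5p=335, n_orphan_3p=460,
                          n_nuclei=300, n_large_foci=80, seed=21)
        truth = generate_field(cfg).truth
        small = truth[truth.kind == "small_focus"]
        for channel, lam in (("5p", 585.0), ("3p", 710.0)):
            n = (small.channel == channel).sum()
            assert abs(n - lam) < 3 * math.sqrt(lam)

    def test_ground_truth_pair_structure(self, wt_field):
        small = wt_field.truth[wt_field.truth.kind == "small_focus"]
        paired = small.dropna(subset=["pair_id"])
        for pid, grp in paired.groupby("pair_id"):
            assert sorted(grp.channel) == ["3p", "5p"]
            (x5, y5), (x3, y3) = grp[["x_um", "y_um"]].to_numpy()
            d = math.hypot(x5 - x3, y5 - y3)
            assert d <= wt_field.config.pair_offset_um + 1e-9

    def test_all_small_foci_outside_nuclei_when_fraction_zero(self,
                                                              quarter_geom):
        cfg = clean_scene(quarter_geom, frac_small_in_nucleus=0.0, seed=3)
        truth = generate_field(cfg).truth
        nuclei = truth[truth.kind == "nucleus"]
        radii = np.sqrt(nuclei.area_um2.to_numpy() / math.pi)
        small = truth[truth.kind == "small_focus"]
        assert (small.compartment == "sarcoplasmic").all()
        for _, f in small.iterrows():
            d = np.hypot(nuclei.x_um.to_numpy() - f.x_um,
                         nuclei.y_um.to_numpy() - f.y_um)
            assert (d > radii).all()

    def test_large_foci_lie_wholly_inside_nuclei(self, wt_field):
        truth = wt_field.truth
        nuclei = truth[truth.kind == "nucleus"]
        radii = np.sqrt(nuclei.area_um2.to_numpy() / math.pi)
        for _, f in truth[truth.kind == "large_focus"].iterrows():
            r_focus = math.sqrt(f.area_um2 / math.pi)
            d = np.hypot(nuclei.x_um.to_numpy() - f.x_um,
                         nuclei.y_um.to_numpy() - f.y_um)
            assert (d + r_focus <= radii + 1e-6).any()
            assert f.compartment == "nuclear"

    def test_crowded_field_raises(self):
        tiny = FieldGeometry(width_px=60, height_px=60)
        cfg = SceneConfig(geometry=tiny, n_nuclei=200, n_pairs=0,
                          n_orphan_5p=0, n_orphan_3p=0, n_large_foci=0,
                          seed=0)
        with pytest.raises(CrowdedFieldError):
            generate_field(cfg)

    @pytest.mark.parametrize("bad", [
        dict(n_pairs=-1), dict(frac_small_in_nucleus=1.5),
        dict(large_focus_area_um2_range=(5.0, 50.0)),
        dict(pair_offset_um=-0.1), dict(field_effect_cv=-0.2),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneConfig(**bad)


class TestExposureSeries:
    def test_linear_scaling_without_saturation(self, quarter_geom):
        cfg = clean_scene(quarter_geom, seed=7)
        ser = generate_exposure_series(cfg, [100, 200],
                                       saturation_au=math.inf)
        np.testing.assert_allclose(ser.images[1], 2.0 * ser.images[0])

    def test_large_foci_clip_while_small_and_background_stay_linear(
            self, quarter_geom):
        from fociq import ExposureSeries, check_linearity
        exposures = [100, 200, 400, 600, 800]
        cfg = clean_scene(quarter_geom, seed=7)
        ser = generate_exposure_series(cfg, exposures, saturation_au=35.0)
        truth = ser.truth
        lf = truth[truth.kind == "large_focus"].iloc[0]
        sf = truth[(truth.kind == "small_focus")
                   & (truth.channel == "5p")].iloc[0]
        large = [roi_mean(im, lf.x_um, lf.y_um, 2.0, quarter_geom)
                 for im in ser.images]
        small = [roi_mean(im, sf.x_um, sf.y_um, 1.0, quarter_geom)
                 for im in ser.images]
        bg = [float(im[:30, :30].mean()) for im in ser.images]
        # bright transcription-site pixels clip, attenuating the
        # large-focus ROI above the lowest exposures; small foci and
        # background stay linear across the full ladder
        assert large[-1] < 0.8 * 8 * large[0]
        assert check_linearity(
            ExposureSeries("l", "large_focus", exposures, large)) is False
        assert check_linearity(
            ExposureSeries("s", "small_focus", exposures, small)) is True
        np.testing.assert_allclose(bg, np.array(bg[:1]) * [1, 2, 4, 6, 8],
                                   rtol=1e-6)

    def test_exposures_validated(self, quarter_geom):
        cfg = clean_scene(quarter_geom)
        with pytest.raises(ValueError):
            generate_exposure_series(cfg, [])
        with pytest.raises(ValueError):
            generate_exposure_series(cfg, [100, 100])

    def test_same_scene_as_generate_field(self, quarter_geom):
        cfg = clean_scene(quarter_geom, seed=13)
        ser = generate_exposure_series(cfg, [100, 200])
        sim = generate_field(cfg)
        pd.testing.assert_frame_equal(ser.truth, sim.truth)


class TestSteadyStateCounts:
    def ratio(self, table):
        c5 = table.loc[table.region == "5p", "counts"].to_numpy()
        c3 = table.loc[table.region == "3p", "counts"].to_numpy()
        return float(c5.sum() / c3.sum())

    def test_no_decay_limit_ratio_approaches_one(self):
        tab = generate_steady_state_counts(GENE_11H, lifetime_h=1e7,
                                           initiation_interval_min=22,
                                           n_nuclei=80, noise_cv=0, seed=0)
        assert self.ratio(tab) == pytest.approx(1.0, abs=1e-5)

    def test_transcription_time_equal_lifetime_gives_ratio_two(self):
        tab = generate_steady_state_counts(GENE_11H, lifetime_h=11.0,
                                           initiation_interval_min=22,
                                           n_nuclei=80, noise_cv=0, seed=0)
        assert self.ratio(tab) == pytest.approx(2.0)

    def test_reference_configuration_gives_ratio_3_2(self):
        # lifetime 5 h against an 11 h inter-probe transcription time
        tab = generate_steady_state_counts(GENE_11H, lifetime_h=5.0,
                                           initiation_interval_min=22,
                                           n_nuclei=80, noise_cv=0, seed=0)
        assert self.ratio(tab) == pytest.approx(3.2)

    def test_counts_non_increasing_from_5p_to_3p(self):
        gene = GeneModel(regions={"5p": (190_000, 715_000),
                                  "mid": (1_240_000, 1_250_000),
                                  "3p": (2_177_000, 2_265_000)})
        tab = generate_steady_state_counts(gene, lifetime_h=5.0,
                                           initiation_interval_min=22,
                                           n_nuclei=80, noise_cv=0, seed=0)
        by_region = tab.set_index("region").counts
        assert by_region["5p"] >= by_region["mid"] >= by_region["3p"]

    def test_sampled_ratio_matches_closed_form_within_2pct(self):
        # >= 1e4 simulated transcripts per region via Poisson sampling
        tab = generate_steady_state_counts(GENE_11H, lifetime_h=5.0,
                                           initiation_interval_min=22,
                                           n_nuclei=2000, noise_cv=0,
                                           seed=1, sampled=True)
        assert self.ratio(tab) == pytest.approx(3.2, rel=0.02)
        assert tab.loc[tab.region == "3p", "counts"].iloc[0] >= 1e4

    def test_noise_cv_is_respected(self):
        tab = generate_steady_state_counts(GENE_11H, lifetime_h=5.0,
                                           initiation_interval_min=22,
                                           n_nuclei=80, noise_cv=0.1,
                                           seed=2, n_replicates=200)
        c5 = tab.loc[tab.region == "5p", "counts"]
        assert c5.std() / c5.mean() == pytest.approx(0.1, rel=0.25)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_steady_state_counts(GENE_11H, lifetime_h=0,
                                         initiation_interval_min=22,
                                         n_nuclei=80, noise_cv=0, seed=0)
        with pytest.raises(ValueError):
            generate_steady_state_counts(GENE_11H, lifetime_h=5,
                                         initiation_interval_min=0,
                                         n_nuclei=80, noise_cv=0, seed=0)


class TestPresets:
    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            example_scene("cat")

    def test_counts_scale_with_field_area(self, quarter_geom):
        full = example_scene("wt")
        quarter = example_scene("wt", geometry=quarter_geom)
        ratio = quarter_geom.area_um2 / full.geometry.area_um2
        assert quarter.n_pairs == pytest.approx(full.n_pairs * ratio)
        assert quarter.n_nuclei == pytest.approx(full.n_nuclei * ratio)
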