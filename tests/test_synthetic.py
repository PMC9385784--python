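"""Generator fidelity: determinism, noise statistics, coupling, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dapicyto.synthetic import (
    ComponentSpec,
    PlacementError,
    SyntheticSceneSpec,
    ValidationError,
    background_model,
    gen_intensity_table,
    render_scene,
    stage_presets,
    suggest_shape,
)
from conftest import make_scene_spec


class TestComponentValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mean_pg": 0.0},
            {"mean_pg": -1.0},
            {"cv": -0.1},
            {"n": -5},
            {"weight": 1.5},
        ],
    )
    def test_invalid_component_rejected(self, kwargs):
        base = {"label": "x", "mean_pg": 1.0, "cv": 0.1, "n": 10}
        with pytest.raises(ValidationError):
            ComponentSpec(**{**base, **kwargs})


class TestIntensityTable:
    def test_zero_cv_intensities_exact(self):
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("z", 0.76, 0.0, 5)],
            n_standard=0,
            gain=1000.0,
            seed=0,
        )
        table = gen_intensity_table(spec)
        assert len(table) == 5
        assert np.all(table["intensity"].to_numpy() == 760.0)
        assert np.all(table["true_pg"].to_numpy() == 0.76)

    def test_sample_mean_close_to_component_mean(self):
        # released-zoospore dispersion: mean recovered within sampling error
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("z", 0.76, 0.07 / 0.76, 387)],
            n_standard=0,
            seed=1,
        )
        table = gen_intensity_table(spec)
        se = 0.07 / np.sqrt(387)
        assert abs(table["true_pg"].mean() - 0.76) <= 2 * se

    @pytest.mark.parametrize("mean,cv,n", [(0.76, 0.09, 500), (2.4, 0.17, 300)])
    def test_statistical_fidelity_three_se(self, mean, cv, n):
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("c", mean, cv, n)], n_standard=0, seed=7
        )
        t = gen_intensity_table(spec)
        se = mean * cv / np.sqrt(n)
        assert abs(t["true_pg"].mean() - mean) <= 3 * se

    def test_standard_rows_constant_truth(self):
        spec = SyntheticSceneSpec(components=[], n_standard=25, seed=2)
        t = gen_intensity_table(spec)
        std = t[t["is_standard"]]
        assert len(std) == 25
        assert np.all(std["true_pg"] == 2.4)
        # intensity noise bounded by the standard cv
        cv = std["intensity"].std() / std["intensity"].mean()
        assert cv < 0.05

    def test_determinism_bit_identical(self):
        spec = lambda: SyntheticSceneSpec(  # noqa: E731
            components=[ComponentSpec("z", 0.76, 0.09, 50)], n_standard=5, seed=9
        )
        a, b = gen_intensity_table(spec()), gen_intensity_table(spec())
        pd.testing.assert_frame_equal(a, b)

    def test_coupled_area_tracks_dna(self):
        # two coupled components spanning 4x in pg
        spec = SyntheticSceneSpec(
            components=[
                ComponentSpec("lo", 0.76, 0.09, 200),
                ComponentSpec("hi", 3.04, 0.09, 200),
            ],
            n_standard=0,
            seed=3,
        )
        t = gen_intensity_table(spec)
        rho = stats.spearmanr(t["area"], t["true_pg"]).statistic
        assert rho >= 0.9

    def test_decoupled_area_ignores_dna(self):
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("male_gp", 2.01, 0.11, 400)],
            decoupled_labels=("male_gp",),
            n_standard=0,
            seed=3,
        )
        t = gen_intensity_table(spec)
        rho = stats.spearmanr(t["area"], t["true_pg"]).statistic
        assert abs(rho) <= 0.2

    def test_decoupled_group_small_but_dna_rich(self):
        # male-gametophyte-style anomaly: same nucleus size, ~2.6x the DNA
        spec = SyntheticSceneSpec(
            components=[
                ComponentSpec("zoospore", 0.76, 0.09, 300),
                ComponentSpec("male_gp", 2.01, 0.11, 300),
            ],
            decoupled_labels=("male_gp",),
            n_standard=0,
            seed=4,
        )
        t = gen_intensity_table(spec)
        g = t.groupby("label")[["area", "true_pg"]].mean()
        area_ratio = g.loc["male_gp", "area"] / g.loc["zoospore", "area"]
        pg_ratio = g.loc["male_gp", "true_pg"] / g.loc["zoospore", "true_pg"]
        assert abs(area_ratio - 1) < 0.10
        assert 2.4 < pg_ratio < 2.9


class TestRenderScene:
    def test_empty_scene_is_background(self):
        spec = SyntheticSceneSpec(
            components=[], n_standard=0, image_shape=(64, 64), noise_sd=0.0, seed=0
        )
        image, gt = render_scene(spec)
        assert np.allclose(image, background_model(spec))
        assert len(gt.table) == 0
        assert gt.mask.max() == 0

    def test_integrated_signal_conserved(self):
        spec = make_scene_spec(
            [ComponentSpec("z", 0.76, 0.09, 10)], n_standard=0, seed=6, noise_sd=0.0
        )
        image, gt = render_scene(spec)
        sub = image - background_model(spec)
        for _, row in gt.table.iterrows():
            got = sub[gt.mask == row["id"]].sum()
            assert got == pytest.approx(row["intensity"], rel=0.01)
        # whole-scene conservation
        assert sub.sum() == pytest.approx(gt.table["intensity"].sum(), rel=0.01)

    def test_masks_non_overlapping_and_complete(self, small_scene):
        _, _, gt = small_scene
        ids = set(gt.table["id"])
        present = set(np.unique(gt.mask)) - {0}
        assert present == ids

    def test_seed_changes_placement_not_statistics(self):
        mk = lambda s: make_scene_spec(  # noqa: E731
            [ComponentSpec("z", 0.76, 0.09, 40)], n_standard=0, seed=s
        )
        img1, gt1 = render_scene(mk(1))
        img2, gt2 = render_scene(mk(2))
        assert not np.array_equal(img1, img2)
        m1, m2 = gt1.table["true_pg"].mean(), gt2.table["true_pg"].mean()
        se = 0.76 * 0.09 / np.sqrt(40)
        assert abs(m1 - m2) < 6 * se

    def test_render_determinism(self):
        mk = lambda: make_scene_spec(  # noqa: E731
            [ComponentSpec("z", 0.76, 0.09, 15)], n_standard=3, seed=8
        )
        img1, gt1 = render_scene(mk())
        img2, gt2 = render_scene(mk())
        assert np.array_equal(img1, img2)
        assert np.array_equal(gt1.mask, gt2.mask)

    def test_placement_failure_is_informative(self):
        spec = SyntheticSceneSpec(
            components=[ComponentSpec("z", 2.4, 0.0, 40)],
            n_standard=0,
            image_shape=(120, 120),
            seed=0,
        )
        with pytest.raises(PlacementError, match="larger image|too small"):
            render_scene(spec)

    def test_standard_mask_marks_standards_only(self, small_scene):
        _, _, gt = small_scene
        std_ids = set(gt.table.loc[gt.table["is_standard"], "id"])
        assert set(np.unique(gt.mask[gt.standard_mask])) - {0} == std_ids


class TestPresets:
    def test_published_stage_means(self, presets):
        assert presets["zoospores_released"].mean_pg == 0.76
        assert presets["zoospores_unreleased"].mean_pg == 0.79
        assert presets["male_gametophytes"].mean_pg == 2.01
        assert presets["female_gametophytes"].mean_pg == 2.27
        assert presets["sporophytes_embryonic"].mean_pg == 1.64
        assert presets["meristoderm"].mean_pg == 1.51
        assert presets["cortex_medulla"].mean_pg == 2.40

    def test_nucleus_counts_preserved(self, presets):
        for name, p in presets.items():
            assert sum(c.n for c in p.components) == p.n_total, name

    def test_cortex_has_higher_ploidy_components(self, presets):
        comps = presets["cortex_medulla"].components
        multiples = sorted(c.mean_pg / 2.40 for c in comps)
        assert multiples == pytest.approx([1, 2, 4, 8])

    def test_flagged_stages_gain_minor_components(self, presets):
        assert len(presets["zoospores_released"].components) == 2
        assert len(presets["meristoderm"].components) == 1
        female = presets["female_gametophytes"]
        fracs = {round(c.mean_pg / 2.27): c.weight for c in female.components[1:]}
        assert fracs == {2: 0.10, 4: 0.02}

    def test_male_preset_is_decoupled(self, presets):
        assert presets["male_gametophytes"].decoupled
        assert not presets["zoospores_released"].decoupled


def test_spec_json_roundtrip():
    spec = make_scene_spec([ComponentSpec("z", 0.76, 0.09, 12)], n_standard=4, seed=11)
    clone = SyntheticSceneSpec.from_json(spec.to_json())
    assert clone == spec
    pd.testing.assert_frame_equal(gen_intensity_table(clone), gen_intensity_table(spec))


def test_suggest_shape_scales_with_content():
    small = SyntheticSceneSpec(components=[ComponentSpec("z", 0.76, 0.1, 10)], n_standard=0)
    big = SyntheticSceneSpec(components=[ComponentSpec("z", 0.76, 0.1, 400)], n_standard=0)
    assert suggest_shape(big)[0] > suggest_shape(small)[0]
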