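"""Synthetic candled-egg generator: determinism, class signal, bookkeeping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from sklearn.linear_model import LogisticRegression

from ovosex.synthetic import (PAPER_COMPOSITION, DatasetComposition,
                              GeneratorParams, consensus_label, degrade,
                              feather_sex_label, generate_arrays,
                              generate_dataset, render_egg, split_dataset)

PARAMS_128 = GeneratorParams(image_size=128)


class TestRendering:
    def test_same_seed_bit_identical(self):
        a = render_egg(PARAMS_128, 5)
        b = render_egg(PARAMS_128, 5)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert a.label == b.label

    def test_vessels_lie_inside_the_egg(self):
        for seed in range(10):
            s = render_egg(PARAMS_128, seed)
            dilated_egg = ndi.binary_dilation(s.image > 40, iterations=2)
            assert not (s.vessel_mask & ~dilated_egg).any()

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            render_egg(GeneratorParams(image_size=20), 0)

    def test_label_fixed_by_argument(self):
        assert render_egg(PARAMS_128, 3, label="M").label == "M"


class TestClassSignal:
    def test_null_effect_gives_chance_level_vessel_count_classifier(self):
        params = dataclasses.replace(PARAMS_128, class_effect=0.0)
        samples = generate_arrays(200, params, seed=11)
        counts = np.array([[s.vessel_mask.sum()] for s in samples], float)
        y = np.array([s.label == "F" for s in samples])
        clf = LogisticRegression().fit(counts[:200], y[:200])
        acc = clf.score(counts[200:], y[200:])
        # binomial noise around 0.5 at n=200: 3 sigma ~ 0.106
        assert abs(acc - 0.5) <= 0.12

    def test_accuracy_increases_with_effect_knob(self):
        accs = []
        for effect in (0.0, 0.5, 1.0):
            params = dataclasses.replace(PARAMS_128, class_effect=effect)
            samples = generate_arrays(100, params, seed=21)
            counts = np.array([[s.vessel_mask.sum()] for s in samples], float)
            y = np.array([s.label == "F" for s in samples])
            clf = LogisticRegression().fit(counts[:100], y[:100])
            accs.append(clf.score(counts[100:], y[100:]))
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02
        assert accs[2] >= accs[0] + 0.15


class TestDegradation:
    def test_normal_stratum_is_identity(self):
        s = render_egg(PARAMS_128, 8)
        d = degrade(s, "normal", 1)
        assert np.array_equal(d.image, s.image) and d.quality == "normal"

    def test_blur_reduces_high_frequency_energy(self):
        s = render_egg(PARAMS_128, 9)
        d = degrade(s, "blurry", 2)
        lap = lambda im: np.abs(ndi.laplace(im.astype(float))).mean()
        assert lap(d.image) < lap(s.image)
        assert np.array_equal(d.vessel_mask, s.vessel_mask)

    def test_bubble_overwrites_a_bright_disc(self):
        s = render_egg(PARAMS_128, 10)
        d = degrade(s, "bubble", 3)
        changed = d.image != s.image
        assert changed.sum() >= np.pi * (0.03 * 128) ** 2 * 0.8
        assert d.image[changed].min() >= 200    # bubbles are bright

    def test_exposure_shift_changes_mean(self):
        s = render_egg(PARAMS_128, 11)
        d = degrade(s, "low-or-over-exposed", 4)
        assert abs(d.image.mean() - s.image.mean()) > 5

    def test_unknown_stratum_rejected(self):
        s = render_egg(PARAMS_128, 12)
        with pytest.raises(ValueError, match="unknown quality stratum"):
            degrade(s, "hazy", 0)


class TestLabelRules:
    @pytest.mark.parametrize("wing,covert,expected", [
        (10.5, 8.0, "F"),      # difference 2.5 -> fast-feathering female
        (7.0, 5.0, "M"),       # exactly 2.00: strict inequality -> male
        (5.0, 5.0, "M"),
        (9.1, 6.0, "F"),
    ])
    def test_feathering_rule(self, wing, covert, expected):
        assert feather_sex_label(wing, covert) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            feather_sex_label(-1.0, 2.0)

    @pytest.mark.parametrize("a,b,expected", [
        ("F", "F", "F"), ("M", "M", "M"), ("F", "M", "excluded"),
        ("M", "F", "excluded")])
    def test_consensus(self, a, b, expected):
        assert consensus_label(a, b) == expected


@pytest.fixture(scope="module")
def paper_manifest():
    return generate_dataset(GeneratorParams(), PAPER_COMPOSITION,
                            seed=0, manifest_only=True)


class TestManifest:
    def test_hatchery_scale_arithmetic(self, paper_manifest):
        m = paper_manifest
        assert len(m) == 4011
        assert (~m["hatched"]).sum() == 160
        hatched = m[m["hatched"]]
        assert len(hatched) == 4011 - 160
        assert (hatched["label"] == "F").sum() == 1889
        assert (hatched["label"] == "M").sum() == 1962

    def test_split_sizes_and_exclusion(self, paper_manifest):
        m = paper_manifest
        assert (m["split"] == "test").sum() == 770
        assert (m["split"] == "train").sum() == 3081
        assert (m.loc[~m["hatched"], "split"] == "excluded").all()

    def test_class_balance_close_to_parity(self, paper_manifest):
        hatched = paper_manifest[paper_manifest["hatched"]]
        ratio = (hatched["label"] == "F").mean()
        assert abs(ratio - 0.5) <= 0.02

    def test_test_strata_counts_match_preset(self, paper_manifest):
        test = paper_manifest[paper_manifest["split"] == "test"]
        counts = test["quality"].value_counts()
        assert counts["normal"] == 420
        assert counts["low-or-over-exposed"] == 120
        assert counts["bubble"] == 130
        assert counts["blurry"] == 100

    def test_tiny_composition(self):
        comp = DatasetComposition(females=2, males=2, unhatched=0,
                                  test_fraction=0.25)
        m = generate_dataset(GeneratorParams(), comp, seed=1, manifest_only=True)
        assert len(m) == 4
        assert (m["label"] == "F").sum() == 2

    def test_inconsistent_strata_sum_rejected(self):
        comp = DatasetComposition(females=10, males=10, unhatched=0,
                                  test_fraction=0.5, test_strata=(5, 5, 5, 5))
        with pytest.raises(ValueError, match="strata sum"):
            comp.validate()

    def test_split_determinism_and_seed_sensitivity(self):
        m = pd.DataFrame({"hatched": [True] * 10, "label": ["F"] * 10})
        s1 = split_dataset(m, 0.2, seed=3)
        s2 = split_dataset(m, 0.2, seed=3)
        s3 = split_dataset(m, 0.2, seed=4)
        assert (s1["split"] == s2["split"]).all()
        assert (s1["split"] == "test").sum() == 2
        assert (s3["split"] == "test").sum() == 2
        assert not (s1["split"] == s3["split"]).all()

    def test_bad_fraction_rejected(self):
        m = pd.DataFrame({"hatched": [True] * 4})
        with pytest.raises(ValueError, match="test_fraction"):
            split_dataset(m, 1.5, seed=0)

    def test_rendered_dataset_writes_images_and_masks(self, tmp_path):
        comp = DatasetComposition(females=3, males=3, unhatched=1,
                                  test_fraction=0.2)
        m = generate_dataset(GeneratorParams(image_size=96), comp, seed=2,
                             out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert len(list((tmp_path / "images").glob("*.png"))) == 7
        assert len(list((tmp_path / "masks").glob("*.png"))) == 7
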