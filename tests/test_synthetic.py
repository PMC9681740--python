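"""Synthetic generator: determinism, contracts, and exact Bayes references."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from woundmm.bodymap import BACKGROUND_CODE
from woundmm.pipeline import WoundClass as W, read_manifest
from woundmm.synthetic import (
    SynthConfig,
    bayes_reference,
    generate_arrays,
    generate_bodymap_fixture,
    generate_dataset,
)


class TestGenerateDataset:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SynthConfig(classes=(W.D, W.P, W.S, W.V), n_per_class=10, image_size=16, seed=9)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        img = "images/roi_00003.png"
        assert (tmp_path / "a" / img).read_bytes() == (tmp_path / "b" / img).read_bytes()

    def test_class_balance_and_bg_location(self, tmp_path):
        cfg = SynthConfig(n_per_class=5, image_size=16, seed=0)  # default 6-class roster
        manifest, registry = generate_dataset(cfg, tmp_path)
        assert len(manifest) == 30
        per_class = {c: 0 for c in cfg.classes}
        for rec in manifest.records:
            per_class[rec.wound_class] += 1
            if rec.wound_class == W.BG:
                assert rec.location == BACKGROUND_CODE
            else:
                assert rec.location in registry
        assert set(per_class.values()) == {5}

    def test_generated_manifest_passes_read_validation(self, tmp_path):
        cfg = SynthConfig(n_per_class=4, image_size=16, seed=1)
        _, registry = generate_dataset(cfg, tmp_path)
        back = read_manifest(tmp_path / "manifest.csv", registry=registry, check_images=True)
        assert len(back) == 24

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="empty class"):
            SynthConfig(classes=())
        with pytest.raises(ValueError, match="n_per_class"):
            SynthConfig(n_per_class=0)
        with pytest.raises(ValueError, match="signal strengths"):
            SynthConfig(s_img=1.5)


class TestBayesReference:
    def test_no_location_signal_means_chance(self):
        cfg = SynthConfig(classes=(W.D, W.P, W.S, W.V), s_loc=0.0, location_overlap=0.0)
        assert bayes_reference(cfg).location_accuracy == pytest.approx(0.25)

    def test_full_signal_disjoint_supports_is_perfect(self):
        cfg = SynthConfig(classes=(W.D, W.P, W.S, W.V), s_loc=1.0, location_overlap=0.0)
        assert bayes_reference(cfg).location_accuracy == pytest.approx(1.0)

    def test_half_mixture_two_classes_two_codes_gives_three_quarters(self):
        cfg = SynthConfig(
            classes=(W.D, W.P),
            s_loc=0.5,
            location_dists={W.D: {101: 1.0}, W.P: {102: 1.0}},
        )
        assert bayes_reference(cfg).location_accuracy == pytest.approx(0.75)

    def test_image_accuracy_follows_mixture_formula(self):
        for s in (0.0, 0.5, 1.0):
            cfg = SynthConfig(classes=(W.D, W.P, W.S, W.V), s_img=s)
            expected = s + (1 - s) / 4
            assert bayes_reference(cfg).image_accuracy == pytest.approx(expected)

    def test_bayes_monotone_in_signal_strength(self):
        locs = [
            bayes_reference(
                SynthConfig(classes=(W.D, W.P, W.S, W.V), s_loc=s, location_overlap=0.0)
            ).location_accuracy
            for s in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert locs == sorted(locs)

    def test_joint_ceiling_dominates_each_modality(self):
        cfg = SynthConfig(
            classes=(W.D, W.P, W.S, W.V), s_img=2 / 3, s_loc=0.98, location_overlap=0.5
        )
        ref = bayes_reference(cfg)
        assert ref.joint_accuracy >= max(ref.image_accuracy, ref.location_accuracy)
        # graded boundary evidence creates genuine synergy, not just the max
        assert ref.joint_accuracy > max(ref.image_accuracy, ref.location_accuracy) + 0.05

    def test_location_sampler_matches_declared_distribution(self):
        cfg = SynthConfig(
            classes=(W.D, W.P, W.S, W.V), n_per_class=4000, image_size=8,
            s_loc=0.7, seed=3,
        )
        data = generate_arrays(cfg)
        mixed = cfg.mixed_location_dists()
        labels = np.array([cfg.classes.index(c) for c in data["classes"]])
        d_codes = data["location_codes"][labels == 0]
        dist = mixed[W.D]
        for code, p in dist.items():
            emp = np.mean(d_codes == code)
            assert emp == pytest.approx(p, abs=0.03)


class TestEmpiricalMonotonicity:
    def test_location_classifier_accuracy_nondecreasing_in_s_loc(self):
        """A trained location-only classifier tracks the rising Bayes ceiling."""
        means = []
        for s_loc in (0.0, 0.5, 1.0):
            accs = []
            for seed in (0, 1, 2):
                cfg = SynthConfig(
                    classes=(W.D, W.P, W.S, W.V), n_per_class=120, image_size=8,
                    s_loc=s_loc, location_overlap=0.0, seed=seed,
                )
                data = generate_arrays(cfg)
                x, y = data["locations"], data["labels"]
                clf = LogisticRegression(max_iter=200).fit(x[:360], y[:360])
                accs.append(clf.score(x[360:], y[360:]))
            means.append(np.mean(accs))
        assert means[1] >= means[0] - 0.05
        assert means[2] >= means[1] - 0.05

    def test_perfect_location_signal_is_perfectly_classifiable(self):
        cfg = SynthConfig(
            classes=(W.D, W.P, W.S, W.V), n_per_class=50, image_size=8,
            s_loc=1.0, location_overlap=0.0, seed=0,
        )
        data = generate_arrays(cfg)
        # enumerated Bayes rule: each code maps to its owning class
        mixed = cfg.mixed_location_dists()
        support = sorted({c for d in mixed.values() for c in d})
        rule = {
            code: int(np.argmax([mixed[cls].get(code, 0) for cls in cfg.classes]))
            for code in support
        }
        order = {cls: i for i, cls in enumerate(cfg.classes)}
        pred = np.array([rule[c] for c in data["location_codes"]])
        truth = np.array([order[c] for c in data["classes"]])
        assert np.mean(pred == truth) == 1.0


class TestBodymapFixture:
    def test_paper_scale_fixture_matches_counts(self, tmp_path):
        from woundmm.bodymap import apply_merge, load_merge_map, load_registry

        sizes = [3, 4] + [2] * 156  # removes 2 + 3 + 156 = 161
        registry, merge = generate_bodymap_fixture(484, sizes, seed=0, out_dir=tmp_path)
        assert len(registry) == 484
        simplified = apply_merge(registry, merge)
        assert len(simplified) == 323
        # files round-trip through the loaders
        reg2 = load_registry(tmp_path / "bodymap.csv")
        merge2 = load_merge_map(tmp_path / "bodymap_merge.csv", reg2)
        assert len(apply_merge(reg2, merge2)) == 323

    def test_small_fixture_with_explicit_groups(self):
        registry, merge = generate_bodymap_fixture(10, [[1, 2, 3], [5, 6]])
        from woundmm.bodymap import apply_merge

        assert len(apply_merge(registry, merge)) == 7
        assert merge.canonical(3) == 1 and merge.canonical(6) == 5

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_bodymap_fixture(10, [[1, 2], [2, 3]])
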