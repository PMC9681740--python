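"""Experiment runner, cross-validation, external validation, report tables."""

import numpy as np
import pytest

from woundmm.pipeline import WoundClass as W
from woundmm.synthetic import SynthConfig, generate_dataset
from woundmm.train_eval import (
    CVReport,
    ExperimentResult,
    ExperimentSpec,
    MetricsReport,
    TrainingConfig,
    cross_validate,
    external_validate,
    run_experiment,
    write_cv_report,
    write_report,
)


@pytest.fixture(scope="module")
def location_only_dataset(tmp_path_factory):
    """Synthetic set where only the location carries class signal."""
    out = tmp_path_factory.mktemp("loc_only")
    cfg = SynthConfig(
        classes=(W.D, W.P), n_per_class=40, image_size=24,
        s_img=0.0, s_loc=1.0, location_overlap=0.0, seed=2,
    )
    manifest, registry = generate_dataset(cfg, out)
    return manifest, registry


class TestExperimentSpec:
    def test_binary_positive_class_defaults_to_second_listed(self):
        spec = ExperimentSpec(classes=("D", "P"), modality="location")
        assert spec.positive_class == W.P
        assert spec.name == "D-P"

    def test_model_names_follow_the_combo_convention(self):
        assert ExperimentSpec(classes=("D", "P"), modality="image", backbone="vgg16").model_name == "VGG16"
        assert (
            ExperimentSpec(classes=("D", "P"), modality="multimodal",
                           backbone="vgg19", wlc_kind="lstm").model_name
            == "VGG19 + LSTM"
        )

    def test_single_class_experiment_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            ExperimentSpec(classes=("D",), modality="image")


class TestRunExperiment:
    def test_location_signal_only_separates_modalities(self, location_only_dataset):
        """Location modality learns; image modality stays near chance."""
        manifest, registry = location_only_dataset
        tc = TrainingConfig(epochs=12, seed=0)
        loc = run_experiment(
            ExperimentSpec(classes=("D", "P"), modality="location"),
            manifest, registry, training=tc,
        )
        img = run_experiment(
            ExperimentSpec(classes=("D", "P"), modality="image"),
            manifest, registry, training=tc,
        )
        assert loc.metrics.accuracy >= 0.9
        assert abs(img.metrics.accuracy - 0.5) <= 0.25
        assert loc.metrics.n_eval == 20  # 25% of 80 originals
        assert loc.metrics.f1 is not None  # binary experiment reports P/R/F1

    def test_alignment_ablation_destroys_location_information(self, location_only_dataset):
        manifest, registry = location_only_dataset
        tc = TrainingConfig(epochs=12, seed=0)
        intact = run_experiment(
            ExperimentSpec(classes=("D", "P"), modality="multimodal"),
            manifest, registry, training=tc,
        )
        broken = run_experiment(
            ExperimentSpec(classes=("D", "P"), modality="multimodal"),
            manifest, registry, training=tc, permute_locations=True,
        )
        assert intact.metrics.accuracy >= 0.9
        assert broken.metrics.accuracy <= intact.metrics.accuracy - 0.2


class TestCrossValidate:
    def test_folds_partition_and_stratify(self, location_only_dataset):
        manifest, registry = location_only_dataset
        report = cross_validate(
            ExperimentSpec(classes=("D", "P"), modality="location"),
            manifest, registry, k=5, seed=0,
            training=TrainingConfig(epochs=4, seed=0), augment=False,
        )
        assert report.k == 5
        all_test = [i for plan in report.fold_plans for i in plan]
        originals = {r.index for r in manifest.originals()}
        assert sorted(all_test) == sorted(originals)  # partition, disjoint
        for plan in report.fold_plans:
            assert len(plan) == 16  # 80 originals / 5 folds, stratified 8+8
        assert report.average == pytest.approx(np.mean(report.fold_accuracies), abs=1e-12)

    def test_class_too_small_for_k_rejected(self, location_only_dataset):
        manifest, registry = location_only_dataset
        with pytest.raises(ValueError, match="fewer than k"):
            cross_validate(
                ExperimentSpec(classes=("D", "P"), modality="location"),
                manifest, registry, k=100,
            )


class TestExternalValidate:
    def test_common_class_restriction(self, location_only_dataset, tmp_path):
        manifest, registry = location_only_dataset
        tc = TrainingConfig(epochs=10, seed=0)
        spec = ExperimentSpec(classes=("D", "P"), modality="location")
        # train on dataset A via the pipeline, then validate on dataset B
        from woundmm.estimators import WoundLocationClassifier
        from woundmm.pipeline import pair_modalities, subset_classes

        sub, label_map = subset_classes(manifest, {W.D, W.P})
        paired = pair_modalities(sub, registry)
        est = WoundLocationClassifier(epochs=10, seed=0).fit(paired.locations, paired.labels)

        cfg_b = SynthConfig(
            classes=(W.D, W.P, W.AV), n_per_class=15, image_size=24,
            s_img=0.0, s_loc=1.0, location_overlap=0.0, seed=5,
        )
        manifest_b, _ = generate_dataset(cfg_b, tmp_path / "b")
        report = external_validate(est, label_map, manifest_b, registry)
        assert report.n_eval == 30  # D and P only; A+V is not common
        assert report.accuracy >= 0.9  # same location layout on both sides

    def test_disjoint_class_sets_rejected(self, location_only_dataset, tmp_path):
        manifest, registry = location_only_dataset
        from woundmm.estimators import WoundLocationClassifier

        est = WoundLocationClassifier(epochs=1)
        cfg_b = SynthConfig(classes=(W.S, W.AV), n_per_class=4, image_size=16, seed=0)
        manifest_b, _ = generate_dataset(cfg_b, tmp_path / "c")
        with pytest.raises(ValueError, match="no common classes"):
            external_validate(est, {W.D: 0, W.P: 1}, manifest_b, registry)


class TestReports:
    def fake_result(self, experiment, model, acc):
        report = MetricsReport.from_predictions(
            [0] * int(acc * 100) + [1] * (100 - int(acc * 100)),
            [0] * 100,
            labels=[0, 1],
        )
        return ExperimentResult(experiment, model, report)

    def test_grid_table_flags_single_best_per_experiment(self, tmp_path):
        results = [
            self.fake_result("D-P-S-V", "VGG16 + MLP", 0.81),
            self.fake_result("D-P-S-V", "VGG19 + MLP", 0.78),
            self.fake_result("D-P-S-V", "MLP", 0.74),
        ]
        paths = write_report(results, tmp_path)
        md = paths["markdown"].read_text()
        assert md.count("**") == 2  # one bolded best cell
        import pandas as pd

        table = pd.read_csv(paths["csv"], index_col=0)
        assert table.loc["VGG16 + MLP", "D-P-S-V"] == pytest.approx(81.0)

    def test_cv_table_has_fold_columns_and_average(self, tmp_path):
        report = CVReport((0.7, 0.72, 0.68, 0.75, 0.7), ((0,), (1,), (2,), (3,), (4,)))
        paths = write_cv_report([("D-P", "VGG19 + LSTM", report)], tmp_path)
        header = paths["csv"].read_text().splitlines()[0]
        assert header == "experiment,model,Fold1,Fold2,Fold3,Fold4,Fold5,Average"

    def test_empty_reports_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no experiment results"):
            write_report([], tmp_path)
        with pytest.raises(ValueError, match="no cross-validation"):
            write_cv_report([], tmp_path)
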