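"""Classifier benchmark with subject-grouped cross-validation.

Runs the selection + classification tail of the pipeline on a small
ground-truth cohort: MRMR top-10 features, leave-one-subject-out folds
over the training mice, and validation on a held-out mouse, for a subset
of the 30-model registry.
"""
import numpy as np

from spectromics import CohortDesign, TumorTrajectory, load_default_registry
from spectromics.cohort import generate_scene
from spectromics.pipeline import Observation, benchmark_observations

design = CohortDesign(n_mice=5, days=(0, 1, 3, 7, 9), n_validation=1,
                      scene_shape=(32, 40))
observations = []
val = set(design.validation_mice)
for mouse in range(design.n_mice):
    for day in design.days:
        rng = np.random.default_rng(
            np.random.SeedSequence((23, mouse, int(day * 10))))
        maps, mask = generate_scene(mouse, day, design, TumorTrajectory(),
                                    rng)
        observations.append(Observation(
            subject=mouse, day=day,
            split="validation" if mouse in val else "train",
            maps=maps, mask=mask))

registry = load_default_registry().subset([
    "LogisticRegression", "RidgeClassifier", "RandomForestClassifier",
    "GradientBoostingClassifier", "LinearDiscriminantAnalysis",
    "KNeighborsClassifier", "DummyClassifier"])

table, sel, report, validation, cols = benchmark_observations(
    observations, registry=registry, seed=0)

print("cross-validated AUC (mean over 4 subject folds) and validation AUC:")
for _, row in report.summary.iterrows():
    v = validation.loc[validation.model == row["model"], "auc"].iloc[0]
    print(f"  {row['model']:<28s} CV {row['auc_mean']:.3f}   val {v:.3f}")
print(f"\nbest model by CV AUC: {report.best_model}")
print("The dummy baseline stays at chance (0.5) while real models "
      "separate tumors from healthy tissue; folds never mix subjects, so "
      "these numbers are free of within-animal leakage.")
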