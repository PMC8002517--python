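"""Per-step identification accuracy under the openness condition.

At every openness step the classifier is refit from scratch on the
feature-space rows of the currently enrolled subjects (repetitive batch
learning) and scored by stratified k-fold cross-validation; the step
accuracy is the mean of the fold accuracies.  Running all steps of all M
label sequences yields the M x R openness-accuracy matrix whose column
mean OAm summarises the system's accuracy trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .config import ClassifierSpec
from .features import FeatureSpace
from .openness import OpennessSimulation

__all__ = [
    "StepEvaluation",
    "OpennessAccuracy",
    "make_classifier",
    "subset_features",
    "evaluate_step",
    "run_openness",
]


@dataclass
class StepEvaluation:
    """Cross-validated identification accuracy at one openness step."""

    step: int
    labels: frozenset[int]
    n_classes: int
    fold_accuracies: np.ndarray
    accuracy: float


@dataclass
class OpennessAccuracy:
    """The M x R accuracy matrix and its column mean OAm."""

    per_sequence: np.ndarray  # shape (M, R)
    mean: np.ndarray  # shape (R,)

    def __post_init__(self) -> None:
        self.per_sequence = np.asarray(self.per_sequence, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)

    def to_frame(self, config_id: str = "") -> pd.DataFrame:
        """Tidy long-format table: one row per (sequence, step)."""
        m, r = self.per_sequence.shape
        seq, step = np.meshgrid(np.arange(1, m + 1), np.arange(1, r + 1), indexing="ij")
        return pd.DataFrame(
            {
                "config_id": config_id,
                "sequence": seq.ravel(),
                "step": step.ravel(),
                "accuracy": self.per_sequence.ravel(),
            }
        )


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the classifier behind a :class:`ClassifierSpec`."""
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.neighbors, metric="euclidean")
    if spec.kind == "naive_bayes":
        return GaussianNB()
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def subset_features(space: FeatureSpace, labels) -> FeatureSpace:
    """Rows of the feature space whose subject label is enrolled, order
    preserved."""
    label_set = set(int(l) for l in labels)
    if not label_set:
        raise ValueError("label set must be non-empty")
    known = set(int(l) for l in space.subjects)
    unknown = label_set - known
    if unknown:
        raise KeyError(f"label(s) not present in the feature space: {sorted(unknown)}")
    mask = np.isin(space.labels, sorted(label_set))
    return FeatureSpace(
        matrix=space.matrix[mask], labels=space.labels[mask], config_id=space.config_id
    )


def evaluate_step(
    space_j: FeatureSpace,
    clf_spec: ClassifierSpec,
    kfold: int,
    seed: int,
    step: int = 0,
) -> StepEvaluation:
    """Stratified k-fold cross-validation on one step's feature space.

    The classifier is refit on the training folds at every split (no state
    carried over) and the step accuracy is the mean fold accuracy, each
    fold accuracy being the fraction of correct predictions in its pooled
    confusion matrix.
    """
    labels, counts = np.unique(space_j.labels, return_counts=True)
    if counts.min() < kfold:
        thin = labels[counts < kfold]
        raise ValueError(
            f"class(es) {thin.tolist()} have fewer than kfold={kfold} feature vectors"
        )
    splitter = StratifiedKFold(n_splits=kfold, shuffle=True, random_state=seed)
    fold_acc = []
    for train_idx, test_idx in splitter.split(space_j.matrix, space_j.labels):
        clf = make_classifier(clf_spec, seed=seed)
        clf.fit(space_j.matrix[train_idx], space_j.labels[train_idx])
        predicted = clf.predict(space_j.matrix[test_idx])
        fold_acc.append(float(np.mean(predicted == space_j.labels[test_idx])))
    fold_acc = np.asarray(fold_acc)
    return StepEvaluation(
        step=step,
        labels=frozenset(int(l) for l in labels),
        n_classes=labels.size,
        fold_accuracies=fold_acc,
        accuracy=float(fold_acc.mean()),
    )


def run_openness(
    space: FeatureSpace,
    sim: OpennessSimulation,
    clf_spec: ClassifierSpec,
    kfold: int,
    seed: int,
) -> OpennessAccuracy:
    """Evaluate every step of every enrollment sequence.

    Fold partitions are redrawn independently at each (sequence, step)
    from sub-streams of ``seed``, so results are reproducible and adding
    sequences never perturbs earlier ones.
    """
    sim_labels = set()
    for seq in sim.labels.sequences:
        sim_labels |= set(seq[-1])
    known = set(int(l) for l in space.subjects)
    missing = sim_labels - known
    if missing:
        raise KeyError(
            f"simulation enrolls label(s) absent from the feature space: {sorted(missing)}"
        )

    m = sim.labels.n_sequences
    r = sim.sizes.n_steps
    seeds = np.random.SeedSequence(seed).generate_state(m * r) % (2**31)
    acc = np.zeros((m, r))
    for i, seq in enumerate(sim.labels.sequences):
        for j, step_labels in enumerate(seq):
            step_space = subset_features(space, step_labels)
            result = evaluate_step(
                step_space,
                clf_spec,
                kfold,
                seed=int(seeds[i * r + j]),
                step=j + 1,
            )
            acc[i, j] = result.accuracy
    return OpennessAccuracy(per_sequence=acc, mean=acc.mean(axis=0))


def write_results(
    oa: OpennessAccuracy, sim: OpennessSimulation, config_id: str, out_dir: str | Path
) -> Path:
    """Persist one configuration's openness accuracy as a tidy CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = oa.to_frame(config_id)
    frame["n_classes"] = np.tile(sim.sizes.sizes, oa.per_sequence.shape[0])
    path = out_dir / f"accuracy_{config_id}.csv"
    frame.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> tuple[str, OpennessAccuracy]:
    """Load a tidy accuracy CSV back into an :class:`OpennessAccuracy`."""
    frame = pd.read_csv(path)
    config_id = str(frame["config_id"].iloc[0])
    matrix = frame.pivot(index="sequence", columns="step", values="accuracy")
    per_sequence = matrix.sort_index().to_numpy(float)
    return config_id, OpennessAccuracy(
        per_sequence=per_sequence, mean=per_sequence.mean(axis=0)
    )
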