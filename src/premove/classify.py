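"""Cross-validated SVM evaluation and the component-pair search scheme.

Single-window stage: every unordered pair of retained components is
evaluated in every window (3 positions x 4 sizes) for each binary task
(left vs. right, top vs. bottom) with an 8-fold cross-validated linear SVM
-- 10,440 classifications for 30 retained components. Pairs/windows
exceeding 65% feed a second, two-window stage that fuses a window-B pair
with a window-F or window-M pair (four components total). A spatial variant
restricts the pair search to components sharing a scalp area, and a shuffle
control re-evaluates the best configuration on permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold

from .ica import ICADecomposition
from .windows import (
    FeatureMatrix,
    WindowSpec,
    all_window_specs,
    build_feature_matrix,
)

TASKS: tuple[str, ...] = ("LR", "TB")


@dataclass(frozen=True)
class ClassificationRecord:
    """One evaluated configuration and its pooled cross-validated accuracy."""

    task: str
    component_ids: tuple[int, ...]
    specs: tuple[WindowSpec, ...]
    accuracy: float            # percent: 100 - 100 * misclassified / n_trials
    folds: int
    cv_seed: int
    n_trials: int

    @property
    def position_key(self) -> str:
        """F/M/B for single windows; FB or MB for fused ones."""
        if len(self.specs) == 1:
            return self.specs[0].position
        other = [s.position for s in self.specs if s.position != "B"]
        return (other[0] if other else "B") + "B"

    @property
    def n_features(self) -> int:
        return sum(2 * int(round(s.size * 100)) for s in self.specs)

    def sort_key(self) -> tuple:
        """Best-first deterministic ordering: highest accuracy, then fewer
        features, then lexicographic component ids."""
        return (-self.accuracy, self.n_features, self.component_ids)


@dataclass
class SearchResult:
    records: list[ClassificationRecord] = field(default_factory=list)
    subject: str = "S1"
    condition: str = "visual"
    total_runs: int = 0

    def best(self) -> ClassificationRecord:
        if not self.records:
            raise ValueError("empty search result has no best record")
        return min(self.records, key=ClassificationRecord.sort_key)

    def top_accuracies(self, k: int = 3) -> list[float]:
        ordered = sorted(self.records, key=ClassificationRecord.sort_key)
        return [r.accuracy for r in ordered[:k]]


def _fold_error(X, y, train, test) -> int:
    # linear maximum-margin classifier, C fixed at 1.0; standardization is
    # fit on training rows only (leakage-free)
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=1.0).fit((X[train] - mu) / sd, y[train])
    return int(np.sum(clf.predict((X[test] - mu) / sd) != y[test]))


def crossval_accuracy(
    features: FeatureMatrix,
    folds: int = 8,
    cv_seed: int = 1,
    labels: np.ndarray | None = None,
) -> float:
    """Pooled stratified k-fold accuracy, in percent.

    Folds come from a Mersenne-Twister-seeded stratified shuffle; accuracy
    is 100 minus the percentage of misclassifications summed over every
    test fold. Deterministic given (features, folds, cv_seed). ``labels``
    overrides the feature labels (used by the shuffle control).
    """
    y = np.asarray(features.labels if labels is None else labels).astype(str)
    X = features.values
    if X.shape[0] < folds:
        raise ValueError(f"{X.shape[0]} trials is fewer than {folds} folds")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need two classes to classify")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} trials; "
            f"stratified {folds}-fold cross-validation needs >= {folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    n_wrong = sum(_fold_error(X, y, train, test) for train, test in skf.split(X, y))
    return 100.0 - 100.0 * n_wrong / X.shape[0]


def count_single_window_runs(
    n_components: int, n_windows: int = 12, n_tasks: int = 2
) -> int:
    """Size of the exhaustive single-window search grid."""
    return comb(n_components, 2) * n_windows * n_tasks


def enumerate_single_window_runs(
    component_ids: Sequence[int],
    windows: Sequence[WindowSpec] | None = None,
    tasks: Sequence[str] = TASKS,
) -> Iterator[tuple[str, tuple[int, int], WindowSpec]]:
    """Yield every (task, component pair, window) of the search grid without
    evaluating anything."""
    windows = list(windows) if windows is not None else all_window_specs()
    for task in tasks:
        for pair in combinations(sorted(component_ids), 2):
            for spec in windows:
                yield task, pair, spec


def single_window_search(
    decomp: ICADecomposition,
    task: str,
    windows: Sequence[WindowSpec] | None = None,
    cv_seed: int = 1,
    folds: int = 8,
    component_ids: Sequence[int] | None = None,
    subject: str = "S1",
) -> SearchResult:
    """Evaluate all component pairs in all windows for one task.

    Artifact-flagged components are excluded unless ``component_ids`` names
    an explicit set.
    """
    ids = list(component_ids) if component_ids is not None else decomp.usable_components()
    if len(ids) < 2:
        raise ValueError("need at least 2 usable components for a pair search")
    windows = list(windows) if windows is not None else all_window_specs()
    records = []
    for _, pair, spec in enumerate_single_window_runs(ids, windows, tasks=(task,)):
        feats = build_feature_matrix(decomp, list(pair), [spec], task)
        acc = crossval_accuracy(feats, folds=folds, cv_seed=cv_seed)
        records.append(
            ClassificationRecord(
                task=task,
                component_ids=pair,
                specs=(spec,),
                accuracy=acc,
                folds=folds,
                cv_seed=cv_seed,
                n_trials=feats.n_trials,
            )
        )
    return SearchResult(
        records=records,
        subject=subject,
        condition=decomp.condition,
        total_runs=len(records),
    )


def select_candidates(
    result: SearchResult, threshold: float = 65.0
) -> list[ClassificationRecord]:
    """Records strictly above the accuracy threshold (65% vs. 50% chance);
    selection is per (pair, window-size) -- sizes that fail are dropped even
    if the same pair passes at another size."""
    return [r for r in result.records if r.accuracy > threshold]


def fuse_two_windows(
    decomp: ICADecomposition,
    candidates_b: Iterable[ClassificationRecord],
    candidates_fm: Iterable[ClassificationRecord],
    task: str,
    cv_seed: int = 1,
    folds: int = 8,
    subject: str = "S1",
) -> SearchResult:
    """Two-window classifiers: every window-B candidate crossed with every
    window-F-or-M candidate (four components, two windows each).

    An empty candidate list yields an empty result, not an exception. The
    same pair may appear on both sides (four feature slices, two windows).
    """
    cands_b = [c for c in candidates_b if c.task == task]
    cands_fm = [c for c in candidates_fm if c.task == task]
    for c in cands_b:
        if c.specs[0].position != "B":
            raise ValueError("candidates_b must hold window-B records")
    for c in cands_fm:
        if c.specs[0].position not in ("F", "M"):
            raise ValueError("candidates_fm must hold window-F or window-M records")
    records = []
    for cb in cands_b:
        for cf in cands_fm:
            ids = list(cb.component_ids) + list(cf.component_ids)
            specs = [cb.specs[0], cf.specs[0]]
            feats = build_feature_matrix(decomp, ids, specs, task)
            acc = crossval_accuracy(feats, folds=folds, cv_seed=cv_seed)
            records.append(
                ClassificationRecord(
                    task=task,
                    component_ids=tuple(ids),
                    specs=tuple(specs),
                    accuracy=acc,
                    folds=folds,
                    cv_seed=cv_seed,
                    n_trials=feats.n_trials,
                )
            )
    return SearchResult(
        records=records,
        subject=subject,
        condition=decomp.condition,
        total_runs=len(records),
    )


def spatial_group_search(
    decomp: ICADecomposition,
    area: str,
    task: str,
    windows: Sequence[WindowSpec] | None = None,
    cv_seed: int = 1,
    folds: int = 8,
    subject: str = "S1",
) -> SearchResult:
    """Single-window pair search restricted to components whose scalp-map
    peak falls in one area; fewer than 2 such components gives an empty
    result."""
    if not decomp.area or all(a == "" for a in decomp.area):
        raise ValueError("components are not categorized; run categorize_components")
    ids = [i for i in decomp.usable_components() if decomp.area[i] == area]
    if len(ids) < 2:
        return SearchResult(
            records=[], subject=subject, condition=decomp.condition, total_runs=0
        )
    return single_window_search(
        decomp, task, windows=windows, cv_seed=cv_seed, folds=folds,
        component_ids=ids, subject=subject,
    )


def shuffle_control(
    decomp: ICADecomposition,
    best: ClassificationRecord,
    n_shuffles: int = 50,
    seed: int = 0,
) -> float:
    """Mean accuracy of the best configuration re-evaluated on shuffled
    trial labels -- the empirical chance level (about 50% for balanced
    two-class data)."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    feats = build_feature_matrix(
        decomp, list(best.component_ids), list(best.specs), best.task
    )
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_shuffles):
        perm = rng.permutation(feats.n_trials)
        accs.append(
            crossval_accuracy(
                feats, folds=best.folds, cv_seed=best.cv_seed,
                labels=feats.labels[perm],
            )
        )
    return float(np.mean(accs))
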