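"""Temporal windows of the 4-s premovement phase and feature extraction.

Three window positions are analyzed: F starts at premovement onset (target
appearance), M starts 1 s after onset (past the typical recognition span),
and B ends at the go cue. Each takes one of four sizes (0.5, 1.0, 1.5,
2.0 s). Features are the raw 100-Hz activation samples of the selected
components inside the window, one value per time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ica import ICADecomposition

POSITIONS: tuple[str, ...] = ("F", "M", "B")
SIZES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
EPOCH_LENGTH = 4.0
M_START = 1.0

#: Trial labels contrasted by each binary task.
TASK_CLASSES: dict[str, tuple[str, str]] = {"LR": ("L", "R"), "TB": ("T", "B")}


@dataclass(frozen=True)
class WindowSpec:
    """One resolved window: position (F/M/B), size, absolute start/stop."""

    position: str
    size: float
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        if not (0.0 <= self.start < self.stop <= EPOCH_LENGTH):
            raise ValueError("window must lie inside [0, 4] s")
        if abs((self.stop - self.start) - self.size) > 1e-9:
            raise ValueError("stop - start must equal size")
        anchors = {"F": self.start == 0.0, "M": self.start == M_START,
                   "B": self.stop == EPOCH_LENGTH}
        if not anchors[self.position]:
            raise ValueError(f"window {self.position} anchored incorrectly")

    @classmethod
    def make(cls, position: str, size: float) -> "WindowSpec":
        """Resolve a (position, size) pair to absolute times."""
        if position == "F":
            start = 0.0
        elif position == "M":
            start = M_START
        elif position == "B":
            start = EPOCH_LENGTH - size
        else:
            raise ValueError(f"position must be one of {POSITIONS}")
        return cls(position=position, size=size, start=start, stop=start + size)

    @property
    def key(self) -> str:
        return f"{self.position}{self.size:g}"


def all_window_specs() -> list[WindowSpec]:
    """The 12 position x size combinations."""
    return [WindowSpec.make(p, s) for p in POSITIONS for s in SIZES]


def window_samples(spec: WindowSpec, rate: float = 100.0) -> tuple[int, int]:
    """Half-open sample index range of a window on the given grid."""
    return int(round(spec.start * rate)), int(round(spec.stop * rate))


@dataclass
class FeatureMatrix:
    """Trials x features with task labels and full provenance."""

    values: np.ndarray
    labels: np.ndarray
    task: str
    component_ids: tuple[int, ...]
    specs: tuple[WindowSpec, ...]
    trial_indices: np.ndarray   # indices into the decomposition's trial axis

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(
    decomp: ICADecomposition,
    component_ids: list[int] | tuple[int, ...],
    specs: list[WindowSpec] | tuple[WindowSpec, ...],
    task: str,
) -> FeatureMatrix:
    """Concatenate windowed activation slices into per-trial feature rows.

    ``component_ids`` holds one pair per spec, flattened in order: a
    single-window classifier passes two components and one spec, a
    two-window (fusion) classifier passes four components and two specs.
    Trials are filtered to the task's two classes.
    """
    if task not in TASK_CLASSES:
        raise ValueError(f"task must be one of {tuple(TASK_CLASSES)}")
    if len(specs) == 0 or len(component_ids) != 2 * len(specs):
        raise ValueError("need exactly two components per window spec")
    flagged = set(component_ids) - set(decomp.usable_components())
    if flagged:
        raise ValueError(f"components {sorted(flagged)} are artifact-flagged")

    classes = TASK_CLASSES[task]
    mask = np.isin(decomp.labels.astype(str), classes)
    trial_idx = np.where(mask)[0]
    if trial_idx.size == 0:
        raise ValueError(f"no trials remain for task {task}")

    rate = decomp.activation_rate
    blocks = []
    for j, spec in enumerate(specs):
        lo, hi = window_samples(spec, rate)
        if hi > decomp.activations.shape[2]:
            raise ValueError("window exceeds activation length")
        for comp in component_ids[2 * j : 2 * j + 2]:
            blocks.append(decomp.activations[trial_idx, comp, lo:hi])
    return FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        labels=decomp.labels[trial_idx].astype(str),
        task=task,
        component_ids=tuple(component_ids),
        specs=tuple(specs),
        trial_indices=trial_idx,
    )
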