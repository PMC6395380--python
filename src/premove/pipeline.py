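"""End-to-end orchestration: session -> epochs -> ICA -> searches -> fusion.

Thin composition of the stage modules with the package defaults; every
stage remains individually callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import (
    SearchResult,
    TASKS,
    fuse_two_windows,
    select_candidates,
    single_window_search,
)
from .ica import (
    ICADecomposition,
    categorize_components,
    downsample_activations,
    fit_extended_infomax,
    identify_artifact_components,
)
from .preprocess import EpochSet, bandpass_filter, extract_epochs, reject_noisy
from .session import RawSession

#: Pipeline defaults: dimensionality kept after whitening, and the stride
#: used when estimating unmixing weights (activations stay full-rate).
DEFAULT_N_COMPONENTS = 10
DEFAULT_FIT_DECIM = 10


def preprocess_session(
    raw: RawSession, z_channel: float = 4.0, ptp_trial: float = 6.0
) -> EpochSet:
    """Band-pass 1.5-4 Hz, epoch the premovement phase, reject outliers."""
    filtered = bandpass_filter(raw)
    epochs = extract_epochs(filtered)
    return reject_noisy(epochs, z_channel=z_channel, ptp_trial=ptp_trial)


def decompose(
    epochs: EpochSet,
    n_components: int = DEFAULT_N_COMPONENTS,
    ica_seed: int = 0,
    fit_decim: int = DEFAULT_FIT_DECIM,
    max_iter: int = 512,
    tol: float = 1e-6,
    target_rate: float = 100.0,
) -> ICADecomposition:
    """ICA + artifact flagging + area categorization + 100-Hz activations."""
    decomp = fit_extended_infomax(
        epochs,
        n_components=n_components,
        max_iter=max_iter,
        tol=tol,
        seed=ica_seed,
        fit_decim=fit_decim,
    )
    identify_artifact_components(decomp)
    categorize_components(decomp)
    return downsample_activations(decomp, target=target_rate)


@dataclass
class SubjectAnalysis:
    """All searches for one subject-condition dataset."""

    decomp: ICADecomposition
    single: dict[str, SearchResult] = field(default_factory=dict)     # task -> result
    fused: dict[tuple[str, str], SearchResult] = field(default_factory=dict)
    # (task, "FB"|"MB") -> result


def analyze_decomposition(
    decomp: ICADecomposition,
    tasks: tuple[str, ...] = TASKS,
    cv_seed: int = 1,
    threshold: float = 65.0,
    subject: str = "S1",
    fusion_positions: tuple[str, ...] = ("F", "M"),
) -> SubjectAnalysis:
    """Exhaustive single-window search per task, then two-window fusion of
    window-B candidates with candidates from each position in
    ``fusion_positions`` (>threshold selection)."""
    out = SubjectAnalysis(decomp=decomp)
    for task in tasks:
        res = single_window_search(decomp, task, cv_seed=cv_seed, subject=subject)
        out.single[task] = res
        cands = select_candidates(res, threshold=threshold)
        cands_b = [c for c in cands if c.specs[0].position == "B"]
        for pos in fusion_positions:
            cands_p = [c for c in cands if c.specs[0].position == pos]
            out.fused[(task, pos + "B")] = fuse_two_windows(
                decomp, cands_b, cands_p, task, cv_seed=cv_seed, subject=subject
            )
    return out


def analyze_session(
    raw: RawSession,
    tasks: tuple[str, ...] = TASKS,
    n_components: int = DEFAULT_N_COMPONENTS,
    ica_seed: int = 0,
    cv_seed: int = 1,
    threshold: float = 65.0,
    subject: str = "S1",
    fusion_positions: tuple[str, ...] = ("F", "M"),
) -> SubjectAnalysis:
    """The full pipeline on one session: preprocessing, decomposition,
    exhaustive single-window searches, two-window fusion."""
    epochs = preprocess_session(raw)
    decomp = decompose(epochs, n_components=n_components, ica_seed=ica_seed)
    return analyze_decomposition(
        decomp, tasks=tasks, cv_seed=cv_seed, threshold=threshold,
        subject=subject, fusion_positions=fusion_positions,
    )
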