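"""ICA decomposition of premovement epochs and component triage.

Fits extended Infomax on mean-removed, PCA-whitened concatenated epochs,
then (a) flags ocular artifact components from their scalp topography and
activation statistics, (b) assigns each component to a scalp area by its
peak electrode, and (c) downsamples activations for feature extraction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .infomax import amari_index, extended_infomax  # re-exported
from .montage import AREA_MAP, normalize_label
from .preprocess import EpochSet

__all__ = [
    "ICADecomposition",
    "fit_extended_infomax",
    "identify_artifact_components",
    "categorize_components",
    "downsample_activations",
    "amari_index",
]

_FRONTAL_SET = ("FP1", "FP2", "AF3", "AF4")
_POSTERIOR_SET = ("P7", "P3", "PZ", "P4", "P8", "PO7", "PO3", "PO4", "PO8", "O1", "O2")


@dataclass
class ICADecomposition:
    """Unmixing/mixing matrices plus per-trial component activations.

    ``scalp_maps`` are the mixing columns (channels x components); component
    order and sign are arbitrary (nothing downstream depends on them).
    """

    unmixing: np.ndarray                 # components x channels
    mixing: np.ndarray                   # channels x components
    activations: np.ndarray              # trials x components x samples
    activation_rate: float
    channel_labels: list[str]
    channel_mean: np.ndarray
    labels: np.ndarray                   # per-trial direction labels
    condition: str
    converged: bool = True
    n_iterations: int = 0
    artifact_flags: list[str] = field(default_factory=list)   # none/blink/saccade/other
    area: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def scalp_maps(self) -> np.ndarray:
        return self.mixing

    def usable_components(self) -> list[int]:
        """Components retained for classification (blink/saccade removed)."""
        if not self.artifact_flags:
            return list(range(self.n_components))
        return [
            i for i, f in enumerate(self.artifact_flags) if f not in ("blink", "saccade")
        ]

    def reconstruct(self) -> np.ndarray:
        """Back-project activations: trials x channels x samples (adds the
        removed channel mean; equals the input up to whitening rank)."""
        rec = np.einsum("ck,tkn->tcn", self.mixing, self.activations)
        return rec + self.channel_mean[None, :, None]


def fit_extended_infomax(
    epochs: EpochSet,
    n_components: int | None = None,
    l_rate: float | None = None,
    max_iter: int = 512,
    tol: float = 1e-6,
    seed: int = 0,
    fit_decim: int = 1,
) -> ICADecomposition:
    """Decompose an EpochSet with extended Infomax.

    Data are concatenated across trials, mean-removed per channel and
    PCA-whitened to at most ``n_components`` (never above numerical rank;
    rank deficiency reduces the count with a warning). ``fit_decim`` fits
    the unmixing weights on every k-th whitened sample -- the band-limited
    data are heavily oversampled and Infomax treats samples as exchangeable,
    so this changes nothing statistically while cutting fit cost -- the
    returned activations are always computed at the full rate. Identical
    seed gives an identical decomposition; non-convergence is reported via
    ``converged`` rather than raised.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot fit ICA on an empty EpochSet")
    X = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]

    cov = (Xc @ Xc.T) / Xc.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    rank = int(np.sum(eigval > eigval[0] * 1e-10))
    if rank < epochs.n_channels:
        warnings.warn(
            f"data rank {rank} < {epochs.n_channels} channels; reducing", stacklevel=2
        )
    ncomp = min(n_components or rank, rank)
    K = (eigvec[:, :ncomp] / np.sqrt(eigval[:ncomp])).T  # whitening, ncomp x channels
    Z = K @ Xc

    n_fit = Z[:, ::fit_decim].shape[1]
    if n_fit < 20 * ncomp**2:
        raise ValueError(
            f"{n_fit} samples is too few to fit {ncomp} components "
            f"(need >= {20 * ncomp ** 2})"
        )
    W, converged, n_iter = extended_infomax(
        Z[:, ::fit_decim], l_rate=l_rate, max_iter=max_iter, tol=tol, seed=seed
    )

    unmixing = W @ K
    mixing = np.linalg.pinv(unmixing)
    acts = np.einsum("kc,tcn->tkn", unmixing, epochs.data - mean[None, :, None])
    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        activations=acts,
        activation_rate=epochs.sample_rate,
        channel_labels=[normalize_label(c) for c in epochs.kept_channel_labels],
        channel_mean=mean,
        labels=epochs.labels,
        condition=epochs.condition,
        converged=converged,
        n_iterations=n_iter,
        artifact_flags=["none"] * ncomp,
        area=[""] * ncomp,
    )


def identify_artifact_components(
    decomp: ICADecomposition,
    frontal_ratio: float = 3.0,
    laterality_ratio: float = 2.0,
    kurtosis_min: float = 5.0,
) -> list[str]:
    """Flag blink and saccade components from topography + activation shape.

    Blink: the two largest |weights| sit at FP1/FP2 (or AF3/AF4) with the
    same sign, frontal-polar weights outweigh posterior ones by
    ``frontal_ratio``, and the activation is sparse/high-kurtosis. Saccade:
    a single lateral-frontal electrode (F7 or F8) has the largest |weight|
    and exceeds its contralateral partner by ``laterality_ratio``.
    Ambiguous components stay flagged ``none``; flags are advisory --
    removal happens where components are selected for classification.
    """
    labels = decomp.channel_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    flags = []
    for k in range(decomp.n_components):
        w = decomp.scalp_maps[:, k]
        absw = np.abs(w)
        top2 = set(labels[i] for i in np.argsort(absw)[::-1][:2])
        flag = "none"

        front = np.mean([absw[idx[c]] for c in _FRONTAL_SET if c in idx])
        post = np.mean([absw[idx[c]] for c in _POSTERIOR_SET if c in idx])
        kurt = float(scipy.stats.kurtosis(decomp.activations[:, k, :], axis=None))
        if (
            top2 in ({"FP1", "FP2"}, {"AF3", "AF4"})
            and np.prod([np.sign(w[idx[c]]) for c in top2]) > 0
            and front > frontal_ratio * max(post, 1e-300)
            and kurt > kurtosis_min
        ):
            flag = "blink"
        elif "F7" in idx and "F8" in idx:
            peak = labels[int(np.argmax(absw))]
            if peak in ("F7", "F8"):
                other = "F8" if peak == "F7" else "F7"
                if absw[idx[peak]] > laterality_ratio * max(absw[idx[other]], 1e-300):
                    flag = "saccade"
        flags.append(flag)
    decomp.artifact_flags = flags
    return flags


def categorize_components(
    decomp: ICADecomposition, area_map: dict[str, str] | None = None
) -> list[str]:
    """Assign each component the scalp area of its peak-|weight| electrode.

    Exact ties are broken by the larger summed |weight| within each
    candidate area, then by alphabetical electrode order.
    """
    area_map = area_map or AREA_MAP
    labels = decomp.channel_labels
    areas = []
    for k in range(decomp.n_components):
        absw = np.abs(decomp.scalp_maps[:, k])
        m = absw.max()
        cand = [i for i in range(len(labels)) if absw[i] >= m * (1.0 - 1e-12)]
        cand_areas = sorted({area_map[labels[i]] for i in cand})
        if len(cand_areas) == 1:
            areas.append(cand_areas[0])
            continue
        weight_in = {
            a: sum(absw[i] for i, lab in enumerate(labels) if area_map[lab] == a)
            for a in cand_areas
        }
        best_w = max(weight_in.values())
        heaviest = [a for a in cand_areas if weight_in[a] >= best_w * (1.0 - 1e-12)]
        if len(heaviest) == 1:
            areas.append(heaviest[0])
        else:
            first = min(
                (labels[i] for i in cand if area_map[labels[i]] in heaviest)
            )
            areas.append(area_map[first])
    decomp.area = areas
    return areas


def downsample_activations(
    decomp: ICADecomposition, target: float = 100.0
) -> ICADecomposition:
    """Anti-alias filter and decimate activations to ``target`` Hz.

    The source rate must be an integer multiple of the target (500 -> 100
    gives 400 samples for a 4-s epoch). Returns a new decomposition;
    matrices and flags are shared.
    """
    ratio = decomp.activation_rate / target
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"cannot decimate {decomp.activation_rate} Hz to {target} Hz: "
            "non-integer factor"
        )
    if q == 1:
        return decomp
    acts = scipy.signal.decimate(
        decomp.activations, q, axis=-1, ftype="fir", zero_phase=True
    )
    return dataclasses.replace(decomp, activations=acts, activation_rate=float(target))
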