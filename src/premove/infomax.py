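"""Extended Infomax ICA: natural-gradient learning on whitened data.

The update maximizes information transfer through a bank of sigmoidal units,
with a per-component sign matrix (re-estimated from a running kurtosis
sample) switching each unit between super-Gaussian and sub-Gaussian
nonlinearities. The learning rate anneals whenever successive weight-change
directions turn by more than a threshold angle, and the fit restarts with a
smaller rate if the weights blow up.
"""

from __future__ import annotations

import numpy as np

_ANNEAL_DEG = 60.0
_ANNEAL_STEP = 0.9
_BLOWUP = 1e4
_BLOWUP_FAC = 0.5
_RESTART_FAC = 0.9
_MIN_L_RATE = 1e-10
_KURT_SIZE = 3000
_SIGNS_BIAS = 0.02
_SIGNCOUNT_THRESH = 10


def extended_infomax(
    Z: np.ndarray,
    l_rate: float | None = None,
    block: int | None = None,
    max_iter: int = 512,
    tol: float = 1e-6,
    seed: int = 0,
    n_subgauss: int = 1,
    ext_blocks: int = 1,
) -> tuple[np.ndarray, bool, int]:
    """Fit an unmixing matrix W (components x components) to whitened data.

    Parameters
    ----------
    Z : ndarray, shape (n_components, n_samples)
        Whitened (unit-covariance, zero-mean) observations.
    l_rate : float, optional
        Initial learning rate; default ``0.01 / log(n**2)``.
    block : int, optional
        Mini-batch size; default ``floor(sqrt(n_samples / 3))``.
    tol : float
        Stop when the summed squared weight change of a full pass falls
        below this threshold.
    seed : int
        Seeds the sample permutation and the kurtosis subsample; identical
        seeds give identical decompositions.

    Returns
    -------
    W : ndarray, shape (n, n)
        Estimated sources are ``W @ Z``.
    converged : bool
    n_iterations : int
    """
    Z = np.asarray(Z, dtype=np.float64)
    n, n_samples = Z.shape
    if n_samples < n:
        raise ValueError("need at least as many samples as components")
    data = Z.T  # (samples, components): mini-batches as row blocks
    rng = np.random.default_rng(seed)

    if l_rate is None:
        l_rate = 0.01 / np.log(float(n) ** 2 + 1.0)
    if block is None:
        block = int(np.sqrt(n_samples / 3.0))
    block = max(8, min(block, n_samples))

    weights = np.identity(n)
    startweights = weights.copy()
    oldweights = weights.copy()
    BI = block * np.identity(n)
    signs = np.ones(n)
    signs[:min(n_subgauss, n)] = -1.0
    oldsigns = np.zeros(n)
    signcount = 0
    kurt_size = min(_KURT_SIZE, n_samples)
    olddelta, oldchange = None, 0.0
    lastt = (n_samples // block - 1) * block + 1

    converged = False
    it = 0
    while it < max_iter:
        permute = rng.permutation(n_samples)
        blockno = 0
        blowup = False
        for t in range(0, lastt, block):
            u = data[permute[t : t + block], :] @ weights
            y = np.tanh(u)
            weights += l_rate * (
                weights @ (BI - signs[None, :] * (u.T @ y) - u.T @ u)
            )
            blockno += 1
            if np.max(np.abs(weights)) > _BLOWUP:
                blowup = True
                break
            if ext_blocks > 0 and blockno % ext_blocks == 0:
                rp = (
                    rng.permutation(n_samples)[:kurt_size]
                    if kurt_size < n_samples
                    else slice(None)
                )
                part = data[rp, :] @ weights
                m2 = np.mean(part**2, axis=0)
                kurt = np.mean(part**4, axis=0) / np.maximum(m2**2, 1e-300) - 3.0
                kurt += _SIGNS_BIAS
                newsigns = np.sign(kurt)
                newsigns[newsigns == 0] = 1.0
                if np.array_equal(newsigns, oldsigns):
                    signcount += 1
                else:
                    signcount = 0
                oldsigns = newsigns
                signs = newsigns
                if signcount >= _SIGNCOUNT_THRESH:
                    ext_blocks = int(ext_blocks * 2)  # signs settled; probe less
                    signcount = 0

        if blowup:
            # diverged: shrink the rate and restart from the initial weights
            l_rate *= _BLOWUP_FAC * _RESTART_FAC
            if l_rate < _MIN_L_RATE:
                raise RuntimeError("extended Infomax failed to stabilize")
            weights = startweights.copy()
            oldweights = startweights.copy()
            olddelta, oldchange = None, 0.0
            continue

        it += 1
        wtschange = weights - oldweights
        delta = wtschange.ravel()
        change = float(delta @ delta)
        if olddelta is not None and change > 1e-300 and oldchange > 1e-300:
            cosang = float(olddelta @ delta) / np.sqrt(change * oldchange)
            angledelta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angledelta > _ANNEAL_DEG:
                l_rate *= _ANNEAL_STEP
                olddelta, oldchange = delta, change
        else:
            olddelta, oldchange = delta, change
        oldweights = weights.copy()
        if change < tol:
            converged = True
            break

    return weights.T, converged, it


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of a square gain matrix.

    ``P = W_est @ A_true`` (possibly through the whitening transform) is a
    scaled permutation for perfect separation, giving 0; the normalization
    keeps the index in [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("Amari index needs a square matrix")
    rows = (P / np.maximum(P.max(axis=1, keepdims=True), 1e-300)).sum(axis=1) - 1.0
    cols = (P / np.maximum(P.max(axis=0, keepdims=True), 1e-300)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))
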