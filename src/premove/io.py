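"""File interfaces: EDF recordings, events sidecars, array containers.

Sessions are written as standard EDF (16-bit, 1-s data records) with a
plain-TSV events sidecar (onset_sample, label, condition). Reading goes
through mne's EDF reader. Epochs, decompositions and ground truth use
NumPy ``.npz`` containers with JSON metadata alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .preprocess import EpochSet
from .session import Event, RawSession
from .simulate import GroundTruth, SimConfig

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(session: RawSession, path: str | Path) -> Path:
    """Write a RawSession as EDF (one signal per channel, microvolts).

    Data records last 1 s; the final record is zero-padded, and the true
    sample count is recorded in the events sidecar so loaders can trim.
    """
    path = Path(path)
    fs = session.sample_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_ch, n_samp = session.data.shape
    n_rec = int(np.ceil(n_samp / spr))

    phys_min = session.data.min(axis=1)
    phys_max = session.data.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span <= 0, phys_min + 1.0, phys_max)

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X premove synthetic", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (1 + n_ch)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for ch in session.channel_labels:
            fh.write(_pad(ch, 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_EDF_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_EDF_DIG_MAX), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))

        # physical -> digital scaling uses the *printed* (8-char) physical
        # bounds so a reader recovers our values exactly up to quantization
        pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
        gain = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
        padded = np.zeros((n_ch, n_rec * spr))
        padded[:, :n_samp] = session.data
        dig = np.clip(
            np.round((padded - pmin[:, None]) * gain[:, None] + _EDF_DIG_MIN),
            _EDF_DIG_MIN,
            _EDF_DIG_MAX,
        ).astype("<i2")
        for r in range(n_rec):
            fh.write(dig[:, r * spr : (r + 1) * spr].tobytes())
    return path


def write_events_tsv(session: RawSession, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={session.sample_rate:g}\n")
        fh.write(f"# epoch_length={session.epoch_length:g}\n")
        fh.write(f"# n_samples={session.n_samples}\n")
        fh.write("onset_sample\tlabel\tcondition\n")
        for ev in session.events:
            fh.write(f"{ev.onset}\t{ev.label}\t{ev.condition}\n")
    return path


def read_session(edf_path: str | Path, events_path: str | Path | None = None) -> RawSession:
    """Load an EDF recording plus its events sidecar into a RawSession."""
    import mne

    edf_path = Path(edf_path)
    if events_path is None:
        events_path = edf_path.with_suffix(".events.tsv")
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned EDF signals
    fs = float(raw.info["sfreq"])

    meta: dict = {}
    events: list[Event] = []
    n_samples = data.shape[1]
    epoch_length = 4.0
    with open(events_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, val = line.lstrip("# ").split("=")
                meta[key] = float(val)
                continue
            if line.startswith("onset_sample"):
                continue
            onset, label, condition = line.split("\t")
            events.append(Event(onset=int(onset), label=label, condition=condition))
    if "n_samples" in meta:
        n_samples = int(meta["n_samples"])
        data = data[:, :n_samples]
    if "epoch_length" in meta:
        epoch_length = meta["epoch_length"]
    if "sample_rate" in meta and abs(meta["sample_rate"] - fs) > 1e-6:
        raise ValueError("events sidecar sample rate disagrees with the EDF header")
    return RawSession(
        data=data,
        channel_labels=list(raw.ch_names),
        events=events,
        sample_rate=fs,
        epoch_length=epoch_length,
    )


def save_ground_truth(truth: GroundTruth, stem: str | Path) -> None:
    """GroundTruth -> <stem>.npz (arrays) + <stem>.json (ids, labels)."""
    stem = Path(stem)
    np.savez_compressed(
        stem.with_suffix(".npz"),
        mixing_matrix=truth.mixing_matrix,
        source_activations=truth.source_activations,
        artifact_timecourses=truth.artifact_timecourses,
    )
    meta = {
        "informative_source_ids": truth.informative_source_ids,
        "artifact_source_ids": truth.artifact_source_ids,
        "labels": truth.labels,
        "source_centers": truth.source_centers,
        "saccade_events": truth.saccade_events,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_ground_truth(stem: str | Path) -> GroundTruth:
    stem = Path(stem)
    arrays = np.load(stem.with_suffix(".npz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return GroundTruth(
        mixing_matrix=arrays["mixing_matrix"],
        source_activations=arrays["source_activations"],
        artifact_timecourses=arrays["artifact_timecourses"],
        informative_source_ids={
            ph: {t: int(i) for t, i in d.items()}
            for ph, d in meta["informative_source_ids"].items()
        },
        artifact_source_ids={
            k: [int(i) for i in v] for k, v in meta["artifact_source_ids"].items()
        },
        labels=meta["labels"],
        source_centers=meta["source_centers"],
        saccade_events=meta["saccade_events"],
    )


def save_epochs(epochs: EpochSet, stem: str | Path) -> None:
    stem = Path(stem)
    np.savez_compressed(stem.with_suffix(".npz"), data=epochs.data)
    meta = {
        "labels": list(map(str, epochs.labels)),
        "condition": epochs.condition,
        "sample_rate": epochs.sample_rate,
        "kept_channel_labels": epochs.kept_channel_labels,
        "rejection_log": epochs.rejection_log,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(
        data=np.load(stem.with_suffix(".npz"))["data"],
        labels=np.asarray(meta["labels"], dtype=object),
        condition=meta["condition"],
        sample_rate=meta["sample_rate"],
        kept_channel_labels=meta["kept_channel_labels"],
        rejection_log=meta["rejection_log"],
    )


def save_decomposition(decomp, stem: str | Path) -> None:
    from .ica import ICADecomposition  # noqa: F401  (type only)

    stem = Path(stem)
    np.savez_compressed(
        stem.with_suffix(".npz"),
        unmixing=decomp.unmixing,
        mixing=decomp.mixing,
        activations=decomp.activations,
        channel_mean=decomp.channel_mean,
    )
    meta = {
        "activation_rate": decomp.activation_rate,
        "channel_labels": decomp.channel_labels,
        "labels": list(map(str, decomp.labels)),
        "condition": decomp.condition,
        "converged": bool(decomp.converged),
        "n_iterations": int(decomp.n_iterations),
        "artifact_flags": decomp.artifact_flags,
        "area": decomp.area,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_decomposition(stem: str | Path):
    from .ica import ICADecomposition

    stem = Path(stem)
    arrays = np.load(stem.with_suffix(".npz"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ICADecomposition(
        unmixing=arrays["unmixing"],
        mixing=arrays["mixing"],
        activations=arrays["activations"],
        channel_mean=arrays["channel_mean"],
        activation_rate=meta["activation_rate"],
        channel_labels=meta["channel_labels"],
        labels=np.asarray(meta["labels"], dtype=object),
        condition=meta["condition"],
        converged=meta["converged"],
        n_iterations=meta["n_iterations"],
        artifact_flags=meta["artifact_flags"],
        area=meta["area"],
    )


def export_scalp_maps_csv(decomp, path: str | Path) -> Path:
    """Scalp maps as long-format CSV: component, electrode, weight."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("component,electrode,weight\n")
        for k in range(decomp.n_components):
            for i, ch in enumerate(decomp.channel_labels):
                fh.write(f"{k},{ch},{decomp.scalp_maps[i, k]:.10g}\n")
    return path


def save_search_result(result, stem: str | Path) -> None:
    """SearchResult -> CSV (one record per row) + JSON."""
    stem = Path(stem)
    rows = []
    for r in result.records:
        rows.append(
            {
                "task": r.task,
                "component_ids": " ".join(map(str, r.component_ids)),
                "windows": " ".join(s.key for s in r.specs),
                "position": r.position_key,
                "accuracy": r.accuracy,
                "folds": r.folds,
                "cv_seed": r.cv_seed,
                "n_trials": r.n_trials,
            }
        )
    with open(stem.with_suffix(".csv"), "w") as fh:
        cols = ["task", "component_ids", "windows", "position", "accuracy",
                "folds", "cv_seed", "n_trials"]
        fh.write(",".join(cols) + "\n")
        for row in rows:
            fh.write(",".join(str(row[c]) for c in cols) + "\n")
    payload = {
        "subject": result.subject,
        "condition": result.condition,
        "total_runs": result.total_runs,
        "records": rows,
    }
    stem.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def load_sim_config(path: str | Path) -> SimConfig:
    """SimConfig from a YAML mapping (unknown keys rejected)."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig(**payload)


def save_sim_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return path
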