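"""File containers for EEG, TRFs, and result tables.

The native EEG container is a plain CSV matrix (rows = samples over all
trials concatenated, columns = channels) next to a JSON sidecar holding
``fs``, ``channel_labels``, ``trial_boundaries`` (start sample of each
trial plus the total length), and optionally a 2-D channel layout.
A minimal EDF reader covers the common single-record-layout continuous
case so recorded data can be imported without extra dependencies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trf import AccuracyTable, EEGTrialSet, TRFModel


# ---------------------------------------------------------------------------
# CSV + JSON sidecar container
# ---------------------------------------------------------------------------

def write_eeg_container(path_prefix, eeg: EEGTrialSet) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (samples x channels) and ``<prefix>.json``."""
    prefix = Path(path_prefix)
    data = np.concatenate([t.T for t in eeg.trials], axis=0)
    bounds = np.cumsum([0] + [t.shape[1] for t in eeg.trials]).tolist()
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame(data, columns=eeg.channel_labels).to_csv(csv_path, index=False)
    sidecar = {
        "fs": eeg.fs,
        "channel_labels": eeg.channel_labels,
        "trial_boundaries": bounds,
        "normalized": eeg.normalized,
        "layout": None if eeg.layout is None else eeg.layout.tolist(),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_eeg_container(path_prefix) -> EEGTrialSet:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    data = pd.read_csv(prefix.with_suffix(".csv")).to_numpy(dtype=float)
    bounds = sidecar["trial_boundaries"]
    trials = [data[a:b].T for a, b in zip(bounds[:-1], bounds[1:])]
    layout = sidecar.get("layout")
    return EEGTrialSet(
        trials=trials,
        fs=float(sidecar["fs"]),
        channel_labels=list(sidecar["channel_labels"]),
        layout=None if layout is None else np.asarray(layout, dtype=float),
        normalized=bool(sidecar.get("normalized", False)),
    )


# ---------------------------------------------------------------------------
# EDF import (continuous recordings, identical rate across signals)
# ---------------------------------------------------------------------------

def read_edf(path) -> EEGTrialSet:
    """Read an EDF file as a single-trial :class:`EEGTrialSet`.

    Supports the standard EDF layout: 16-bit little-endian samples with
    per-signal digital/physical scaling. Annotation channels
    (``EDF Annotations``) are skipped. All retained signals must share one
    sampling rate.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_records = int(header[236:244].decode("ascii").strip())
        record_dur = float(header[244:252].decode("ascii").strip())
        n_sig = int(header[252:256].decode("ascii").strip())

        def fields(width):
            raw = fh.read(width * n_sig)
            return [raw[i * width:(i + 1) * width].decode("ascii").strip()
                    for i in range(n_sig)]

        labels = fields(16)
        fh.read(80 * n_sig)  # transducer
        fh.read(8 * n_sig)   # physical dimension
        phys_min = [float(v) for v in fields(8)]
        phys_max = [float(v) for v in fields(8)]
        dig_min = [float(v) for v in fields(8)]
        dig_max = [float(v) for v in fields(8)]
        fh.read(80 * n_sig)  # prefiltering
        n_samp = [int(v) for v in fields(8)]
        fh.read(32 * n_sig)  # reserved

        keep = [i for i, lab in enumerate(labels) if lab != "EDF Annotations"]
        rates = {n_samp[i] / record_dur for i in keep}
        if len(rates) != 1:
            raise ValueError("EDF signals with mixed sampling rates are unsupported")
        fs = rates.pop()

        chunks: dict[int, list[np.ndarray]] = {i: [] for i in keep}
        for _ in range(n_records):
            for i in range(n_sig):
                raw = np.frombuffer(fh.read(2 * n_samp[i]), dtype="<i2")
                if i in chunks:
                    chunks[i].append(raw.astype(float))

    trial = []
    for i in keep:
        dig = np.concatenate(chunks[i])
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        trial.append(phys_min[i] + (dig - dig_min[i]) * gain)
    return EEGTrialSet(
        trials=[np.vstack(trial)], fs=fs,
        channel_labels=[labels[i] for i in keep],
    )


def split_trials(eeg: EEGTrialSet, n_trials: int) -> EEGTrialSet:
    """Segment a single continuous trial into equal-length trials."""
    if eeg.n_trials != 1:
        raise ValueError("split_trials expects a single continuous trial")
    data = eeg.trials[0]
    per = data.shape[1] // n_trials
    trials = [data[:, i * per:(i + 1) * per] for i in range(n_trials)]
    return EEGTrialSet(
        trials=trials, fs=eeg.fs, channel_labels=list(eeg.channel_labels),
        layout=eeg.layout, normalized=eeg.normalized,
    )


# ---------------------------------------------------------------------------
# result tables: TSV body + JSON header sidecar
# ---------------------------------------------------------------------------

def write_trf_tsv(path, model: TRFModel, meta: dict | None = None) -> None:
    """Long-format TRF export: feature, lag_ms, channel, weight."""
    path = Path(path)
    rows = []
    lag_ms = model.lag_spec.lag_times_ms
    for fi, name in enumerate(model.feature_names):
        for li, t in enumerate(lag_ms):
            for ch in range(model.n_channels):
                rows.append((name, t, ch, model.weights[fi, li, ch]))
    pd.DataFrame(rows, columns=["feature", "lag_ms", "channel", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    header = {
        "lambda": model.lambda_used,
        "feature_names": model.feature_names,
        "bias": model.bias.tolist(),
        "fs": model.lag_spec.fs,
        "lag_min_ms": model.lag_spec.lag_min_ms,
        "lag_max_ms": model.lag_spec.lag_max_ms,
    }
    if meta:
        header.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def write_accuracy_tsv(path, table: AccuracyTable, meta: dict | None = None) -> None:
    path = Path(path)
    n_trials, n_ch = table.r.shape
    rows = [
        (ti, ch, table.r[ti, ch], table.valid_sample_fraction[ti])
        for ti in range(n_trials) for ch in range(n_ch)
    ]
    pd.DataFrame(rows, columns=["trial", "channel", "r", "valid_fraction"]).to_csv(
        path, sep="\t", index=False
    )
    header = {"model_id": table.model_id, "condition": table.condition}
    if meta:
        header.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def read_accuracy_tsv(path) -> AccuracyTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    n_trials = df["trial"].max() + 1
    n_ch = df["channel"].max() + 1
    r = np.full((n_trials, n_ch), np.nan)
    r[df["trial"], df["channel"]] = df["r"]
    frac = df.groupby("trial")["valid_fraction"].first().to_numpy()
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return AccuracyTable(
        r=r, valid_sample_fraction=frac,
        model_id=header.get("model_id", ""), condition=header.get("condition", ""),
    )
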