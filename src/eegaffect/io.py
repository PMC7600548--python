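"""Cohort containers on disk and external-format import.

A cohort directory holds one sub-directory per participant with an HDF5
array file (``epochs.h5``: epochs × channels × samples, float32) and a JSON
sidecar (sampling rate, channel names/positions, per-epoch stimulus ids,
generator ground truth when simulated), plus the shared stimulus table and
schedule as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import ParticipantRecording
from .stimuli import StimulusSet, TrialSchedule


def _json_safe(obj):
    if isinstance(obj, dict):
        return {
            ("/".join(map(str, k)) if isinstance(k, tuple) else k): _json_safe(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def save_cohort(
    recordings: list[ParticipantRecording],
    stimuli: StimulusSet,
    schedule: TrialSchedule,
    directory,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stimuli.to_csv(directory / "stimuli.csv")
    schedule.table.to_csv(directory / "schedule.csv", index=False)
    for rec in recordings:
        pdir = directory / rec.participant_id
        pdir.mkdir(exist_ok=True)
        with h5py.File(pdir / "epochs.h5", "w") as f:
            f.create_dataset("epochs", data=rec.epochs.astype(np.float32))
        meta = {
            "participant_id": rec.participant_id,
            "sampling_rate": rec.sampling_rate,
            "channel_names": list(rec.channel_names),
            "channel_positions": rec.channel_positions.tolist(),
            "stimulus_ids": np.asarray(rec.stimulus_ids).tolist(),
            "ground_truth": _json_safe(rec.ground_truth),
        }
        (pdir / "meta.json").write_text(json.dumps(meta))
    return directory


def _restore_ground_truth(gt: dict) -> dict:
    gt = dict(gt)
    sources = []
    for s in gt.get("sources", []):
        s = dict(s)
        for key in ("location_mm", "moment_direction", "lead_uv"):
            if key in s:
                s[key] = np.asarray(s[key], dtype=float)
        if "band_slopes" in s and s["band_slopes"]:
            s["band_slopes"] = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in s["band_slopes"].items()
            }
        sources.append(s)
    gt["sources"] = sources
    gt["log_band_power"] = {
        name: np.asarray(v, dtype=float)
        for name, v in gt.get("log_band_power", {}).items()
    }
    return gt


def load_cohort(directory) -> tuple[list[ParticipantRecording], StimulusSet, TrialSchedule]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"cohort directory {directory} does not exist")
    stimuli = StimulusSet.from_csv(directory / "stimuli.csv")
    schedule = TrialSchedule(table=pd.read_csv(directory / "schedule.csv"))
    recordings = []
    for pdir in sorted(d for d in directory.iterdir() if d.is_dir()):
        meta = json.loads((pdir / "meta.json").read_text())
        with h5py.File(pdir / "epochs.h5", "r") as f:
            epochs = f["epochs"][()]
        recordings.append(
            ParticipantRecording(
                participant_id=meta["participant_id"],
                epochs=epochs,
                sampling_rate=float(meta["sampling_rate"]),
                channel_names=list(meta["channel_names"]),
                channel_positions=np.asarray(meta["channel_positions"], dtype=float),
                stimulus_ids=np.asarray(meta["stimulus_ids"], dtype=int),
                schedule=schedule,
                ground_truth=_restore_ground_truth(meta.get("ground_truth", {})),
            )
        )
    if not recordings:
        raise FileNotFoundError(f"no participant directories under {directory}")
    return recordings, stimuli, schedule


def load_continuous_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Import a continuous EDF/BDF recording as (data µV, rate, names)."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_results(results: pd.DataFrame, directory, report: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results.to_csv(directory / "results.csv", index=False)
    (directory / "results.json").write_text(
        json.dumps(_json_safe(results.to_dict(orient="records")), indent=2)
    )
    if report is not None:
        (directory / "report.json").write_text(json.dumps(_json_safe(report), indent=2))
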