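"""Reading and writing the pipeline's plain-text exchange formats.

A cohort directory holds one subdirectory per participant
(``beats.csv``, ``truth_hr.csv``, ``device_<id>.csv``, optionally
``ecg.csv``) plus cohort-level ``annotations.csv`` and
``provenance.json``. All tables are plain CSV with seconds-from-start
timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BeatSequence, SampleStream
from .synthetic import DeviceErrorModel, Malfunction

__all__ = ["LoadedRecording", "load_cohort", "device_model_from_dict"]


@dataclass
class LoadedRecording:
    participant_id: str
    beats: BeatSequence
    device_streams: dict[str, SampleStream]
    annotations: pd.DataFrame
    ecg: tuple[np.ndarray, np.ndarray] | None = None


def _infer_mode(t_s: np.ndarray) -> str:
    if len(t_s) < 2:
        return "sparse"
    return "oversampled" if np.median(np.diff(t_s)) <= 1.0 else "sparse"


def load_cohort(data_dir: str | Path) -> list[LoadedRecording]:
    """Load a cohort directory into pipeline-ready records.

    Device sampling modes are taken from ``provenance.json`` when
    available and inferred from the median inter-sample gap otherwise.
    """
    data_dir = Path(data_dir)
    ann_path = data_dir / "annotations.csv"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.csv in {data_dir}")
    annotations = pd.read_csv(ann_path)
    prov = {}
    prov_path = data_dir / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
    records = []
    for pid, ann in annotations.groupby("participant_id", sort=True):
        pdir = data_dir / str(pid)
        beats = BeatSequence.from_frame(pd.read_csv(pdir / "beats.csv"))
        streams: dict[str, SampleStream] = {}
        for f in sorted(pdir.glob("device_*.csv")):
            dev_id = f.stem[len("device_") :]
            df = pd.read_csv(f)
            mode = None
            dev_prov = prov.get(str(pid), {}).get("devices", {}).get(dev_id)
            if dev_prov:
                mode = DeviceErrorModel(**_malf(dev_prov)).nominal_mode
            if mode is None:
                mode = _infer_mode(df["t_s"].to_numpy())
            streams[dev_id] = SampleStream(
                samples=df, device_id=dev_id, nominal_mode=mode
            )
        ecg = None
        ecg_path = pdir / "ecg.csv"
        if ecg_path.exists():
            edf = pd.read_csv(ecg_path)
            ecg = (edf["t_s"].to_numpy(float), edf["mv"].to_numpy(float))
        records.append(
            LoadedRecording(
                participant_id=str(pid),
                beats=beats,
                device_streams=streams,
                annotations=ann.reset_index(drop=True),
                ecg=ecg,
            )
        )
    return records


def _malf(d: dict) -> dict:
    d = dict(d)
    if isinstance(d.get("malfunction"), dict):
        d["malfunction"] = Malfunction(**d["malfunction"])
    return d


def device_model_from_dict(device_id: str, params: dict) -> DeviceErrorModel:
    """Build a device error model from a plain config mapping."""
    return DeviceErrorModel(device_id=device_id, **_malf(params))
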