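"""Dataset persistence: portable array containers with JSON sidecars plus
CSV tables.

Layout of a study directory::

    dataset/
      config.yaml                  resolved simulation config
      design_sessions.csv          participant, session, treatment, session_order
      design_sequences.csv         participant, session, sequence, face_hz, house_hz
      events.csv                   color changes (s from sequence onset)
      presses.csv                  key presses (s from sequence onset)
      recordings/sub-XX_ses-Y.npy  float32 channels x samples, µV
      recordings/sub-XX_ses-Y.json sidecar: ch_names, sfreq, events, units
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimulationConfig
from .containers import Recording


def write_recording(path: str | Path, rec: Recording) -> None:
    path = Path(path)
    try:
        np.save(path, rec.data.astype(np.float32))
    except OSError as exc:  # pragma: no cover - disk failure path
        raise OSError(f"failed to write recording to {path}: {exc}") from exc
    sidecar = dict(
        ch_names=list(rec.ch_names),
        sfreq=rec.sfreq,
        events=[[float(t), lab] for t, lab in rec.events],
        units="uV",
        meta={k: v for k, v in rec.meta.items() if isinstance(v, (int, float, str))},
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    data = np.load(path).astype(float)
    side = json.loads(path.with_suffix(".json").read_text())
    return Recording(
        data=data,
        sfreq=float(side["sfreq"]),
        ch_names=list(side["ch_names"]),
        events=[(float(t), str(lab)) for t, lab in side["events"]],
        meta=side.get("meta", {}),
    )


def write_study_tables(out_dir: str | Path, study) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study.design.sessions.to_csv(out_dir / "design_sessions.csv", index=False)
    study.design.sequences.to_csv(out_dir / "design_sequences.csv", index=False)
    study.events.to_csv(out_dir / "events.csv", index=False)
    study.presses.to_csv(out_dir / "presses.csv", index=False)
    cfg = dataclasses.asdict(study.config)
    cfg["cell_means"] = {f"{k[0]}/{k[1]}": v for k, v in cfg["cell_means"].items()}
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_study(dataset_dir: str | Path):
    """Load a study directory written by :func:`fpvs.simulate.simulate_study`.

    Recordings stay on disk; :class:`fpvs.simulate.StudyData` loads them
    lazily via their paths.
    """
    from .simulate import StudyData, StudyDesign

    d = Path(dataset_dir)
    for req in ("design_sessions.csv", "design_sequences.csv", "events.csv", "presses.csv"):
        if not (d / req).exists():
            raise FileNotFoundError(f"dataset {d} is missing {req}")
    cfg_raw = yaml.safe_load((d / "config.yaml").read_text()) if (d / "config.yaml").exists() else {}
    if "cell_means" in cfg_raw:
        cfg_raw["cell_means"] = {
            tuple(k.split("/")): v for k, v in cfg_raw["cell_means"].items()
        }
    if "face_house_rates" in cfg_raw and isinstance(cfg_raw["face_house_rates"], list):
        cfg_raw["face_house_rates"] = tuple(cfg_raw["face_house_rates"])
    config = SimulationConfig(**cfg_raw)
    design = StudyDesign(
        pd.read_csv(d / "design_sessions.csv"), pd.read_csv(d / "design_sequences.csv")
    )
    recordings = {}
    for path in sorted((d / "recordings").glob("sub-*_ses-*.npy")):
        stem = path.stem  # sub-XX_ses-Y
        pid = int(stem.split("_")[0].split("-")[1])
        ses = int(stem.split("_")[1].split("-")[1])
        recordings[(pid, ses)] = path
    return StudyData(
        design=design,
        config=config,
        recordings=recordings,
        events=pd.read_csv(d / "events.csv"),
        presses=pd.read_csv(d / "presses.csv"),
        profiles={},
    )
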