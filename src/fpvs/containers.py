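"""In-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """A continuous multi-channel recording in microvolts.

    ``data`` is (n_channels, n_samples); ``events`` is a list of
    ``(time_in_seconds, label)`` markers, e.g. ``(2.0, "sequence:0")``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def sequence_onsets(self) -> list[float]:
        return [t for t, lab in self.events if lab.startswith("sequence")]


@dataclass
class Epoch:
    """One sequence epoch (channels x samples, microvolts) with provenance.

    ``info`` carries the design coordinates of the epoch: participant,
    session, sequence index, treatment, session order and the
    rate-to-category map (``face_hz``/``house_hz``).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    info: dict = field(default_factory=dict)
    bad_channels: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, data: np.ndarray, note: str | None = None) -> "Epoch":
        ep = Epoch(
            data=data,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            info=dict(self.info),
            bad_channels=list(self.bad_channels),
            provenance=list(self.provenance),
        )
        if note:
            ep.provenance.append(note)
        return ep

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]
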