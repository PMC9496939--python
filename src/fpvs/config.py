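"""Pipeline configuration: dataclasses with YAML round-trip.

Every tunable the pipeline exposes lives here so a run can write its
resolved configuration next to its outputs and be reproduced from it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


def _within_sd_for_retest(
    rho: float, between_sd: float, row_sd: float, rows_per_mean: int = 6
) -> float:
    """Session-level noise SD that hits a target test-retest correlation.

    Between-session correlation of per-stimulus session means (averages of
    ``rows_per_mean`` rows) is
    ``rho = sb^2 / (sb^2 + sw^2 + se^2 / rows_per_mean)``; solve for ``sw``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    var = between_sd**2 * (1 - rho) / rho - row_sd**2 / rows_per_mean
    if var <= 0:
        raise ValueError("target correlation infeasible for given row noise")
    return float(var**0.5)


@dataclass
class SimulationConfig:
    """Generative study conditions.

    Amplitudes are summed baseline-corrected responses in microvolts (the
    quantity the analysis reports); cell means reproduce the observed
    face/house-by-ROI topography. ``treatment_effect_*`` is added to the
    summed amplitude under the active (OT) condition; 0 models the null.
    """

    n_participants: int = 31
    n_sequences: int = 4
    sequence_duration: float = 60.0
    sfreq: float = 512.0
    face_house_rates: tuple[float, float] = (6.0, 7.5)
    pre_pad: float = 2.0
    post_pad: float = 7.0
    inter_sequence_gap: float = 8.0

    # fixation-cross color-change task
    n_color_changes: int = 15
    change_duration: float = 0.3
    min_change_gap: float = 2.0
    false_alarm_rate: float = 0.01  # presses/s outside real changes

    # response topography: mean summed amplitude (µV) per stimulus x ROI.
    # ROI marginals are (LOT, MO, ROT) = (1.22, 2.20, 1.61), the stimulus
    # marginals are equal, and the face-house contrast is positive over the
    # lateral occipito-temporal regions and negative medially.
    cell_means: dict = field(
        default_factory=lambda: {
            ("face", "LOT"): 1.445,
            ("face", "MO"): 1.575,
            ("face", "ROT"): 2.010,
            ("house", "LOT"): 0.995,
            ("house", "MO"): 2.825,
            ("house", "ROT"): 1.210,
        }
    )
    harmonic_decay: float = 0.5
    n_harmonics: int = 2
    topography_falloff: float = 0.35  # unit-sphere chord scale of ROI gaussians

    # variance structure (µV on the summed-amplitude scale)
    between_sd: float = 0.45  # participant effect, shared across sessions
    within_sd: float = _within_sd_for_retest(0.90, 0.45, 0.10)  # per session
    row_sd: float = 0.10  # residual per table row
    target_retest_r: float = 0.90
    z_noise_sd: float = 0.05  # bin-noise scale used for the fast-path Z proxy

    treatment_effect_face: float = 0.0
    treatment_effect_house: float = 0.0

    # nuisance components of the raw signal
    noise_scale: float = 10.0  # pink-noise SD, µV
    pink_exponent: float = 1.0
    alpha_burst_rate: float = 0.05  # bursts/s
    alpha_burst_amp: float = 3.0  # µV at posterior electrodes
    alpha_freq: float = 10.0
    blink_rate_mean: float = 0.09  # blinks/s across participants
    blink_rate_sd: float = 0.08
    blink_amp_veog: float = 150.0  # µV on the vertical ocular difference
    blink_amp_scalp: float = 50.0  # µV at the most frontal scalp sites
    blink_duration: float = 0.4

    # behavior
    hit_p_mean: float = 0.945
    hit_p_sd: float = 0.02
    rt_shift: float = 0.1
    rt_median: float = 0.31  # median of the lognormal part, s
    rt_median_sd: float = 0.02  # between-participant spread of rt_median
    rt_sigma: float = 0.25  # lognormal shape


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (0.1, 100.0)
    filter_order: int = 4
    resample_to: float = 256.0
    blink_flag_sd: float = 1.5  # flag participants > mean + this*SD
    blink_mad_threshold: float = 4.0  # detection threshold in scaled-MAD units
    blink_refractory: float = 0.2  # s
    bad_channels: dict = field(default_factory=dict)  # participant -> [labels]


@dataclass
class SpectralConfig:
    crop_mode: str = "nominal"  # "nominal" (15203 samples) or "exact-bin" (15360)
    noise_bins: str = "split"  # "split" | "shared" | "narrow"  (see spectral)
    z_threshold: float = 1.64
    max_harmonics: int = 6
    flank_bins: int = 22  # each side, individual-level windows


@dataclass
class StatsConfig:
    mad_k: float = 3.0
    alpha: float = 0.05
    n_posterior_draws: int = 20000
    reml: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuple-keyed cell means are not YAML-representable; flatten
        cm = d["simulation"]["cell_means"]
        d["simulation"]["cell_means"] = {f"{k[0]}/{k[1]}": v for k, v in cm.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.get("simulation", {}))
        if "cell_means" in sim:
            sim["cell_means"] = {
                tuple(k.split("/")) if isinstance(k, str) else tuple(k): v
                for k, v in sim["cell_means"].items()
            }
        sim = _coerce_tuples(sim, ("face_house_rates",))
        pre = _coerce_tuples(dict(d.get("preprocess", {})), ("band",))
        return cls(
            seed=int(d.get("seed", 0)),
            simulation=SimulationConfig(**sim),
            preprocess=PreprocessConfig(**pre),
            spectral=SpectralConfig(**d.get("spectral", {})),
            stats=StatsConfig(**d.get("stats", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def apply_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``section.key=value`` overrides and return a new config."""
        d = self.to_dict()
        for ov in overrides:
            key, _, raw = ov.partition("=")
            if not _:
                raise ValueError(f"override {ov!r} is not key=value")
            target = d
            parts = key.strip().split(".")
            for p in parts[:-1]:
                target = target[p]
            target[parts[-1]] = yaml.safe_load(raw)
        return PipelineConfig.from_dict(d)


def _coerce_tuples(d: dict, keys: tuple[str, ...]) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d
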