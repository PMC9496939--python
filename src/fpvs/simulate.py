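"""Synthetic frequency-tagging EEG studies.

Generates complete cross-over studies — raw recordings, sequence/color-change
events, key presses and design tables — with the statistical structure the
downstream analysis assumes:

* two 60-s stimulation streams tagged at 6 and 7.5 Hz (rate-to-category
  counterbalanced across the 4 sequences of a session),
* face-selective lateral occipito-temporal and house-selective medial
  occipital topographies (zero-mean "dipolar" scalp maps, so common-average
  re-referencing leaves the signal untouched),
* 1/f pink noise, 10 Hz alpha bursts and biphasic blink transients,
* a participant random effect shared across the two sessions, which is what
  produces the ~0.9 between-session reliability of the summed responses,
* a configurable additive treatment effect (default 0, the null).

Two generation paths exist. The full-waveform path (`simulate_study`) renders
raw 512 Hz recordings and is meant for end-to-end validation at small n; a
31-participant study is ~2.4 GB of samples, so it streams sessions to disk
when given a directory. The amplitude-level path (`simulate_response_table`)
draws the measured summed responses directly from the same generative model
and is what the statistics layer is calibrated on at full scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import Recording
from .montage import OCULAR, ROIS, all_channels, roi_centroid, scalp_channels, unit_sphere_positions

STIMULI = ("face", "house")
TREATMENTS = ("OT", "PL")
ORDERS = ("OT-first", "PL-first")


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Session and sequence bookkeeping of a cross-over study.

    ``sessions``: participant, session (1/2), treatment, session_order.
    ``sequences``: participant, session, sequence (0..3), face_hz, house_hz.
    """

    sessions: pd.DataFrame
    sequences: pd.DataFrame

    @property
    def n_participants(self) -> int:
        return self.sessions["participant"].nunique()

    def treatment_of(self, participant: int, session: int) -> str:
        m = self.sessions
        row = m[(m.participant == participant) & (m.session == session)]
        return str(row["treatment"].iloc[0])


def make_design(n_participants: int, seed: int) -> StudyDesign:
    """Balanced cross-over design: 2 sessions per participant with opposite
    treatments, treatment order balanced across participants, and the
    rate-to-category assignment counterbalanced over the 4 sequences of each
    session (2 sequences per mapping)."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_participants % 2:
        warnings.warn(
            "odd n_participants: treatment order can only be balanced to within one",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    orders = [ORDERS[0]] * (n_participants // 2) + [ORDERS[1]] * (n_participants // 2)
    if n_participants % 2:
        orders.append(ORDERS[rng.integers(2)])
    rng.shuffle(orders)

    srows, qrows = [], []
    for pid in range(1, n_participants + 1):
        order = orders[pid - 1]
        for session in (1, 2):
            if order == "OT-first":
                treatment = "OT" if session == 1 else "PL"
            else:
                treatment = "PL" if session == 1 else "OT"
            srows.append(
                dict(participant=pid, session=session, treatment=treatment,
                     session_order=order)
            )
            maps = ["face6", "face6", "face75", "face75"]
            rng.shuffle(maps)
            for qi, m in enumerate(maps):
                face_hz, house_hz = (6.0, 7.5) if m == "face6" else (7.5, 6.0)
                qrows.append(
                    dict(participant=pid, session=session, sequence=qi,
                         face_hz=face_hz, house_hz=house_hz)
                )
    return StudyDesign(pd.DataFrame(srows), pd.DataFrame(qrows))


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

@dataclass
class SequenceEvents:
    """Fixation-cross color changes of one sequence (times in s from
    sequence onset)."""

    onsets: np.ndarray
    duration: float
    change_duration: float = 0.3

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)


def schedule_color_changes(
    duration: float,
    n_changes: int,
    min_gap: float,
    seed: int | np.random.Generator,
    change_duration: float = 0.3,
) -> SequenceEvents:
    """``n_changes`` onsets in [0, duration - change_duration] with pairwise
    gaps >= ``min_gap``, uniformly distributed subject to the constraints."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_changes < 0:
        raise ValueError("n_changes must be >= 0")
    if n_changes == 0:
        return SequenceEvents(np.empty(0), duration, change_duration)
    if n_changes * min_gap >= duration:
        raise ValueError(
            f"cannot place {n_changes} changes with gap {min_gap} s in {duration} s"
        )
    slack = (duration - change_duration) - (n_changes - 1) * min_gap
    if slack <= 0:
        raise ValueError(
            f"cannot place {n_changes} changes with gap {min_gap} s in {duration} s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n_changes))
    onsets = u + min_gap * np.arange(n_changes)
    return SequenceEvents(onsets, duration, change_duration)


# --------------------------------------------------------------------------
# participant model
# --------------------------------------------------------------------------

@dataclass
class ParticipantProfile:
    """Stable per-participant generative parameters.

    ``face_amp``/``house_amp`` are baseline summed response amplitudes
    (µV, per ROI) already including the session-stable participant random
    effect; drawing that effect once and reusing it in both sessions is what
    induces the test-retest correlation.
    """

    participant: int
    face_amp: dict = field(default_factory=dict)  # ROI -> µV (summed)
    house_amp: dict = field(default_factory=dict)
    harmonic_decay: float = 0.5
    n_harmonics: int = 2
    blink_rate: float = 0.09  # blinks/s
    noise_scale: float = 10.0  # µV
    hit_p: float = 0.945
    rt_shift: float = 0.1
    rt_median: float = 0.31
    rt_sigma: float = 0.25
    random_effect: float = 0.0  # µV, the session-stable shift
    #: response phase per (stimulus, rate, harmonic): the steady-state
    #: response is locked to the stimulation, so its phase reproduces
    #: across sequences and sessions (time-domain averaging adds the
    #: signal coherently while out-of-phase noise cancels)
    phases: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.blink_rate < 0:
            raise ValueError("blink rate must be >= 0")
        if not 0 <= self.hit_p <= 1:
            raise ValueError("hit probability must be in [0, 1]")
        for d in (self.face_amp, self.house_amp):
            for v in d.values():
                if v < 0:
                    raise ValueError("amplitudes must be >= 0")


def draw_profile(
    participant: int, config: SimulationConfig, rng: np.random.Generator
) -> ParticipantProfile:
    """Sample a participant from the population model of ``config``."""
    u = rng.normal(0.0, config.between_sd)
    amps = {"face": {}, "house": {}}
    for (stim, roi), mu in config.cell_means.items():
        amps[stim][roi] = max(mu + u, 0.05)
    phases = {
        (stim, rate, k): rng.uniform(0, 2 * np.pi)
        for stim in STIMULI
        for rate in config.face_house_rates
        for k in range(1, config.n_harmonics + 1)
    }
    return ParticipantProfile(
        participant=participant,
        face_amp=amps["face"],
        house_amp=amps["house"],
        harmonic_decay=config.harmonic_decay,
        n_harmonics=config.n_harmonics,
        blink_rate=max(rng.normal(config.blink_rate_mean, config.blink_rate_sd), 0.0),
        noise_scale=config.noise_scale,
        hit_p=float(np.clip(rng.normal(config.hit_p_mean, config.hit_p_sd), 0.0, 1.0)),
        rt_shift=config.rt_shift,
        rt_median=max(rng.normal(config.rt_median, config.rt_median_sd), 0.05),
        rt_sigma=config.rt_sigma,
        random_effect=u,
        phases=phases,
    )


def session_amplitudes(
    profile: ParticipantProfile,
    config: SimulationConfig,
    treatment: str,
    rng: np.random.Generator,
) -> dict:
    """Per-session summed-amplitude targets {(stim, roi): µV}: the
    participant's baseline plus the treatment effect (under OT) plus a
    session-level disturbance shared by all responses of the session."""
    v = rng.normal(0.0, config.within_sd)
    delta = {
        "face": config.treatment_effect_face if treatment == "OT" else 0.0,
        "house": config.treatment_effect_house if treatment == "OT" else 0.0,
    }
    out = {}
    for stim, amp_map in (("face", profile.face_amp), ("house", profile.house_amp)):
        for roi, a in amp_map.items():
            out[(stim, roi)] = max(a + delta[stim] + v, 0.05)
    return out


# --------------------------------------------------------------------------
# topography and nuisance components
# --------------------------------------------------------------------------

def channel_amplitude_map(
    roi_amps: dict, falloff: float = 0.35
) -> np.ndarray:
    """Signed fundamental-amplitude map over the 64 scalp channels.

    ROI member channels carry exactly their ROI's amplitude; other channels
    get a Gaussian spatial falloff, then a constant is removed from the
    non-ROI channels so the map sums to zero over the scalp (a dipolar
    topography: common-average re-referencing is then exact on the signal).
    """
    chans = scalp_channels()
    pos = unit_sphere_positions()
    amp = np.zeros(len(chans))
    member = np.zeros(len(chans), dtype=bool)
    for roi, a in roi_amps.items():
        cent = roi_centroid(roi)
        d = np.array([np.linalg.norm(pos[ch] - cent) for ch in chans])
        amp = np.maximum(amp, a * np.exp(-(d**2) / (2 * falloff**2)))
        for ch in ROIS[roi]:
            member[chans.index(ch)] = True
    for roi, a in roi_amps.items():
        for ch in ROIS[roi]:
            amp[chans.index(ch)] = a
    shift = amp.sum() / (~member).sum()
    amp[~member] -= shift
    return amp


def pink_noise(
    shape: tuple[int, ...],
    rng: np.random.Generator,
    exponent: float = 1.0,
    sfreq: float = 512.0,
) -> np.ndarray:
    """1/f^exponent noise, unit standard deviation, last axis = time."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def blink_kernel(sfreq: float, duration: float = 0.4) -> np.ndarray:
    """Biphasic blink waveform, peak-normalized to 1."""
    t = np.arange(int(round(duration * sfreq))) / sfreq
    k = np.exp(-(((t - 0.12) / 0.05) ** 2)) - 0.35 * np.exp(-(((t - 0.26) / 0.09) ** 2))
    return k / np.abs(k).max()


def _frontal_weights() -> np.ndarray:
    """Scalp projection of a blink: strongest at the most anterior sites."""
    pos = unit_sphere_positions()
    y = np.array([pos[ch][1] for ch in scalp_channels()])
    w = np.clip(y, 0.0, None) ** 2
    return w / w.max()


def _posterior_weights() -> np.ndarray:
    cent = roi_centroid("MO")
    pos = unit_sphere_positions()
    d = np.array([np.linalg.norm(pos[ch] - cent) for ch in scalp_channels()])
    return np.exp(-(d**2) / (2 * 0.5**2))


def _add_artifacts(
    data: np.ndarray,
    config: SimulationConfig,
    profile: ParticipantProfile,
    rng: np.random.Generator,
) -> None:
    """Add pink noise, alpha bursts and blinks in place. ``data`` is
    (68, n_samples) with scalp channels first."""
    n_ch, n = data.shape
    sfreq = config.sfreq
    dur = n / sfreq
    if profile.noise_scale > 0:
        data += profile.noise_scale * pink_noise(
            (n_ch, n), rng, config.pink_exponent, sfreq
        )
    # alpha bursts on posterior channels
    if config.alpha_burst_amp > 0 and config.alpha_burst_rate > 0:
        w = _posterior_weights()
        burst_len = int(round(1.0 * sfreq))
        env = np.hanning(burst_len)
        for t0 in rng.uniform(0, dur - 1.0, size=rng.poisson(config.alpha_burst_rate * dur)):
            i0 = int(round(t0 * sfreq))
            tt = np.arange(burst_len) / sfreq
            osc = env * np.sin(2 * np.pi * config.alpha_freq * tt + rng.uniform(0, 2 * np.pi))
            data[: len(w), i0 : i0 + burst_len] += config.alpha_burst_amp * np.outer(w, osc)
    # blinks
    if profile.blink_rate > 0:
        kern = blink_kernel(sfreq, config.blink_duration)
        wf = _frontal_weights()
        iexg = {lab: len(scalp_channels()) + i for i, lab in enumerate(OCULAR)}
        n_blinks = rng.poisson(profile.blink_rate * dur)
        for t0 in rng.uniform(0, dur - config.blink_duration, size=n_blinks):
            i0 = int(round(t0 * sfreq))
            seg = slice(i0, i0 + len(kern))
            a = config.blink_amp_veog
            data[iexg["EXG3"], seg] += 0.75 * a * kern
            data[iexg["EXG4"], seg] -= 0.25 * a * kern
            data[iexg["EXG1"], seg] += 0.15 * a * kern
            data[iexg["EXG2"], seg] += 0.15 * a * kern
            data[: len(wf), seg] += config.blink_amp_scalp * np.outer(wf, kern)


def _inject_stream(
    data: np.ndarray,
    onset_idx: int,
    duration: float,
    sfreq: float,
    amp_map: np.ndarray,
    freq: float,
    decay: float,
    n_harmonics: int,
    phases: dict | None,
    stimulus: str,
    rng: np.random.Generator,
) -> None:
    """Add one tagged stream (harmonic stack) to the scalp rows in place."""
    n_sig = int(round(duration * sfreq))
    t = np.arange(n_sig) / sfreq
    sig = np.zeros(n_sig)
    for k in range(1, n_harmonics + 1):
        phi = (phases or {}).get((stimulus, freq, k))
        if phi is None:
            phi = rng.uniform(0, 2 * np.pi)
        sig += decay ** (k - 1) * np.sin(2 * np.pi * k * freq * t + phi)
    # sig is the unit-amplitude harmonic stack; the map scales it per channel
    data[: len(amp_map), onset_idx : onset_idx + n_sig] += np.outer(amp_map, sig)


def simulate_sequence(
    profile: ParticipantProfile,
    rate_map: dict,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
    amps: dict | None = None,
    treatment: str = "PL",
) -> Recording:
    """One stimulation sequence as a raw recording.

    ``rate_map`` assigns {"face", "house"} to {6, 7.5} Hz bijectively. The
    recording spans ``pre_pad`` s before and ``post_pad`` s after the
    stimulation window and carries a sequence-onset marker.
    """
    config = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if set(rate_map) != {"face", "house"} or set(rate_map.values()) != set(
        config.face_house_rates
    ):
        raise ValueError(f"rate_map must assign face/house to {config.face_house_rates}")
    duration = duration if duration is not None else config.sequence_duration
    sfreq = config.sfreq
    n = int(round((config.pre_pad + duration + config.post_pad) * sfreq))
    data = np.zeros((len(all_channels()), n))
    onset_idx = int(round(config.pre_pad * sfreq))
    if amps is None:
        amps = {
            ("face", roi): a for roi, a in profile.face_amp.items()
        } | {("house", roi): a for roi, a in profile.house_amp.items()}
    denom = sum(profile.harmonic_decay ** k for k in range(profile.n_harmonics))
    for stim in STIMULI:
        roi_amps = {roi: amps[(stim, roi)] / denom for roi in ROIS}
        amp_map = channel_amplitude_map(roi_amps, config.topography_falloff)
        _inject_stream(
            data, onset_idx, duration, sfreq, amp_map, rate_map[stim],
            profile.harmonic_decay, profile.n_harmonics, profile.phases, stim, rng,
        )
    _add_artifacts(data, config, profile, rng)
    return Recording(
        data=data,
        sfreq=sfreq,
        ch_names=list(all_channels()),
        events=[(config.pre_pad, "sequence:0")],
        meta=dict(participant=profile.participant, treatment=treatment, rate_map=dict(rate_map)),
    )


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def simulate_behavior(
    events: SequenceEvents,
    profile: ParticipantProfile,
    seed: int | np.random.Generator,
    false_alarm_rate: float = 0.01,
) -> np.ndarray:
    """Key-press times (s from sequence onset) for one sequence.

    Each color change elicits a press with probability ``hit_p`` at
    onset + RT, RT ~ shift + lognormal, constrained to [0.1, 2.0] s; false
    alarms arrive as a Poisson process at ``false_alarm_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    presses = []
    for onset in events.onsets:
        if rng.uniform() < profile.hit_p:
            rt = profile.rt_shift + rng.lognormal(np.log(profile.rt_median), profile.rt_sigma)
            rt = float(np.clip(rt, 0.1, 2.0))
            presses.append(onset + rt)
    n_fa = rng.poisson(false_alarm_rate * events.duration)
    presses.extend(rng.uniform(0, events.duration, size=n_fa))
    return np.sort(np.asarray(presses, dtype=float))


# --------------------------------------------------------------------------
# whole studies
# --------------------------------------------------------------------------

@dataclass
class StudyData:
    """A simulated study: design, per-session recordings (in memory or on
    disk), color-change events and key presses (times relative to sequence
    onset), and the generative profiles (kept for verification)."""

    design: StudyDesign
    config: SimulationConfig
    recordings: dict  # (participant, session) -> Recording | Path
    events: pd.DataFrame
    presses: pd.DataFrame
    profiles: dict

    def get_recording(self, participant: int, session: int) -> Recording:
        rec = self.recordings[(participant, session)]
        if isinstance(rec, (str, Path)):
            from .io import read_recording

            rec = read_recording(rec)
        return rec

    def sequence_events(self, participant: int, session: int, sequence: int) -> SequenceEvents:
        e = self.events
        m = e[(e.participant == participant) & (e.session == session) & (e.sequence == sequence)]
        return SequenceEvents(
            m["onset_s"].to_numpy(), self.config.sequence_duration, self.config.change_duration
        )


def simulate_session(
    profile: ParticipantProfile,
    seq_design: pd.DataFrame,
    config: SimulationConfig,
    treatment: str,
    rng: np.random.Generator,
) -> tuple[Recording, list[SequenceEvents], list[np.ndarray]]:
    """One session: a continuous recording holding the 4 sequences, plus the
    color-change events and key presses of each sequence."""
    sfreq = config.sfreq
    spacing = config.sequence_duration + config.inter_sequence_gap
    total = config.pre_pad + len(seq_design) * spacing - config.inter_sequence_gap + config.post_pad
    n = int(round(total * sfreq))
    data = np.zeros((len(all_channels()), n))
    amps = session_amplitudes(profile, config, treatment, rng)
    denom = sum(profile.harmonic_decay ** k for k in range(profile.n_harmonics))
    events_out, presses_out, markers = [], [], []
    for i, row in enumerate(seq_design.itertuples()):
        onset = config.pre_pad + i * spacing
        onset_idx = int(round(onset * sfreq))
        markers.append((onset, f"sequence:{int(row.sequence)}"))
        rate_map = {"face": float(row.face_hz), "house": float(row.house_hz)}
        for stim in STIMULI:
            roi_amps = {roi: amps[(stim, roi)] / denom for roi in ROIS}
            amp_map = channel_amplitude_map(roi_amps, config.topography_falloff)
            _inject_stream(
                data, onset_idx, config.sequence_duration, sfreq, amp_map,
                rate_map[stim], profile.harmonic_decay, profile.n_harmonics,
                profile.phases, stim, rng,
            )
        ev = schedule_color_changes(
            config.sequence_duration, config.n_color_changes, config.min_change_gap,
            rng, config.change_duration,
        )
        events_out.append(ev)
        presses_out.append(simulate_behavior(ev, profile, rng, config.false_alarm_rate))
    _add_artifacts(data, config, profile, rng)
    rec = Recording(
        data=data, sfreq=sfreq, ch_names=list(all_channels()), events=markers,
        meta=dict(participant=profile.participant, treatment=treatment),
    )
    return rec, events_out, presses_out


def simulate_study(
    config: SimulationConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> StudyData:
    """Simulate a complete study, reproducibly from ``seed``.

    With ``out_dir`` set, recordings are written to disk session by session
    (float32 arrays with JSON sidecars) and only their paths kept in memory;
    otherwise everything stays in memory (intended for small n).
    """
    ss = np.random.SeedSequence(seed)
    design_ss, *participant_ss = ss.spawn(config.n_participants + 1)
    design = make_design(config.n_participants, np.random.default_rng(design_ss).integers(2**31))

    if out_dir is not None:
        from .io import write_study_tables, write_recording

        out_dir = Path(out_dir)
        (out_dir / "recordings").mkdir(parents=True, exist_ok=True)

    recordings, profiles = {}, {}
    erows, prows = [], []
    for pid, pss in zip(range(1, config.n_participants + 1), participant_ss):
        prof_ss, *sess_ss = pss.spawn(3)
        profile = draw_profile(pid, config, np.random.default_rng(prof_ss))
        profiles[pid] = profile
        for session, sss in zip((1, 2), sess_ss):
            rng = np.random.default_rng(sss)
            treatment = design.treatment_of(pid, session)
            seq_design = design.sequences[
                (design.sequences.participant == pid) & (design.sequences.session == session)
            ].sort_values("sequence")
            rec, evs, prs = simulate_session(profile, seq_design, config, treatment, rng)
            for qi, (ev, pr) in enumerate(zip(evs, prs)):
                for t in ev.onsets:
                    erows.append(dict(participant=pid, session=session, sequence=qi, onset_s=t))
                for t in pr:
                    prows.append(dict(participant=pid, session=session, sequence=qi, time_s=t))
            if out_dir is not None:
                path = out_dir / "recordings" / f"sub-{pid:02d}_ses-{session}.npy"
                write_recording(path, rec)
                recordings[(pid, session)] = path
            else:
                recordings[(pid, session)] = rec
    events = pd.DataFrame(erows, columns=["participant", "session", "sequence", "onset_s"])
    presses = pd.DataFrame(prows, columns=["participant", "session", "sequence", "time_s"])
    study = StudyData(design, config, recordings, events, presses, profiles)
    if out_dir is not None:
        write_study_tables(out_dir, study)
    return study


# --------------------------------------------------------------------------
# fast amplitude-level path
# --------------------------------------------------------------------------

def analytic_retest_r(config: SimulationConfig) -> float:
    """Between-session correlation of per-stimulus session means implied by
    the variance components (participant / session / row; 6 rows per mean)."""
    sb2 = config.between_sd**2
    return sb2 / (sb2 + config.within_sd**2 + config.row_sd**2 / 6.0)


def simulate_response_table(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Draw the measured summed responses directly from the generative model.

    Produces the long-format quantification table (2 treatments x 2 stimulus
    types x 2 rates x 3 ROIs per participant -> 24 rows each, 744 for n=31)
    without rendering waveforms. The ``z`` column is the generative proxy
    amp / z_noise_sd (the bin-noise scale of the measurement model).
    """
    ss = np.random.SeedSequence(seed)
    design_ss, table_ss = ss.spawn(2)
    design = make_design(config.n_participants, np.random.default_rng(design_ss).integers(2**31))
    rng = np.random.default_rng(table_ss)
    delta = {"face": config.treatment_effect_face, "house": config.treatment_effect_house}
    rows = []
    for pid in range(1, config.n_participants + 1):
        u = rng.normal(0.0, config.between_sd)
        for session in (1, 2):
            treatment = design.treatment_of(pid, session)
            order = design.sessions[design.sessions.participant == pid]["session_order"].iloc[0]
            v = rng.normal(0.0, config.within_sd)
            for stim in STIMULI:
                d = delta[stim] if treatment == "OT" else 0.0
                for rate in config.face_house_rates:
                    for roi in ROIS:
                        amp = (
                            config.cell_means[(stim, roi)] + u + v + d
                            + rng.normal(0.0, config.row_sd)
                        )
                        rows.append(
                            dict(
                                participant=pid, session=session, session_order=order,
                                treatment=treatment, stimulus=stim, rate_hz=rate,
                                roi=roi, amp_uv=amp, z=amp / config.z_noise_sd,
                            )
                        )
    return pd.DataFrame(rows)
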