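"""Preprocessing: raw recordings to clean re-referenced 68-s epochs.

Fixed pipeline order: crop -> bandpass filter -> resample -> blink ICA (for
flagged participants) -> channel interpolation -> common-average reference.
Filtering is zero-phase (forward-backward Butterworth): the analysis lives
in amplitude spectra, which must not be confounded by group delay.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal

from .containers import Epoch, Recording
from .montage import OCULAR, VEOG_PAIR, interpolation_cap, nearest_neighbors, scalp_channels

logger = logging.getLogger(__name__)

EPOCH_PRE = 2.0  # s before sequence onset
EPOCH_POST = 66.0  # s after sequence onset (60 s stimulation + 6 s)


def segment(recording: Recording, info: dict | None = None) -> list[Epoch]:
    """Cut one 68-s epoch per sequence-onset marker: [onset-2 s, onset+66 s)."""
    epochs = []
    onsets = [(t, lab) for t, lab in recording.events if lab.startswith("sequence")]
    if not onsets:
        raise ValueError("recording has no sequence-onset markers")
    for t, lab in onsets:
        i0 = int(round((t - EPOCH_PRE) * recording.sfreq))
        i1 = i0 + int(round((EPOCH_PRE + EPOCH_POST) * recording.sfreq))
        if i0 < 0 or i1 > recording.n_samples:
            raise ValueError(
                f"sequence {lab!r} at {t:.2f} s lacks {EPOCH_PRE:.0f} s pre / "
                f"{EPOCH_POST:.0f} s post padding"
            )
        ep_info = dict(recording.meta)
        if info:
            ep_info.update(info)
        ep_info["sequence"] = int(lab.split(":")[1]) if ":" in lab else None
        epochs.append(
            Epoch(
                data=recording.data[:, i0:i1].copy(),
                sfreq=recording.sfreq,
                ch_names=list(recording.ch_names),
                info=ep_info,
                provenance=[f"segment[{t - EPOCH_PRE:.3f},{t + EPOCH_POST:.3f})"],
            )
        )
    return epochs


def bandpass(epoch: Epoch, low: float = 0.1, high: float = 100.0, order: int = 4) -> Epoch:
    """Zero-phase Butterworth bandpass of the given order."""
    nyq = epoch.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) at sfreq {epoch.sfreq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epoch.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, epoch.data, axis=-1)
    return epoch.copy_with(out, note=f"bandpass({low},{high},order={order},zero-phase)")


def butter_bandpass_gain(freqs, low: float, high: float, order: int, zero_phase: bool = True):
    """Analytic magnitude response |H(f)| of the applied filter (squared for
    forward-backward application). Serves as the oracle for filter tests."""
    # analog prototype with rad/s band edges
    b, a = signal.butter(
        order, [2 * np.pi * low, 2 * np.pi * high], btype="bandpass", analog=True, output="ba"
    )
    _, h = signal.freqs(b, a, worN=2 * np.pi * np.asarray(freqs, dtype=float))
    mag = np.abs(h)
    return mag**2 if zero_phase else mag


def resample(epoch: Epoch, target: float = 256.0) -> Epoch:
    """Anti-aliased decimation to ``target`` Hz (must divide the rate)."""
    ratio = epoch.sfreq / target
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(f"target {target} Hz must divide sampling rate {epoch.sfreq} Hz")
    q = int(round(ratio))
    if q == 1:
        return epoch.copy_with(epoch.data.copy(), note="resample(noop)")
    out = signal.resample_poly(epoch.data, up=1, down=q, axis=-1)
    ep = epoch.copy_with(out, note=f"resample({epoch.sfreq}->{target})")
    ep.sfreq = target
    return ep


def detect_blinks(
    veog: np.ndarray,
    sfreq: float,
    mad_threshold: float = 4.0,
    refractory: float = 0.2,
) -> np.ndarray:
    """Blink event indices on a vertical-ocular difference signal.

    Threshold crossings of the robust z (scaled-MAD) of the signal, with a
    refractory period so one blink is counted once.
    """
    med = np.median(veog)
    mad = np.median(np.abs(veog - med)) * 1.4826
    if mad == 0:
        # degenerate (noise-free) signal: fall back to the mean absolute
        # deviation so isolated transients remain detectable
        mad = np.mean(np.abs(veog - med))
    if mad == 0:
        return np.empty(0, dtype=int)
    above = (veog - med) / mad > mad_threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return idx
    keep = [idx[0]]
    gap = int(round(refractory * sfreq))
    for i in idx[1:]:
        if i - keep[-1] > gap:
            keep.append(i)
    return np.asarray(keep)


def blink_rate(
    recording: Recording | Epoch,
    mad_threshold: float = 4.0,
    refractory: float = 0.2,
) -> float:
    """Blinks per second from the vertical ocular pair (above - below eye)."""
    for ch in VEOG_PAIR:
        if ch not in recording.ch_names:
            raise ValueError(f"vertical ocular channel {ch!r} missing")
    veog = recording.channel(VEOG_PAIR[0]) - recording.channel(VEOG_PAIR[1])
    events = detect_blinks(veog, recording.sfreq, mad_threshold, refractory)
    return len(events) / (recording.data.shape[1] / recording.sfreq)


def flag_blink_participants(rates: dict, n_sd: float = 1.5) -> set:
    """Participants whose blink rate exceeds mean + n_sd * SD across
    participants (population SD)."""
    vals = np.array(list(rates.values()), dtype=float)
    if vals.size == 0:
        return set()
    thresh = vals.mean() + n_sd * vals.std()
    return {k for k, v in rates.items() if v > thresh}


def remove_blink_component(
    epochs: list[Epoch], seed: int = 0
) -> list[Epoch]:
    """Remove the single highest-variance independent component.

    Infomax ICA (the runica family) is run on the participant's concatenated
    scalp data; the component whose back-projection explains the most
    variance — the blink component when the participant blinks a lot — is
    subtracted, reducing the data rank by exactly one. Ocular channels are
    left untouched. On decomposition failure the epochs pass through
    unmodified with a warning.
    """
    from mne.preprocessing import infomax

    scalp = [ch for ch in epochs[0].ch_names if ch not in OCULAR]
    sel = [epochs[0].ch_names.index(ch) for ch in scalp]
    X = np.concatenate([ep.data[sel] for ep in epochs], axis=1)  # (n_scalp, n)
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    try:
        # PCA whitening, then infomax in whitened space
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if np.any(s[:-1] <= 1e-12 * s.max()):
            raise np.linalg.LinAlgError("rank-deficient data")
        white = (U / s[None, :]).T @ Xc * np.sqrt(Xc.shape[1])  # unit-variance comps
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = infomax(white.T, extended=True, rng=seed, verbose="error")
        sources = W @ white
        # mixing back to sensor space: X ≈ A @ sources
        A = Xc @ np.linalg.pinv(sources)
        var = np.array([np.var(np.outer(A[:, k], sources[k])) for k in range(A.shape[1])])
        worst = int(np.argmax(var))
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("ICA failed (%s); epochs passed through unmodified", exc)
        warnings.warn(f"ICA decomposition failed: {exc}; epochs unmodified", stacklevel=2)
        return epochs
    removal = np.outer(A[:, worst], sources[worst])
    out = []
    i0 = 0
    for ep in epochs:
        n = ep.n_samples
        cleaned = ep.data.copy()
        cleaned[sel] = cleaned[sel] - removal[:, i0 : i0 + n]
        i0 += n
        out.append(ep.copy_with(cleaned, note=f"ica-removed-component[{worst}]"))
    return out


def interpolate_channels(epoch: Epoch, bad: list[str]) -> Epoch:
    """Replace each bad scalp channel by the inverse-distance-weighted mean
    of its three spatially nearest good scalp electrodes.

    At most 5% of the 64 scalp electrodes (= 3) may be interpolated.
    """
    cap = interpolation_cap()
    if len(bad) > cap:
        raise ValueError(f"{len(bad)} bad channels exceeds the cap of {cap}")
    for ch in bad:
        if ch not in scalp_channels():
            raise ValueError(f"bad channel {ch!r} not in the scalp montage")
    if not bad:
        return epoch
    data = epoch.data.copy()
    for ch in bad:
        neigh = nearest_neighbors(ch, k=3, exclude=tuple(b for b in bad if b != ch))
        w = np.array([1.0 / max(d, 1e-12) for _, d in neigh])
        w /= w.sum()
        rows = [epoch.ch_names.index(nm) for nm, _ in neigh]
        data[epoch.ch_names.index(ch)] = w @ epoch.data[rows]
    ep = epoch.copy_with(data, note=f"interpolated{sorted(bad)}")
    ep.bad_channels = sorted(set(epoch.bad_channels) | set(bad))
    return ep


def rereference_average(epoch: Epoch) -> Epoch:
    """Common average reference over the 64 scalp channels (ocular channels
    are excluded from the average but shifted by it too, keeping bipolar
    ocular derivations unchanged)."""
    sel = [i for i, ch in enumerate(epoch.ch_names) if ch not in OCULAR]
    mean = epoch.data[sel].mean(axis=0, keepdims=True)
    data = epoch.data - mean
    return epoch.copy_with(data, note="rereference(common-average)")


def preprocess_epochs(
    epochs: list[Epoch],
    band: tuple[float, float] = (0.1, 100.0),
    order: int = 4,
    resample_to: float = 256.0,
    apply_ica: bool = False,
    bad_channels: list[str] | None = None,
    seed: int = 0,
) -> list[Epoch]:
    """The fixed per-participant chain after segmentation."""
    out = [resample(bandpass(ep, *band, order=order), resample_to) for ep in epochs]
    if apply_ica:
        out = remove_blink_component(out, seed=seed)
    if bad_channels:
        out = [interpolate_channels(ep, bad_channels) for ep in out]
    return [rereference_average(ep) for ep in out]


def preprocess_study(study, config=None) -> tuple[list[Epoch], dict]:
    """Run the whole preprocessing chain over a simulated/loaded study.

    Returns the cleaned epochs and a log dict (blink rates, flagged
    participants, interpolated channels).
    """
    from .config import PreprocessConfig

    config = config or PreprocessConfig()
    pids = sorted(study.design.sessions["participant"].unique())
    rates = {}
    for pid in pids:
        rs = [
            blink_rate(study.get_recording(pid, s), config.blink_mad_threshold,
                       config.blink_refractory)
            for s in (1, 2)
        ]
        rates[pid] = float(np.mean(rs))
    flagged = flag_blink_participants(rates, config.blink_flag_sd)
    all_epochs: list[Epoch] = []
    for pid in pids:
        per_participant: list[Epoch] = []
        for session in (1, 2):
            rec = study.get_recording(pid, session)
            seq = study.design.sequences
            m = seq[(seq.participant == pid) & (seq.session == session)].set_index("sequence")
            eps = segment(
                rec,
                info=dict(
                    participant=pid, session=session,
                    treatment=study.design.treatment_of(pid, session),
                ),
            )
            for ep in eps:
                qi = ep.info["sequence"]
                ep.info["face_hz"] = float(m.loc[qi, "face_hz"])
                ep.info["house_hz"] = float(m.loc[qi, "house_hz"])
                ep.info["session_order"] = str(
                    study.design.sessions[
                        study.design.sessions.participant == pid
                    ]["session_order"].iloc[0]
                )
            per_participant.extend(eps)
        bads = list(config.bad_channels.get(pid, []))
        per_participant = preprocess_epochs(
            per_participant, band=config.band, order=config.filter_order,
            resample_to=config.resample_to, apply_ica=pid in flagged,
            bad_channels=bads, seed=pid,
        )
        all_epochs.extend(per_participant)
    log = dict(
        blink_rates=rates,
        flagged_participants=sorted(flagged),
        n_epochs=len(all_epochs),
        interpolated={p: list(b) for p, b in config.bad_channels.items()},
    )
    return all_epochs, log
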