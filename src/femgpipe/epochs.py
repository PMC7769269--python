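"""Event-locked epoching and reduction of envelope signals.

The processing chain (in the order it is meant to run):

1. :func:`extract_epochs` — cut one epoch per stimulus onset covering
   [onset - baseline, onset + response) ms; trials too close to a
   recording edge are flagged unusable, never silently dropped.
2. :func:`baseline_correct` — subtract each trial/channel's mean over the
   pre-stimulus baseline window.
3. :func:`reject_epochs` — 3-SD sliding-window artifact rejection,
   channels treated independently.
4. :func:`smooth_moving_average` — centered 250 ms moving average.
5. :func:`average_by_condition` — mean time course per channel x emotion
   over accepted trials.
6. :func:`bin_time_course` — 250 ms bin means over the response window,
   yielding the ANOVA input (:func:`binned_response`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .types import EMOTIONS, MUSCLES, PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Trials x channels x time array of envelope amplitudes (µV).

    ``times_ms`` runs from -baseline to +response-1 relative to stimulus
    onset. ``usable`` flags trials fully inside the recording; ``accepted``
    flags (trial, channel) pairs that survived artifact rejection (channels
    are rejected independently). Unusable trials are neither accepted nor
    rejected — they are reported separately so that
    accepted + rejected + unusable equals the number of events.
    """

    data: np.ndarray          # (n_trials, n_channels, n_times)
    times_ms: np.ndarray      # (n_times,)
    events: pd.DataFrame      # one row per trial (emotion, identity, ...)
    usable: np.ndarray        # (n_trials,) bool
    accepted: np.ndarray      # (n_trials, n_channels) bool
    baseline_corrected: bool = False

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def baseline_mask(self) -> np.ndarray:
        return self.times_ms < 0


def extract_epochs(
    envelopes: np.ndarray,
    events: pd.DataFrame,
    fs: float = 1000.0,
    baseline_ms: int = 2000,
    response_ms: int = 1500,
) -> EpochSet:
    """Cut per-trial epochs from continuous channel envelopes.

    ``envelopes`` is (n_channels, n_samples); epoch k covers samples
    [onset_k - baseline, onset_k + response). Onsets without enough
    history or future are flagged unusable (their data is NaN).
    """
    envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
    n_ch, n_samp = envelopes.shape
    onsets = np.round(events["onset_ms"].to_numpy() * fs / 1000.0).astype(int)
    n_b = int(round(baseline_ms * fs / 1000.0))
    n_r = int(round(response_ms * fs / 1000.0))
    n_t = n_b + n_r
    data = np.full((len(onsets), n_ch, n_t), np.nan)
    usable = (onsets - n_b >= 0) & (onsets + n_r <= n_samp)
    for k, onset in enumerate(onsets):
        if usable[k]:
            data[k] = envelopes[:, onset - n_b:onset + n_r]
    if not usable.all():
        log.warning("%d trial(s) too close to recording edge flagged unusable",
                    int((~usable).sum()))
    times = np.arange(-n_b, n_r) * 1000.0 / fs
    accepted = np.repeat(usable[:, None], n_ch, axis=1)
    return EpochSet(data=data, times_ms=times, events=events.reset_index(drop=True),
                    usable=usable, accepted=accepted)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus window.

    After correction the baseline-window mean is exactly zero for every
    usable trial.
    """
    mask = epochs.baseline_mask()
    if not mask.any():
        raise ValueError("epoch time axis contains no pre-stimulus samples")
    data = epochs.data.copy()
    ok = epochs.usable
    base = data[ok][:, :, mask].mean(axis=2, keepdims=True)
    data[ok] = data[ok] - base
    return replace(epochs, data=data, baseline_corrected=True)


def _window_means(data: np.ndarray, win: int, step: int) -> np.ndarray:
    """Sliding-window means along the last axis: (..., n_windows)."""
    n_t = data.shape[-1]
    starts = np.arange(0, n_t - win + 1, step)
    csum = np.cumsum(np.concatenate([np.zeros(data.shape[:-1] + (1,)), data], axis=-1), axis=-1)
    return (csum[..., starts + win] - csum[..., starts]) / win


def reject_epochs(
    epochs: EpochSet,
    sd_mult: float = 3.0,
    window_ms: int = 250,
    step_ms: int = 50,
    fs: float = 1000.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Sliding-window amplitude-based artifact rejection.

    Per channel, mean amplitudes are computed in windows of ``window_ms``
    advanced by ``step_ms`` across every usable epoch; all window values
    of a channel are pooled, and an epoch is rejected on that channel if
    any of its windows deviates from the pooled mean by more than
    ``sd_mult`` pooled standard deviations. Channels are independent: a
    rejection in one channel does not remove the trial from the other.

    Returns the epoch set with updated ``accepted`` flags and a report
    with one row per channel (n_rejected, n_total, rejection_rate).
    """
    win = int(round(window_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    if win > epochs.data.shape[-1]:
        raise ValueError("rejection window longer than epoch")
    if epochs.usable.sum() < 2:
        raise ValueError("need at least 2 usable epochs for rejection")
    accepted = epochs.accepted.copy()
    rows = []
    for ch in range(epochs.n_channels):
        idx = np.flatnonzero(epochs.usable)
        wm = _window_means(epochs.data[idx, ch, :], win, step)  # (n_usable, n_win)
        mu, sd = wm.mean(), wm.std(ddof=0)
        if sd <= 1e-12 * max(1.0, abs(mu)):  # degenerate: identical epochs
            log.warning("channel %s: pooled window SD is zero; no rejections",
                        MUSCLES[ch] if ch < len(MUSCLES) else ch)
            bad = np.zeros(len(idx), dtype=bool)
        else:
            bad = (np.abs(wm - mu) > sd_mult * sd).any(axis=1)
        accepted[idx, ch] = ~bad
        rows.append({
            "channel": MUSCLES[ch] if ch < len(MUSCLES) else str(ch),
            "n_rejected": int(bad.sum()),
            "n_total": int(len(idx)),
            "rejection_rate": float(bad.mean()) if len(idx) else 0.0,
        })
    report = pd.DataFrame(rows)
    log.info("rejection: %s", ", ".join(f"{r['channel']} {r['n_rejected']}/{r['n_total']}"
                                        for r in rows))
    return replace(epochs, accepted=accepted), report


def smooth_moving_average(epochs: EpochSet, window_ms: int = 250, fs: float = 1000.0) -> EpochSet:
    """Centered moving average along time, length-preserving.

    The window is forced to an odd sample count (250 ms at 1000 Hz ->
    251 samples) so the average is exactly centered; edges use symmetric
    (reflection) padding.
    """
    win = int(round(window_ms * fs / 1000.0))
    if win % 2 == 0:
        win += 1
    if win > epochs.data.shape[-1]:
        raise ValueError("smoothing window longer than epoch")
    data = epochs.data.copy()
    ok = epochs.usable
    data[ok] = uniform_filter1d(data[ok], size=win, axis=-1, mode="reflect")
    return replace(epochs, data=data)


def average_by_condition(epochs: EpochSet, participant: str = "?") -> np.ndarray:
    """Mean time course per channel x emotion over accepted trials.

    Returns a (n_channels, 6, n_times) array in canonical emotion order;
    emotions absent from the session are NaN. Raises if an emotion that
    was presented has no accepted trial left on some channel.
    """
    out = np.full((epochs.n_channels, len(EMOTIONS), epochs.data.shape[-1]), np.nan)
    emo_labels = epochs.events["emotion"].to_numpy()
    for ch in range(epochs.n_channels):
        for e, emo in enumerate(EMOTIONS):
            present = emo_labels == emo
            if not present.any():
                continue
            sel = present & epochs.accepted[:, ch]
            if not sel.any():
                raise ValueError(
                    f"participant {participant}: no accepted {emo!r} trial on channel {ch}"
                )
            out[ch, e] = epochs.data[sel, ch, :].mean(axis=0)
    return out


def bin_time_course(course: np.ndarray, bin_ms: int = 250, fs: float = 1000.0) -> np.ndarray:
    """Mean amplitude in consecutive half-open bins [b*bin, (b+1)*bin) ms.

    ``course`` holds post-onset samples along its last axis; the axis
    length must be a multiple of the bin width in samples.
    """
    nb = int(round(bin_ms * fs / 1000.0))
    n_t = course.shape[-1]
    if n_t % nb != 0:
        raise ValueError("bin width must divide the response window length")
    shaped = course.reshape(course.shape[:-1] + (n_t // nb, nb))
    return shaped.mean(axis=-1)


def binned_response(
    epochs: EpochSet,
    participant: str,
    group: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full reduction of one participant's epochs to the ANOVA input.

    Averages accepted trials per channel x emotion, restricts to the
    post-onset response window, and bins it; returns long-format rows
    (participant, group, muscle, emotion, bin, amplitude) — 2 x 6 x 6 = 72
    rows per participant with the default configuration.
    """
    cfg = config or PipelineConfig()
    course = average_by_condition(epochs, participant)
    post = course[..., epochs.times_ms >= 0]
    bins = bin_time_course(post, cfg.bin_ms)
    n_bins = bins.shape[-1]
    present = set(epochs.events["emotion"])
    rows = []
    for ch, muscle in enumerate(MUSCLES[: epochs.n_channels]):
        for e, emo in enumerate(EMOTIONS):
            if emo not in present:
                continue
            for b in range(n_bins):
                rows.append({
                    "participant": participant,
                    "group": group,
                    "muscle": muscle,
                    "emotion": emo,
                    "bin": b,
                    "amplitude": bins[ch, e, b],
                })
    return pd.DataFrame(rows)
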