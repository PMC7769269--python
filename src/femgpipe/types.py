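"""Core data containers shared across the pipeline.

Conventions used throughout the package: signal amplitudes are in
microvolts (µV), time is in milliseconds, sample indices are 0-based,
and all windows are half-open intervals ``[a, b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
import yaml

#: Canonical emotion labels, fixed order (lowercase tokens, machine-diffable).
EMOTIONS: tuple[str, ...] = ("happy", "sad", "anger", "fear", "disgust", "surprise")

#: Recorded muscles, fixed channel order.
MUSCLES: tuple[str, ...] = ("corrugator", "zygomaticus")

#: Group labels: participants with a history of non-suicidal self-injury
#: (hnssi) versus controls.
GROUPS: tuple[str, ...] = ("hnssi", "control")

#: Identities per emotion in a full stimulus set.
N_IDENTITIES = 24

#: Trials in a full session (24 identities x 6 emotions).
N_TRIALS = N_IDENTITIES * len(EMOTIONS)

#: Minimum spacing between stimulus onsets: 1.5 s stimulus + 3 s inter-trial
#: interval.
MIN_ONSET_SPACING_MS = 4500


class FormatError(ValueError):
    """A malformed input file or table (names the offending row/field)."""


@dataclass
class RawRecording:
    """A continuous two-channel facial-EMG recording.

    Channels are ordered (corrugator supercilii, zygomaticus major),
    amplitudes in µV, sampled at a fixed 1000 Hz.
    """

    participant_id: str
    group: str
    corrugator: np.ndarray
    zygomaticus: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.corrugator = np.asarray(self.corrugator, dtype=float)
        self.zygomaticus = np.asarray(self.zygomaticus, dtype=float)
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sampling_rate != 1000.0:
            raise FormatError("sampling_rate must be 1000 Hz")
        if self.corrugator.shape != self.zygomaticus.shape or self.corrugator.ndim != 1:
            raise FormatError("channels must be 1-D vectors of equal length")
        if not (np.isfinite(self.corrugator).all() and np.isfinite(self.zygomaticus).all()):
            raise FormatError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.corrugator.size

    @property
    def channels(self) -> np.ndarray:
        """Stacked (2, n_samples) array in canonical muscle order."""
        return np.stack([self.corrugator, self.zygomaticus])

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    """Validate an event table (one row per stimulus onset).

    Required columns: ``onset_ms, emotion, identity, trial_index``. Onsets
    must be strictly increasing and at least 4500 ms apart (1.5 s stimulus
    + 3 s ITI); each (emotion, identity) pair may occur at most once. When
    ``n_samples`` is given, onsets must lie inside the recording.
    """
    required = ["onset_ms", "emotion", "identity", "trial_index"]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise FormatError(f"events table missing column(s) {missing}")
    events = events[required].copy()
    for row, emo in enumerate(events["emotion"]):
        if emo not in EMOTIONS:
            raise FormatError(f"events row {row}: unknown emotion {emo!r}")
    ident = events["identity"].to_numpy()
    if ((ident < 1) | (ident > N_IDENTITIES)).any():
        row = int(np.argmax((ident < 1) | (ident > N_IDENTITIES)))
        raise FormatError(f"events row {row}: identity {ident[row]} outside 1..{N_IDENTITIES}")
    onsets = events["onset_ms"].to_numpy()
    d = np.diff(onsets)
    if (d <= 0).any():
        row = int(np.argmax(d <= 0)) + 1
        raise FormatError(f"events row {row}: onsets not strictly increasing")
    if (d < MIN_ONSET_SPACING_MS).any():
        row = int(np.argmax(d < MIN_ONSET_SPACING_MS)) + 1
        raise FormatError(
            f"events row {row}: onset spacing {d[row - 1]} ms < {MIN_ONSET_SPACING_MS} ms"
        )
    pairs = list(zip(events["emotion"], events["identity"]))
    if len(set(pairs)) != len(pairs):
        raise FormatError("duplicate (emotion, identity) pair in events table")
    if n_samples is not None:
        ms_per_sample = 1.0
        beyond = onsets >= n_samples * ms_per_sample
        if beyond.any():
            row = int(np.argmax(beyond))
            raise FormatError(
                f"events row {row}: onset {onsets[row]} ms beyond recording end"
            )
    return events


@dataclass
class PipelineConfig:
    """All tunable constants of the preprocessing and analysis chain.

    Defaults encode the published reduction settings: 30 Hz high-pass edge
    of the 30-500 Hz passband, 60 Hz notch, 2 s pre-stimulus baseline,
    1.5 s response window, 3-SD sliding-window epoch rejection advanced in
    50-ms steps, 250 ms smoothing, 250 ms analysis bins, alpha = 0.05.
    """

    highpass_hz: float = 30.0
    notch_hz: float = 60.0
    notch_q: float = 10.0
    filter_order: int = 4
    baseline_ms: int = 2000
    response_ms: int = 1500
    reject_sd: float = 3.0
    reject_window_ms: int = 250
    reject_step_ms: int = 50
    smooth_ms: int = 250
    bin_ms: int = 250
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_ms", "response_ms", "reject_window_ms",
                     "reject_step_ms", "smooth_ms", "bin_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.response_ms % self.bin_ms != 0:
            raise ValueError("bin_ms must divide response_ms")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def n_bins(self) -> int:
        return self.response_ms // self.bin_ms

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ResultsBundle:
    """Everything the analysis stage produces for one cohort.

    ``anova_tables`` maps muscle -> ANOVA table (one per muscle);
    ``contrasts`` holds the 12 planned group contrasts; ``correlations``
    the questionnaire-mimicry Pearson correlations; ``rejection`` the
    per-participant/channel artifact-rejection report; ``binned`` the
    long-format participant x muscle x emotion x bin amplitudes that fed
    the ANOVAs.
    """

    anova_tables: dict[str, pd.DataFrame]
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    rejection: pd.DataFrame
    binned: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.anova_tables) != set(MUSCLES):
            raise ValueError("expected exactly one ANOVA table per muscle")
        rate = self.rejection["rejection_rate"].to_numpy()
        if ((rate < 0) | (rate > 1)).any():
            raise ValueError("rejection rates must lie in [0, 1]")

    @property
    def rejection_rate(self) -> float:
        """Overall fraction of rejected epochs, pooled over participants
        and channels."""
        rep = self.rejection
        return float(rep["n_rejected"].sum() / rep["n_total"].sum())
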