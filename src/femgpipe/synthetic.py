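"""Synthetic fEMG cohort generator.

Emulates the study conditions the analysis assumes: 60 participants (30
with a history of self-injury, 30 controls), 144 trials each (24 stimulus
identities x 6 emotions in random order), two-channel recordings sampled
at 1000 Hz with a 20-s neutral lead-in and tail.

The generative model per channel is multiplicative amplitude modulation
of tonic surface EMG: band-limited (30-250 Hz) zero-mean Gaussian noise
carrying a slow, bounded amplitude wander (saturated sub-hertz noise
emulating nonstationary tonic muscle tone) and scaled, during
[300, 1500) ms after each stimulus onset, by a condition-specific gain g
(contraction g > 1, relaxation g < 1, raised-cosine onset). Because the downstream envelope is
baseline-corrected, relaxation gains produce negative binned amplitudes,
matching the direction convention of the analysis. 60 Hz line
interference and sparse square-pulse artifacts (8-15 x tonic SD, 100-400
ms) are added on top.

Group structure: the self-injury group's corrugator responses to anger
(contraction) and happiness (relaxation) are attenuated toward gain 1 by
a factor alpha, i.e. g_eff = 1 + (1 - alpha) * (g - 1). Questionnaire
subscale scores for that group are drawn with a configurable correlation
to each participant's realized mimicry gain.

Everything is deterministic given the seed; cohort files written by
:func:`write_cohort` are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as st

from .types import (EMOTIONS, MIN_ONSET_SPACING_MS, MUSCLES,
                    N_IDENTITIES, RawRecording, validate_events)
from . import questionnaires as q

log = logging.getLogger(__name__)

#: Default condition gains. Corrugator contracts to anger and relaxes to
#: happy faces; zygomaticus responses are near 1 (little mimicry expected
#: in this muscle). Values are modest multiplicative modulations of tonic
#: amplitude, in line with the sub-microvolt mimicry responses surface
#: fEMG typically shows on a ~10 µV tonic background.
DEFAULT_GAINS: dict[str, dict[str, float]] = {
    "corrugator": {"happy": 0.75, "sad": 1.0, "anger": 1.25, "fear": 1.0,
                   "disgust": 1.0, "surprise": 1.0},
    "zygomaticus": {"happy": 1.10, "sad": 1.0, "anger": 1.0, "fear": 1.0,
                    "disgust": 1.0, "surprise": 1.0},
}

#: Default questionnaire-mimicry couplings:
#: (questionnaire, subscale, muscle, emotion, target correlation with the
#: participant's realized gain for that muscle/emotion).
DEFAULT_QUESTIONNAIRE_EFFECTS: tuple[tuple[str, str, str, str, float], ...] = (
    ("osi", "internal_regulation", "corrugator", "happy", 0.4),
    ("osi", "social_influence", "zygomaticus", "happy", -0.4),
    ("isas", "peer_bonding", "corrugator", "anger", -0.4),
)


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort."""

    n_per_group: int = 30
    seed: int = 0
    fs: float = 1000.0
    tonic_sd_uV: tuple[float, float] = (10.0, 8.0)   # (corrugator, zygomaticus)
    tonic_mod_depth: float = 0.6       # relative SD of slow tonic wander
    tonic_mod_cutoff_hz: float = 1.2   # low-pass cutoff of the wander
    tonic_mod_sat: float = 6.0         # tanh saturation (bounds the wander)
    line_amp_uV: float = 2.0
    gains: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_GAINS.items()})
    hnssi_attenuation: float = 0.5
    gain_jitter_sd: float = 0.02
    artifact_rate: float = 3.0            # expected artifacts per channel/session
    artifact_amp_mult: tuple[float, float] = (8.0, 15.0)
    artifact_dur_ms: tuple[float, float] = (100.0, 400.0)
    response_onset_ms: float = 300.0
    response_ramp_ms: float = 500.0
    response_end_ms: float = 1500.0
    lead_in_ms: float = 20000.0
    tail_ms: float = 20000.0
    questionnaire_effects: tuple = DEFAULT_QUESTIONNAIRE_EFFECTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.hnssi_attenuation <= 1.0:
            raise ValueError("hnssi_attenuation must lie in [0, 1]")
        for m, emo_gains in self.gains.items():
            if any(g <= 0 for g in emo_gains.values()):
                raise ValueError("gains must be positive")
        if self.artifact_rate < 0 or self.gain_jitter_sd < 0 or self.line_amp_uV < 0:
            raise ValueError("rates, jitter and amplitudes must be >= 0")
        for _, _, _, _, r in self.questionnaire_effects:
            if abs(r) >= 1.0:
                raise ValueError("questionnaire target correlations must satisfy |r| < 1")


@dataclass
class SimulatedParticipant:
    participant_id: str
    group: str
    recording: RawRecording
    events: pd.DataFrame
    gains: np.ndarray          # (2, 6) realized gains, canonical order


@dataclass
class Cohort:
    config: SimulationConfig
    participants: list[SimulatedParticipant]
    osi: pd.DataFrame
    isas: pd.DataFrame


def make_trial_schedule(seed: int | np.random.Generator = 0,
                        lead_in_ms: float = 20000.0) -> pd.DataFrame:
    """Random full-session trial schedule.

    144 trials — a random permutation of the 24 identities x 6 emotions —
    with onsets spaced 4500 ms (1.5 s stimulus + 3 s inter-trial
    interval) after a 20-s neutral lead-in baseline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = [(e, i) for e in EMOTIONS for i in range(1, N_IDENTITIES + 1)]
    order = rng.permutation(len(pairs))
    rows = []
    for k, idx in enumerate(order):
        emo, ident = pairs[idx]
        rows.append({"onset_ms": int(lead_in_ms + k * MIN_ONSET_SPACING_MS),
                     "emotion": emo, "identity": ident, "trial_index": k + 1})
    return validate_events(pd.DataFrame(rows))


def effective_gains(group: str, config: SimulationConfig) -> np.ndarray:
    """Population-level (2, 6) gain matrix for a group.

    For the self-injury group the corrugator anger contraction and happy
    relaxation are attenuated toward 1: g_eff = 1 + (1 - alpha)(g - 1).
    """
    g = np.array([[config.gains[m][e] for e in EMOTIONS] for m in MUSCLES])
    if group == "hnssi":
        ci = MUSCLES.index("corrugator")
        for emo in ("anger", "happy"):
            e = EMOTIONS.index(emo)
            g[ci, e] = 1.0 + (1.0 - config.hnssi_attenuation) * (g[ci, e] - 1.0)
    return g


def realize_gains(group: str, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Participant-level gains: group gains plus Gaussian jitter."""
    g = effective_gains(group, config)
    g = g + rng.normal(0.0, config.gain_jitter_sd, size=g.shape)
    return np.clip(g, 0.05, None)


def _band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                        band: tuple[float, float] = (30.0, 250.0)) -> np.ndarray:
    """Zero-mean unit-SD Gaussian noise band-limited to ``band`` Hz."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _tonic_modulation(n: int, fs: float, config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Slow, bounded multiplicative wander of tonic EMG amplitude.

    Saturated (tanh-compressed) low-pass Gaussian noise, scaled to
    relative SD ``tonic_mod_depth``. Tonic muscle tone waxes and wanes
    smoothly with posture, respiration-coupled tension and arousal; the
    saturation keeps the wander strictly bounded (about 1.4 SD), so
    nonstationarity of clean tonic activity widens the pooled rejection
    statistics without itself masquerading as artifact, while the
    broadband spectrum cannot phase-lock to the fixed trial spacing.
    """
    if config.tonic_mod_depth <= 0:
        return np.ones(n)
    # decimate: the wander lives below ~1 Hz, so synthesize at ~20 Hz
    dec = max(1, int(fs // 20))
    n_lo = n // dec + 2
    sos = sps.butter(2, config.tonic_mod_cutoff_hz, btype="lowpass",
                     fs=fs / dec, output="sos")
    u = sps.sosfiltfilt(sos, rng.standard_normal(n_lo))
    u /= u.std()
    s_lo = np.tanh(config.tonic_mod_sat * u)
    s_lo *= config.tonic_mod_depth / s_lo.std()
    s = np.interp(np.arange(n) / dec, np.arange(n_lo), s_lo)
    return np.clip(1.0 + s, 0.05, None)


def simulate_recording(schedule: pd.DataFrame, gains: np.ndarray,
                       config: SimulationConfig, rng: np.random.Generator,
                       participant_id: str = "P000",
                       group: str = "control") -> RawRecording:
    """One participant's continuous two-channel recording.

    ``gains`` is the participant's realized (2, 6) gain matrix. Samples
    are rounded to 4 decimal places so that a TSV round trip is lossless.
    """
    fs = config.fs
    onsets = schedule["onset_ms"].to_numpy()
    n = int(round((onsets[-1] + MIN_ONSET_SPACING_MS + config.tail_ms) * fs / 1000.0))

    # shared response shape: raised-cosine onset, hold to response end
    i0 = int(round(config.response_onset_ms * fs / 1000.0))
    i1 = int(round((config.response_onset_ms + config.response_ramp_ms) * fs / 1000.0))
    i2 = int(round(config.response_end_ms * fs / 1000.0))
    shape = np.zeros(i2 - i0)
    ramp = i1 - i0
    shape[:ramp] = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
    shape[ramp:] = 1.0

    t = np.arange(n) / fs
    channels = []
    emo_idx = np.array([EMOTIONS.index(e) for e in schedule["emotion"]])
    for ch in range(2):
        profile = np.ones(n)
        for onset, e in zip(onsets, emo_idx):
            s = int(round(onset * fs / 1000.0)) + i0
            seg = min(len(shape), n - s)
            if seg > 0:
                profile[s:s + seg] = 1.0 + (gains[ch, e] - 1.0) * shape[:seg]
        sd = config.tonic_sd_uV[ch]
        mod = _tonic_modulation(n, fs, config, rng)
        x = _band_limited_noise(n, fs, rng) * sd * mod * profile
        x = x + config.line_amp_uV * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        # movement/clench artifacts: square-envelope amplitude bursts of
        # 8-15x tonic SD (a DC offset would not survive the 30 Hz
        # high-pass, so the burst lives inside the EMG band)
        n_art = rng.poisson(config.artifact_rate)
        for _ in range(n_art):
            start = rng.integers(int(config.lead_in_ms * fs / 1000.0),
                                 int(round(onsets[-1] * fs / 1000.0)))
            dur = int(round(rng.uniform(*config.artifact_dur_ms) * fs / 1000.0))
            x[start:start + dur] *= rng.uniform(*config.artifact_amp_mult)
        channels.append(np.round(x, 4))
    return RawRecording(participant_id=participant_id, group=group,
                        corrugator=channels[0], zygomaticus=channels[1],
                        sampling_rate=fs)


def _discretize_total(latent: np.ndarray, max_total: int) -> np.ndarray:
    """Gaussian-copula mapping of latent N(0,1) scores to 0..max_total."""
    u = st.norm.cdf(latent)
    return np.clip(np.floor(u * (max_total + 1)).astype(int), 0, max_total)


def _fill_items(total: int, n_items: int, item_max: int) -> list[int]:
    """Distribute a subscale total across items, front-loaded."""
    vals = []
    rem = total
    for _ in range(n_items):
        v = min(item_max, rem)
        vals.append(v)
        rem -= v
    return vals


def simulate_questionnaires(participants: list[SimulatedParticipant],
                            config: SimulationConfig,
                            rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OSI and ISAS response sheets for the self-injury participants.

    Targeted subscales are drawn from a latent normal correlated (target
    r) with the participant's realized gain for the linked muscle/emotion,
    then discretized into valid item responses via a Gaussian copula; the
    discretized, rescored subscale preserves the target correlation to
    within the copula's mild attenuation. Untargeted subscales are
    independent noise. Controls did not complete these instruments.
    """
    hnssi = [p for p in participants if p.group == "hnssi"]
    if not hnssi:
        return pd.DataFrame(), pd.DataFrame()
    n = len(hnssi)
    gain_mat = np.stack([p.gains for p in hnssi])     # (n, 2, 6)
    targets = {(qn, sub): (MUSCLES.index(m), EMOTIONS.index(e), r)
               for qn, sub, m, e, r in config.questionnaire_effects}

    def _latent(qn: str, sub: str) -> np.ndarray:
        eps = rng.standard_normal(n)
        if (qn, sub) in targets:
            ch, e, r = targets[(qn, sub)]
            g = gain_mat[:, ch, e]
            z = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(n)
            return r * z + np.sqrt(1.0 - r**2) * eps
        return eps

    osi_totals = {sub: _discretize_total(_latent("osi", sub), len(items) * q.OSI_ITEM_MAX)
                  for sub, items in q.OSI_SUBSCALES.items()}
    isas_totals = {fn: _discretize_total(_latent("isas", fn), len(items) * q.ISAS_ITEM_MAX)
                   for fn, items in q.ISAS_ITEM_MAP.items()}

    osi_rows = []
    isas_rows = []
    for j, p in enumerate(hnssi):
        rec_o: dict = {"participant": p.participant_id}
        for sub, items in q.OSI_SUBSCALES.items():
            vals = _fill_items(int(osi_totals[sub][j]), len(items), q.OSI_ITEM_MAX)
            rec_o.update(zip(items, vals))
        osi_rows.append(rec_o)
        rec_i: dict = {"participant": p.participant_id}
        for fn, items in q.ISAS_ITEM_MAP.items():
            vals = _fill_items(int(isas_totals[fn][j]), len(items), q.ISAS_ITEM_MAX)
            rec_i.update(zip(items, vals))
        isas_rows.append(rec_i)
    osi = pd.DataFrame(osi_rows)
    isas = pd.DataFrame(isas_rows)
    isas = isas[["participant"] + [f"item_{i:02d}" for i in range(1, 40)]]
    return osi, isas


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """A full balanced cohort, deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_per_group
    seqs = root.spawn(n_total + 1)
    participants = []
    for i in range(n_total):
        group = "hnssi" if i < config.n_per_group else "control"
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(seqs[i])
        schedule = make_trial_schedule(rng, lead_in_ms=config.lead_in_ms)
        gains = realize_gains(group, config, rng)
        rec = simulate_recording(schedule, gains, config, rng, pid, group)
        participants.append(SimulatedParticipant(pid, group, rec, schedule, gains))
        log.info("simulated %s (%s): %d samples", pid, group, rec.n_samples)
    qrng = np.random.default_rng(seqs[n_total])
    osi, isas = simulate_questionnaires(participants, config, qrng)
    return Cohort(config=config, participants=participants, osi=osi, isas=isas)


def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort directory: per-participant signal/events TSVs,
    questionnaire TSVs and a manifest with the config and group map."""
    from pathlib import Path
    from .io import write_recording, write_events

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for p in cohort.participants:
        write_recording(p.recording, d / f"{p.participant_id}_signal.tsv")
        write_events(p.events, d / f"{p.participant_id}_events.tsv")
    if len(cohort.osi):
        cohort.osi.to_csv(d / "osi.tsv", sep="\t", index=False)
        cohort.isas.to_csv(d / "isas.tsv", sep="\t", index=False)
    cfg = asdict(cohort.config)
    cfg["tonic_sd_uV"] = list(cfg["tonic_sd_uV"])
    cfg["questionnaire_effects"] = [list(t) for t in cfg["questionnaire_effects"]]
    manifest = {
        "config": cfg,
        "participants": [{"id": p.participant_id, "group": p.group}
                         for p in cohort.participants],
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
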