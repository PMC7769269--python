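"""End-to-end orchestration: raw cohort -> results bundle.

The per-participant chain is filter -> Hilbert envelope -> epoch ->
baseline-correct -> reject -> smooth -> average by emotion -> bin; the
cohort-level analysis is one mixed ANOVA per muscle, 12 planned group
contrasts (6 emotions x 2 muscles) and questionnaire-mimicry Pearson
correlations for the self-injury group.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import epochs as ep
from . import io as fio
from . import questionnaires as q
from . import stats
from .signal import FilterSpec, bandpass_notch, hilbert_rectify
from .types import EMOTIONS, MUSCLES, PipelineConfig, RawRecording, ResultsBundle

log = logging.getLogger(__name__)

#: Questionnaire subscales entering the correlation analysis, crossed with
#: both muscles and the happy/anger conditions.
CORRELATION_SUBSCALES: tuple[tuple[str, str], ...] = (
    ("osi", "internal_regulation"),
    ("osi", "social_influence"),
    ("isas", "affect_regulation"),
    ("isas", "peer_bonding"),
)
CORRELATION_EMOTIONS: tuple[str, ...] = ("happy", "anger")


def preprocess_participant(rec: RawRecording, events: pd.DataFrame,
                           config: PipelineConfig | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the signal/epoch reduction for one participant.

    Returns (binned long-format rows, rejection report rows). The epoch
    bookkeeping guarantees accepted + rejected + edge-unusable = number
    of events per channel.
    """
    cfg = config or PipelineConfig()
    spec = FilterSpec(highpass_hz=cfg.highpass_hz, notch_hz=cfg.notch_hz,
                      notch_q=cfg.notch_q, order=cfg.filter_order)
    env = np.stack([
        hilbert_rectify(bandpass_notch(ch, spec, rec.sampling_rate))
        for ch in rec.channels
    ])
    log.info("%s: filtered + rectified %d samples x %d channels",
             rec.participant_id, env.shape[1], env.shape[0])
    es = ep.extract_epochs(env, events, fs=rec.sampling_rate,
                           baseline_ms=cfg.baseline_ms, response_ms=cfg.response_ms)
    log.info("%s: %d/%d epochs usable", rec.participant_id,
             int(es.usable.sum()), es.n_trials)
    es = ep.baseline_correct(es)
    es, report = ep.reject_epochs(es, sd_mult=cfg.reject_sd,
                                  window_ms=cfg.reject_window_ms,
                                  step_ms=cfg.reject_step_ms, fs=rec.sampling_rate)
    es = ep.smooth_moving_average(es, window_ms=cfg.smooth_ms, fs=rec.sampling_rate)
    binned = ep.binned_response(es, rec.participant_id, rec.group, cfg)
    report.insert(0, "participant", rec.participant_id)
    report["n_unusable"] = int((~es.usable).sum())
    return binned, report


def analyze_binned(binned: pd.DataFrame, rejection: pd.DataFrame,
                   config: PipelineConfig | None = None,
                   osi_scores: pd.DataFrame | None = None,
                   isas_scores: pd.DataFrame | None = None) -> ResultsBundle:
    """Cohort-level inference on the binned amplitude table."""
    cfg = config or PipelineConfig()
    counts = binned.groupby("group")["participant"].nunique()
    if len(counts) != 2 or counts.nunique() != 1:
        raise ValueError(f"unbalanced groups: {counts.to_dict()}")

    anova_tables: dict[str, pd.DataFrame] = {}
    contrast_rows = []
    anovas: dict[str, stats.AnovaResult] = {}
    for muscle in MUSCLES:
        res = stats.mixed_anova(binned[binned["muscle"] == muscle], alpha=cfg.alpha)
        anovas[muscle] = res
        anova_tables[muscle] = res.table
        log.info("ANOVA (%s): GG epsilons %s", muscle,
                 {k: round(s.epsilon, 3) for k, s in res.strata.items() if k != "between"})
        for emo in EMOTIONS:
            c = stats.planned_group_contrast(res, emo, muscle=muscle)
            contrast_rows.append(vars(c))
    contrasts = pd.DataFrame(contrast_rows)

    corr_rows = []
    scores = {"osi": osi_scores, "isas": isas_scores}
    hnssi = binned[binned["group"] == "hnssi"]
    overall = (hnssi.groupby(["participant", "muscle", "emotion"], sort=True)
               ["amplitude"].mean().reset_index())
    for qn, sub in CORRELATION_SUBSCALES:
        sc = scores[qn]
        if sc is None or sub not in getattr(sc, "columns", []):
            continue
        for muscle in MUSCLES:
            for emo in CORRELATION_EMOTIONS:
                amp = overall[(overall["muscle"] == muscle) & (overall["emotion"] == emo)]
                merged = amp.merge(sc[["participant", sub]], on="participant")
                dropped = len(amp) - len(merged)
                if dropped:
                    log.warning("%s/%s: %d participant(s) without %s scores "
                                "dropped from correlations", muscle, emo, dropped, qn)
                if len(merged) < 3:
                    continue
                res = stats.pearson_correlation(merged[sub], merged["amplitude"])
                corr_rows.append({"questionnaire": qn, "subscale": sub,
                                  "muscle": muscle, "emotion": emo,
                                  "r": res.r, "n": res.n, "p": res.p})
    corr_cols = ["questionnaire", "subscale", "muscle", "emotion", "r", "n", "p"]
    correlations = pd.DataFrame(corr_rows, columns=corr_cols)
    log.info("analysis: %d contrasts, %d correlations", len(contrasts), len(corr_rows))
    return ResultsBundle(anova_tables=anova_tables, contrasts=contrasts,
                         correlations=correlations, rejection=rejection,
                         binned=binned)


def analyze_recordings(recordings: list[tuple[RawRecording, pd.DataFrame]],
                       config: PipelineConfig | None = None,
                       osi: pd.DataFrame | None = None,
                       isas: pd.DataFrame | None = None) -> ResultsBundle:
    """Full pipeline on in-memory recordings (the file-free entry point)."""
    cfg = config or PipelineConfig()
    binned_parts, reports = [], []
    for rec, events in recordings:
        b, r = preprocess_participant(rec, events, cfg)
        binned_parts.append(b)
        reports.append(r)
    binned = pd.concat(binned_parts, ignore_index=True)
    rejection = pd.concat(reports, ignore_index=True)
    osi_scores = q.score_osi(osi) if osi is not None and len(osi) else None
    isas_scores = q.score_isas(isas) if isas is not None and len(isas) else None
    return analyze_binned(binned, rejection, cfg, osi_scores, isas_scores)


def run_pipeline(config: PipelineConfig, cohort_dir) -> ResultsBundle:
    """Run the complete analysis on a cohort directory.

    The directory must contain ``manifest.json`` (participant ids and
    groups), per-participant ``<id>_signal.tsv`` / ``<id>_events.tsv``,
    and optionally ``osi.tsv`` / ``isas.tsv``. A missing questionnaire
    row for a self-injury participant only drops that participant from
    the correlations (with a warning); unbalanced groups are an error.
    """
    d = Path(cohort_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    recordings = []
    for entry in manifest["participants"]:
        pid, group = entry["id"], entry["group"]
        rec, events = fio.read_recording(d / f"{pid}_signal.tsv",
                                         d / f"{pid}_events.tsv",
                                         participant_id=pid, group=group)
        recordings.append((rec, events))
    log.info("loaded %d participants from %s", len(recordings), d)
    osi = pd.read_csv(d / "osi.tsv", sep="\t") if (d / "osi.tsv").exists() else None
    isas = pd.read_csv(d / "isas.tsv", sep="\t") if (d / "isas.tsv").exists() else None
    return analyze_recordings(recordings, config, osi, isas)
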