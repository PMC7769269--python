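"""Plain-text readers and writers.

All files are TSV with header rows; signals are stored at fixed 4-decimal
µV precision (a write -> read round trip is bit-exact for values on that
grid). No binary biosignal formats are supported.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .types import FormatError, RawRecording, ResultsBundle, validate_events

log = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["time_ms", "corrugator_uV", "zygomaticus_uV"]
EVENT_COLUMNS = ["onset_ms", "emotion", "identity", "trial_index"]


def read_recording(path, events_path, participant_id: str | None = None,
                   group: str = "control") -> tuple[RawRecording, pd.DataFrame]:
    """Read a recording TSV plus its events TSV into validated containers.

    The signal file needs columns ``time_ms, corrugator_uV,
    zygomaticus_uV`` (one row per 1-ms sample); units are taken as µV and
    ms. Event onsets must reference samples inside the recording.
    """
    path = Path(path)
    sig = pd.read_csv(path, sep="\t")
    missing = [c for c in SIGNAL_COLUMNS if c not in sig.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    rec = RawRecording(
        participant_id=participant_id or path.stem.replace("_signal", ""),
        group=group,
        corrugator=sig["corrugator_uV"].to_numpy(float),
        zygomaticus=sig["zygomaticus_uV"].to_numpy(float),
    )
    events = read_events(events_path, n_samples=rec.n_samples)
    return rec, events


def read_events(path, n_samples: int | None = None) -> pd.DataFrame:
    events = pd.read_csv(Path(path), sep="\t")
    return validate_events(events, n_samples=n_samples)


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as TSV at fixed 4-decimal precision."""
    n = rec.n_samples
    with open(path, "w") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        cor, zyg = rec.corrugator, rec.zygomaticus
        chunk = 100_000
        for s in range(0, n, chunk):
            e = min(s + chunk, n)
            block = "\n".join(
                f"{t}\t{cor[t]:.4f}\t{zyg[t]:.4f}" for t in range(s, e)
            )
            fh.write(block + "\n")


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results(bundle: ResultsBundle, directory) -> None:
    """Write a results bundle as fixed-column-order TSV tables.

    Files: ``anova_<muscle>.tsv`` (effect, df, MS, F, eta_p2, p, epsilon),
    ``contrasts.tsv`` (muscle, emotion, F, df_num, df_err, p, r),
    ``correlations.tsv``, ``rejection.tsv`` and ``binned.tsv``. Outputs
    are deterministic: same bundle, same bytes.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    for muscle, table in bundle.anova_tables.items():
        table.to_csv(d / f"anova_{muscle}.tsv", sep="\t", index=False,
                     float_format=float_fmt)
    bundle.contrasts[["muscle", "emotion", "F", "df_num", "df_err", "p", "r"]].to_csv(
        d / "contrasts.tsv", sep="\t", index=False, float_format=float_fmt)
    corr_cols = ["questionnaire", "subscale", "muscle", "emotion", "r", "n", "p"]
    corr = bundle.correlations
    if corr.empty:
        corr = pd.DataFrame(columns=corr_cols)
    corr[corr_cols].to_csv(d / "correlations.tsv", sep="\t", index=False,
                           float_format=float_fmt)
    bundle.rejection.to_csv(d / "rejection.tsv", sep="\t", index=False,
                            float_format=float_fmt)
    bundle.binned.to_csv(d / "binned.tsv", sep="\t", index=False,
                         float_format=float_fmt)
    log.info("results written to %s", d)
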