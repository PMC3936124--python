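"""Persistence: session files, study/subject directory layout, CSV export.

Sessions are saved in a documented line-oriented UTF-8 text format (header
of ``key: value`` lines, then one line per trial, ``#`` comments), organized
as ``root/study_id/subject_id/<subject>_<timestamp>.pvt`` so that data are
grouped by study name and subject identifier.  Raw trial data and computed
summary statistics export to RFC-4180 CSV for offline analysis.  All numeric
serialization is locale-independent (period decimal separator, ``repr``
round-trip precision).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

from .protocol import ProtocolConfig, Session, Trial
from .stats import SessionStats, summarize
from .timing import DeviceModel

__all__ = [
    "StudyLayout",
    "write_session",
    "read_session",
    "session_to_text",
    "session_from_text",
    "export_csv",
]

logger = logging.getLogger("pvtsim")

_FORMAT_TAG = "# pvtsim session v1"
_TRIAL_COLUMNS = ("index", "isi_s", "stimulus_time_s", "response_time_s",
                  "true_rt_ms", "recorded_rt_ms", "classification")


@dataclass(frozen=True)
class StudyLayout:
    """Directory layout: session and prediction files live under
    ``root/study_id/subject_id/``."""

    root: Path
    study_id: str

    def subject_dir(self, subject_id: str) -> Path:
        return Path(self.root) / self.study_id / subject_id


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(text: str) -> float | None:
    return None if text == "NA" else float(text)


def session_to_text(session: Session) -> str:
    """Serialize one session to the documented text format."""
    lines = [_FORMAT_TAG]
    header = {
        "study_id": session.study_id,
        "subject_id": session.subject_id,
        "start_time": session.start_time,
        "rng_seed": session.rng_seed,
        "t_awake_h": session.t_awake_h,
        "clock_h": session.clock_h,
    }
    for f in fields(ProtocolConfig):
        header[f"config.{f.name}"] = getattr(session.config, f.name)
    for f in fields(DeviceModel):
        header[f"device.{f.name}"] = getattr(session.device, f.name)
    lines += [f"{k}: {_fmt(v)}" for k, v in header.items()]
    lines.append("# trials: " + " ".join(_TRIAL_COLUMNS))
    for t in session.trials:
        lines.append(" ".join(_fmt(getattr(t, c)) for c in _TRIAL_COLUMNS))
    return "\n".join(lines) + "\n"


def session_from_text(text: str) -> Session:
    """Parse the documented text format back into a Session (lossless)."""
    header: dict[str, str] = {}
    trials: list[Trial] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _FORMAT_TAG:
        raise ValueError("not a pvtsim session file (missing format tag)")
    for line in lines[1:]:
        if line.startswith("#"):
            continue
        if ":" in line and not trials and not _looks_like_trial(line):
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
        else:
            vals = line.split()
            if len(vals) != len(_TRIAL_COLUMNS):
                raise ValueError(f"malformed trial line: {line!r}")
            trials.append(Trial(
                index=int(vals[0]),
                isi_s=float(vals[1]),
                stimulus_time_s=_parse_float(vals[2]),
                response_time_s=_parse_float(vals[3]),
                true_rt_ms=_parse_float(vals[4]),
                recorded_rt_ms=_parse_float(vals[5]),
                classification=vals[6]))

    def pick(prefix: str, cls):
        kwargs = {}
        for f in fields(cls):
            raw = header[f"{prefix}.{f.name}"]
            if raw == "NA":
                kwargs[f.name] = None
            elif f.type in ("float", "float | None"):
                kwargs[f.name] = float(raw)
            elif f.type == "bool":
                kwargs[f.name] = raw == "true"
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)

    return Session(
        study_id=header["study_id"],
        subject_id=header["subject_id"],
        start_time=header["start_time"],
        config=pick("config", ProtocolConfig),
        device=pick("device", DeviceModel),
        trials=tuple(trials),
        rng_seed=int(header["rng_seed"]),
        t_awake_h=float(header["t_awake_h"]),
        clock_h=float(header["clock_h"]))


def _looks_like_trial(line: str) -> bool:
    first = line.split(maxsplit=1)[0]
    return first.isdigit()


def session_filename(session: Session) -> str:
    stamp = (session.start_time.replace("-", "").replace(":", "")
             .replace(".", ""))
    return f"{session.subject_id}_{stamp}.pvt"


def write_session(session: Session, layout: StudyLayout) -> Path:
    """Write one session under the study layout.

    Filenames embed the session start timestamp (ISO-8601 basic); writing
    the same session twice yields a versioned filename, never an overwrite.
    """
    directory = layout.subject_dir(session.subject_id)
    directory.mkdir(parents=True, exist_ok=True)
    base = session_filename(session)
    path = directory / base
    version = 1
    while path.exists():
        version += 1
        path = directory / f"{Path(base).stem}_v{version}.pvt"
    path.write_text(session_to_text(session), encoding="utf-8")
    logger.info("wrote session %s", path)
    return path


def read_session(path: Path | str) -> Session:
    return session_from_text(Path(path).read_text(encoding="utf-8"))


_SUMMARY_COLUMNS = [
    "study_id", "subject_id", "start_time", "rng_seed", "t_awake_h",
    "clock_h", "n_valid", "n_false_start", "n_no_response", "mean_rt_ms",
    "mean_speed_per_s", "minor_lapses", "major_lapses", "fastest10_mean_ms",
    "slowest10_mean_ms", "divergence",
]


def export_csv(
    sessions: list[Session],
    stats: list[SessionStats] | None = None,
    dest: Path | str = ".",
) -> tuple[Path, Path]:
    """Export raw trial data and per-session summary statistics as CSV.

    Writes ``raw_rts.csv`` (one row per trial) and ``summary.csv`` (one row
    per session) under ``dest`` and returns both paths.  ``stats`` must
    align with ``sessions``; if omitted it is computed here.
    """
    if stats is None:
        stats = [summarize(s) for s in sessions]
    if len(stats) != len(sessions):
        raise ValueError("sessions and stats lists must align")
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)

    raw_rows = []
    for session in sessions:
        for t in session.trials:
            raw_rows.append({
                "study_id": session.study_id,
                "subject_id": session.subject_id,
                "start_time": session.start_time,
                **{c: getattr(t, c) for c in _TRIAL_COLUMNS},
            })
    raw_path = dest / "raw_rts.csv"
    pd.DataFrame(raw_rows, columns=["study_id", "subject_id", "start_time",
                                    *_TRIAL_COLUMNS]).to_csv(
        raw_path, index=False, quoting=csv.QUOTE_MINIMAL)

    summary_rows = []
    for session, st in zip(sessions, stats):
        row = {"study_id": session.study_id, "subject_id": session.subject_id,
               "start_time": session.start_time, "rng_seed": session.rng_seed,
               "t_awake_h": session.t_awake_h, "clock_h": session.clock_h}
        row.update({f.name: getattr(st, f.name) for f in fields(SessionStats)})
        summary_rows.append(row)
    summary_path = dest / "summary.csv"
    pd.DataFrame(summary_rows, columns=_SUMMARY_COLUMNS).to_csv(
        summary_path, index=False, quoting=csv.QUOTE_MINIMAL)
    logger.info("exported %d sessions to %s", len(sessions), dest)
    return raw_path, summary_path


def export_forecasts(steps, dest: Path | str) -> Path:
    """Write a post-hoc forecast trail beside the session data.

    One CSV row per (sessions-observed, forecast-time) pair with the point
    prediction, the prediction-interval bounds and the prior-weight
    diagnostic.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    rows = []
    for step in steps:
        fc = step.forecast
        for t, p, lo, hi in zip(fc.times_h, fc.point, fc.pi_low, fc.pi_high):
            rows.append({
                "n_sessions": step.n_sessions,
                "prior_weight": step.posterior.prior_weight,
                "t_awake_h": t, "point": p,
                "pi_low": lo, "pi_high": hi, "level": fc.level,
            })
    path = dest / "predictions.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    logger.info("wrote forecast trail %s", path)
    return path
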