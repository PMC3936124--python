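"""Event-driven PVT session executor on a continuous virtual clock.

The psychomotor vigilance task presents a millisecond counter after a random
inter-stimulus interval (ISI, usually 2-10 s) and the subject responds as
fast as possible.  A response during the ISI is a *false start*; failure to
respond within 65 s of the stimulus is a *no-response*; otherwise the trial
is *valid* and the RT is shown for 500 ms before the next ISI starts.  A 5-
or 10-min session typically yields 50-100 stimulus-response events.

The engine reproduces those protocol semantics on a virtual clock with
sub-millisecond (real-valued seconds) resolution: no rendering, no wall
clock, one seeded random generator per session, so the same seed and
parameters yield a byte-identical session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np

from .timing import DeviceModel, simulate_recorded_rt

if TYPE_CHECKING:  # pragma: no cover
    from .subject import SubjectParams

__all__ = [
    "ProtocolConfig",
    "Trial",
    "Session",
    "draw_isi",
    "classify_response",
    "run_session",
]

Classification = Literal["valid", "false_start", "no_response"]

#: recorded RTs are stored at this resolution (0.1 ms), matching a platform
#: that timestamps events with sub-millisecond precision.
RT_RESOLUTION_MS = 0.1


@dataclass(frozen=True)
class ProtocolConfig:
    """PVT protocol parameters.

    Defaults follow the standard task: uniform 2-10 s ISI, 500-ms feedback
    after each valid response, 65-s no-response timeout, minor lapses at
    RTs > 500 ms.  The major-lapse threshold is analysis-configurable (the
    task itself only defines the 500-ms minor threshold); 3000 ms is the
    shipped default.  ``false_start_redraws_isi`` selects whether a false
    start aborts the pending ISI and draws a fresh one (default) or resumes
    the remainder after feedback.
    """

    isi_min_s: float = 2.0
    isi_max_s: float = 10.0
    session_duration_s: float = 300.0
    feedback_ms: float = 500.0
    no_response_timeout_s: float = 65.0
    minor_lapse_ms: float = 500.0
    major_lapse_ms: float = 3000.0
    false_start_redraws_isi: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.isi_min_s <= self.isi_max_s:
            raise ValueError("require 0 < isi_min_s <= isi_max_s")
        durations = (self.session_duration_s, self.feedback_ms,
                     self.no_response_timeout_s, self.minor_lapse_ms,
                     self.major_lapse_ms)
        if any(not math.isfinite(d) or d < 0 for d in durations):
            raise ValueError("all durations must be finite and non-negative")
        if not self.minor_lapse_ms < self.major_lapse_ms:
            raise ValueError("require minor_lapse_ms < major_lapse_ms")

    @property
    def feedback_s(self) -> float:
        return self.feedback_ms / 1000.0


@dataclass(frozen=True)
class Trial:
    """One stimulus-response event.

    For a false start the stimulus was never shown: ``stimulus_time_s`` and
    both RT fields are ``None`` and ``response_time_s`` marks the premature
    click.  For a no-response both RT fields are ``None``.
    """

    index: int
    isi_s: float
    classification: Classification
    stimulus_time_s: float | None = None
    response_time_s: float | None = None
    true_rt_ms: float | None = None
    recorded_rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.classification == "valid":
            if self.true_rt_ms is None or self.recorded_rt_ms is None:
                raise ValueError("valid trial requires both RT fields")
            if not self.recorded_rt_ms >= self.true_rt_ms >= 0:
                raise ValueError("require recorded_rt_ms >= true_rt_ms >= 0")
        elif self.true_rt_ms is not None or self.recorded_rt_ms is not None:
            raise ValueError(f"{self.classification} trial carries no RT")


@dataclass(frozen=True)
class Session:
    """An ordered collection of trials with protocol, device and identity."""

    study_id: str
    subject_id: str
    start_time: str  # ISO-8601 wall-clock label; not used by the engine
    config: ProtocolConfig
    device: DeviceModel
    trials: tuple[Trial, ...]
    rng_seed: int
    t_awake_h: float = 0.0
    clock_h: float = 8.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[str, int]:
        out = {"valid": 0, "false_start": 0, "no_response": 0}
        for t in self.trials:
            out[t.classification] += 1
        return out

    def recorded_rts(self) -> list[float]:
        return [t.recorded_rt_ms for t in self.trials
                if t.classification == "valid"]

    def true_rts(self) -> list[float]:
        return [t.true_rt_ms for t in self.trials
                if t.classification == "valid"]


def draw_isi(rng: np.random.Generator, config: ProtocolConfig) -> float:
    """Draw one inter-stimulus interval, uniform on [isi_min_s, isi_max_s]."""
    if config.isi_min_s == config.isi_max_s:
        return float(config.isi_min_s)
    return float(rng.uniform(config.isi_min_s, config.isi_max_s))


def classify_response(
    stimulus_time_s: float | None,
    response_time_s: float | None,
    config: ProtocolConfig,
) -> tuple[Classification, float | None]:
    """Classify one response against the protocol rules.

    Returns ``(classification, rt_ms)``; ``rt_ms`` is ``None`` unless valid.
    A response with no stimulus shown (i.e. during the ISI) is a false
    start; no response within the timeout of the stimulus is a no-response.
    """
    if response_time_s is not None and response_time_s < 0:
        raise ValueError("response precedes the start of the trial")
    if stimulus_time_s is None:
        if response_time_s is None:
            raise ValueError("neither stimulus nor response present")
        return "false_start", None
    if response_time_s is not None and response_time_s < stimulus_time_s:
        return "false_start", None
    if (response_time_s is None
            or response_time_s - stimulus_time_s > config.no_response_timeout_s):
        return "no_response", None
    return "valid", (response_time_s - stimulus_time_s) * 1000.0


def _round_rt(rt_ms: float) -> float:
    """Store RTs at 0.1-ms resolution (sub-millisecond timestamping)."""
    return round(rt_ms / RT_RESOLUTION_MS) * RT_RESOLUTION_MS


def run_session(
    subject: "SubjectParams",
    device: DeviceModel,
    config: ProtocolConfig,
    wake_time_offset_h: float = 0.0,
    seed: int = 0,
    *,
    clock_h: float | None = None,
    study_id: str = "study",
    subject_id: str = "subject",
    start_time: str = "1970-01-01T00:00:00",
) -> Session:
    """Simulate one full PVT session.

    The loop alternates ISI -> stimulus -> response -> 500-ms feedback.  A
    new ISI begins only while the virtual clock is strictly below the session
    duration, and a stimulus whose onset would fall past the duration is not
    shown (so every event lies within duration + timeout); a stimulus shown
    in time runs to completion even past the nominal duration.

    ``subject`` is anything implementing the subject interface
    (``false_start_wait_s`` and ``sample_rt_ms``); ``wake_time_offset_h`` is
    the hours-awake at session start and ``clock_h`` the time-of-day on the
    24-h circadian clock (defaults to 8 + hours awake, i.e. an 08:00 wake).
    All randomness flows through one generator seeded with ``seed``.
    """
    if clock_h is None:
        clock_h = (8.0 + wake_time_offset_h) % 24.0
    rng = np.random.default_rng(seed)
    state = subject.alertness(wake_time_offset_h, clock_h)

    trials: list[Trial] = []
    t = 0.0
    duration = config.session_duration_s
    index = 0

    while t < duration:
        isi = draw_isi(rng, config)
        pending = isi
        session_over = False
        while True:
            wait = subject.false_start_wait_s(state, rng)
            if wait < pending:
                # premature click during the ISI
                t += wait
                trials.append(Trial(index=index, isi_s=isi,
                                    classification="false_start",
                                    response_time_s=t))
                index += 1
                t += config.feedback_s
                if config.false_start_redraws_isi:
                    break
                pending -= wait
                continue
            stim_request = t + pending
            if stim_request > duration:
                # no stimulus scheduled after the clock expires
                session_over = True
                break
            true_rt = subject.sample_rt_ms(state, rng)
            recorded_rt, onset_s = simulate_recorded_rt(
                true_rt, stim_request, device, rng)
            response_s = onset_s + recorded_rt / 1000.0
            cls, _ = classify_response(onset_s, response_s, config)
            if cls == "no_response":
                trials.append(Trial(index=index, isi_s=isi,
                                    classification="no_response",
                                    stimulus_time_s=onset_s))
                t = onset_s + config.no_response_timeout_s
            else:
                trials.append(Trial(index=index, isi_s=isi,
                                    classification="valid",
                                    stimulus_time_s=onset_s,
                                    response_time_s=response_s,
                                    true_rt_ms=_round_rt(true_rt),
                                    recorded_rt_ms=_round_rt(recorded_rt)))
                t = response_s + config.feedback_s
            index += 1
            break
        if session_over:
            break

    return Session(study_id=study_id, subject_id=subject_id,
                   start_time=start_time, config=config, device=device,
                   trials=tuple(trials), rng_seed=int(seed),
                   t_awake_h=float(wake_time_offset_h),
                   clock_h=float(clock_h))
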