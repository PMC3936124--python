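"""Synthetic PVT subject: a two-process alertness model driving an RT mixture.

Alertness is modelled as the sum of a homeostatic sleep-pressure process
(saturating exponential in hours awake) and a 24-h single-harmonic circadian
process, expressed directly as a latent reaction-time *deficit* in
milliseconds:

    deficit(t, c) = max(0, G * (1 - exp(-t / tau)) + A * cos(2*pi*(c - phi)/24))

with ``t`` hours awake, ``c`` time-of-day, ``G`` the asymptotic homeostatic
RT penalty, ``tau`` the build-up time constant, ``A`` the circadian
amplitude and ``phi`` the circadian trough (worst-alertness) hour.  The
deficit shifts the location of a right-skewed lognormal RT distribution and
raises the probability of a lapse tail; false starts are a Poisson process
over the inter-stimulus interval.

Sleep-satiated humans produce a mean RT of about 240 ms with an intrasubject
SD of about 29 ms; the ``satiated`` preset is calibrated to exactly that
anchor.  The exact group-average two-process parameterization used by
operational prediction tools is not public; the form here is a documented
standard stand-in, not a reproduction of any fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolConfig, Session, run_session
from .timing import DeviceModel

__all__ = [
    "SubjectParams",
    "AlertnessState",
    "SessionSlot",
    "alertness_deficit",
    "sample_trial",
    "simulate_study",
    "tsd_schedule",
]


@dataclass(frozen=True)
class SubjectParams:
    """Parameters of the synthetic subject.

    baseline_mu_ms / baseline_sigma_ms are the *mean and SD* of the valid-RT
    distribution at zero deficit (the lognormal is re-parameterized so these
    are exact moments, keeping the calibration anchor interpretable).
    ``lapse_gain`` couples deficit to lapse probability:
    p_lapse = clip(lapse_base_p + lapse_gain * deficit_ms / 1000, 0, 1).
    Lapse RTs are ``lapse_floor_ms`` plus an exponential tail whose mean
    grows with deficit.
    """

    baseline_mu_ms: float = 240.0
    baseline_sigma_ms: float = 29.0
    s_tau_wake_h: float = 16.0
    s_gain_ms: float = 120.0
    c_amplitude_ms: float = 40.0
    c_phase_h: float = 5.0
    lapse_base_p: float = 0.0
    lapse_gain: float = 0.0
    false_start_rate_per_s: float = 0.0
    lapse_floor_ms: float = 500.0
    lapse_scale_ms: float = 300.0
    name: str = "subject"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_base_p <= 1.0:
            raise ValueError("lapse_base_p must be in [0, 1]")
        if self.baseline_sigma_ms < 0:
            raise ValueError("baseline_sigma_ms must be >= 0")
        if self.s_tau_wake_h <= 0:
            raise ValueError("s_tau_wake_h must be > 0")
        if self.false_start_rate_per_s < 0:
            raise ValueError("false_start_rate_per_s must be >= 0")

    # --- subject interface used by the protocol engine -------------------

    def alertness(self, t_awake_h: float, clock_h: float) -> "AlertnessState":
        return AlertnessState(
            t_awake_h=t_awake_h, clock_h=clock_h,
            deficit=alertness_deficit(t_awake_h, clock_h, self))

    def false_start_wait_s(self, state: "AlertnessState",
                           rng: np.random.Generator) -> float:
        """Waiting time to the next premature click (inf if none pending)."""
        if self.false_start_rate_per_s <= 0:
            return math.inf
        return float(rng.exponential(1.0 / self.false_start_rate_per_s))

    def lapse_probability(self, state: "AlertnessState") -> float:
        return float(np.clip(
            self.lapse_base_p + self.lapse_gain * state.deficit / 1000.0,
            0.0, 1.0))

    def sample_rt_ms(self, state: "AlertnessState",
                     rng: np.random.Generator) -> float:
        return float(self.sample_rts(state, rng, 1)[0])

    def sample_rts(self, state: "AlertnessState", rng: np.random.Generator,
                   n: int) -> np.ndarray:
        """Vectorized draw of n true RTs (ms) at the given alertness state."""
        mean = self.baseline_mu_ms + state.deficit
        sigma = self.baseline_sigma_ms
        if sigma == 0.0:
            base = np.full(n, mean)
        else:
            # lognormal with exact mean/SD (mean, sigma) via moment matching
            s2 = math.log1p((sigma / mean) ** 2)
            mu = math.log(mean) - s2 / 2.0
            base = rng.lognormal(mu, math.sqrt(s2), size=n)
        p = self.lapse_probability(state)
        if p <= 0.0:
            return base
        is_lapse = rng.random(n) < p
        scale = self.lapse_scale_ms + state.deficit
        lapse_rts = self.lapse_floor_ms + rng.exponential(scale, size=n)
        return np.where(is_lapse, lapse_rts, base)


@dataclass(frozen=True)
class AlertnessState:
    """Latent state: hours awake, circadian clock hour, and the RT deficit."""

    t_awake_h: float
    clock_h: float
    deficit: float

    def __post_init__(self) -> None:
        if self.t_awake_h < 0:
            raise ValueError("t_awake_h must be >= 0")
        if self.deficit < 0:
            raise ValueError("deficit must be >= 0")


def homeostatic_deficit(t_awake_h: float, params: SubjectParams) -> float:
    """Homeostatic component: G * (1 - exp(-t/tau)), the solution of
    dS/dt = (G - S)/tau with S(0) = 0."""
    return params.s_gain_ms * -math.expm1(-t_awake_h / params.s_tau_wake_h)


def circadian_deficit(clock_h: float, params: SubjectParams) -> float:
    """Circadian component, peaking (worst alertness) at ``c_phase_h``."""
    return params.c_amplitude_ms * math.cos(
        2.0 * math.pi * (clock_h - params.c_phase_h) / 24.0)


def alertness_deficit(t_awake_h: float, clock_h: float,
                      params: SubjectParams) -> float:
    """Latent RT deficit (ms): homeostat + circadian, floored at zero.

    Zero at full rest and circadian-neutral phase; 24-h periodic in
    ``clock_h``; monotone non-decreasing in ``t_awake_h`` at fixed phase.
    """
    if t_awake_h < 0:
        raise ValueError("t_awake_h must be >= 0")
    return max(0.0, homeostatic_deficit(t_awake_h, params)
               + circadian_deficit(clock_h, params))


def sample_trial(
    state: AlertnessState,
    params: SubjectParams,
    rng: np.random.Generator,
    isi_s: float = 0.0,
    no_response_timeout_s: float = 65.0,
) -> tuple[str, float | None]:
    """Sample one trial outcome at the given alertness state.

    Returns ``("false_start", None)`` if a premature click falls inside the
    ISI window, ``("no_response", None)`` if the sampled RT exceeds the
    timeout, else ``("valid", true_rt_ms)``.
    """
    if params.false_start_wait_s(state, rng) < isi_s:
        return "false_start", None
    rt = params.sample_rt_ms(state, rng)
    if rt / 1000.0 > no_response_timeout_s:
        return "no_response", None
    return "valid", rt


@dataclass(frozen=True)
class SessionSlot:
    """One scheduled session: cumulative hours awake and time-of-day."""

    t_awake_h: float
    clock_h: float


def tsd_schedule(duration_h: float = 85.0, interval_h: float = 2.0,
                 wake_clock_h: float = 8.0) -> list[SessionSlot]:
    """Total-sleep-deprivation schedule: sessions every ``interval_h`` hours
    from wake (t=0) while t <= duration_h.  85 h at 2-h spacing gives
    floor(85/2)+1 = 43 sessions."""
    n = int(math.floor(duration_h / interval_h)) + 1
    return [SessionSlot(t_awake_h=k * interval_h,
                        clock_h=(wake_clock_h + k * interval_h) % 24.0)
            for k in range(n)]


def simulate_study(
    subject: SubjectParams,
    schedule: list[SessionSlot],
    config: ProtocolConfig,
    device: DeviceModel,
    seed: int = 0,
    *,
    study_id: str = "study",
    subject_id: str = "subject",
) -> list[Session]:
    """Simulate one session per scheduled slot, advancing alertness along the
    wake history.  Deterministic given ``seed`` (each session gets an
    independent child seed from one SeedSequence)."""
    times = [s.t_awake_h for s in schedule]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("schedule times must be strictly increasing")
    min_gap_h = config.session_duration_s / 3600.0
    if any(b - a < min_gap_h for a, b in zip(times, times[1:])):
        raise ValueError("sessions overlap: spacing shorter than a session")
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(schedule), 1))
    sessions = []
    for slot, s in zip(schedule, child_seeds):
        sessions.append(run_session(
            subject, device, config,
            wake_time_offset_h=slot.t_awake_h, clock_h=slot.clock_h,
            seed=int(s) % (2**31), study_id=study_id, subject_id=subject_id))
    return sessions
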