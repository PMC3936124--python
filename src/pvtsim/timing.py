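"""Input-latency model: the PC delay chain between a true and a recorded RT.

A reaction time measured on a general-purpose computer is never the true
stimulus-to-response interval.  The stimulus only becomes visible at the next
monitor refresh, the button press is only seen at the next USB poll, and the
operating system, device driver and the mouse's own click-detection logic add
a further (noisy) latency on top.  This module models that chain as

    recorded RT = poll-quantized(true RT) + fixed latency + jitter,

where the stimulus-onset timestamp is taken at the refresh tick on which the
stimulus actually appears (mirroring software that tracks the refresh cycle
to timestamp the physical onset, so refresh quantization shifts the onset
*event* but does not inflate the recorded RT).

Typical numbers: monitors refresh at 60-120 Hz; a standard USB mouse is
polled at 125 Hz (8-ms period), a gaming mouse at 1000 Hz (1-ms period), so
the poll-rate difference alone is worth 7 ms of worst-case delay and 3.5 ms
of mean delay.  Measured mean delays of real configurations are larger
(roughly 5-10 ms with a gaming mouse, 30-36 ms with standard mice); the
excess is lumped into ``fixed_latency_ms``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DeviceModel",
    "quantize_to_next_tick",
    "simulate_recorded_rt",
    "expected_mean_delay",
]

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # E|N(0,1)|


def quantize_to_next_tick(t_ms: float, rate_hz: float, phase_ms: float = 0.0) -> float:
    """Round *t_ms* up to the next tick of a periodic sampling grid.

    The grid is ``{phase_ms + k * 1000/rate_hz : k integer}``; the result is
    the smallest grid point >= ``t_ms``.  An infinite rate means continuous
    sampling and returns ``t_ms`` unchanged.

    Parameters
    ----------
    t_ms : event time in milliseconds.
    rate_hz : sampling rate; must be positive.
    phase_ms : grid offset, in ``[0, 1000/rate_hz)``.
    """
    if not rate_hz > 0:
        raise ValueError(f"sampling rate must be positive, got {rate_hz}")
    if math.isinf(rate_hz):
        return float(t_ms)
    period = 1000.0 / rate_hz
    if not 0.0 <= phase_ms < period:
        raise ValueError(f"phase {phase_ms} ms outside [0, {period}) ms")
    # round() guards against 10.0/8*8 -> 10.000000000000002-style float noise
    # so that on-tick inputs are fixed points (idempotence).
    k = math.ceil(round((t_ms - phase_ms) / period, 9))
    return phase_ms + k * period


@dataclass(frozen=True)
class DeviceModel:
    """Parameters of the delay chain mapping a true RT to a recorded RT.

    ``refresh_phase_s`` / ``poll_phase_s`` of ``None`` (the default) mean the
    phase is redrawn uniformly per trial — the realistic case of free-running
    clock domains.  Fixed phases give exact, deterministic quantization for
    unit testing and oracle studies.

    A *reference* device (the role of an external RT box with sub-millisecond
    event timestamps) has infinite rates and zero latency/jitter: it records
    the true RT exactly.
    """

    name: str = "device"
    refresh_hz: float = 60.0
    refresh_phase_s: float | None = None
    poll_hz: float = 125.0
    poll_phase_s: float | None = None
    fixed_latency_ms: float = 0.0
    jitter_sd_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.refresh_hz > 0 and self.poll_hz > 0):
            raise ValueError("refresh_hz and poll_hz must be positive")
        if self.fixed_latency_ms < 0 or self.jitter_sd_ms < 0:
            raise ValueError("fixed_latency_ms and jitter_sd_ms must be >= 0")
        for phase, rate, what in (
            (self.refresh_phase_s, self.refresh_hz, "refresh"),
            (self.poll_phase_s, self.poll_hz, "poll"),
        ):
            if math.isinf(rate):
                if phase not in (None, 0.0):
                    raise ValueError(f"{what}_phase_s must be 0 at infinite rate")
                continue
            if phase is not None and not 0.0 <= phase < 1.0 / rate:
                raise ValueError(f"{what}_phase_s {phase} outside [0, {1.0 / rate})")

    @classmethod
    def reference(cls) -> "DeviceModel":
        """Zero-delay reference device: recorded RT equals true RT exactly."""
        return cls(name="reference", refresh_hz=math.inf, refresh_phase_s=0.0,
                   poll_hz=math.inf, poll_phase_s=0.0,
                   fixed_latency_ms=0.0, jitter_sd_ms=0.0)

    def with_fixed_phases(self, refresh_phase_s: float = 0.0,
                          poll_phase_s: float = 0.0) -> "DeviceModel":
        return replace(self, refresh_phase_s=refresh_phase_s,
                       poll_phase_s=poll_phase_s)

    @property
    def poll_period_ms(self) -> float:
        return 0.0 if math.isinf(self.poll_hz) else 1000.0 / self.poll_hz

    @property
    def refresh_period_ms(self) -> float:
        return 0.0 if math.isinf(self.refresh_hz) else 1000.0 / self.refresh_hz


def _phase_ms(fixed_phase_s: float | None, rate_hz: float,
              rng: np.random.Generator) -> float:
    if math.isinf(rate_hz):
        return 0.0
    if fixed_phase_s is not None:
        return fixed_phase_s * 1000.0
    return rng.uniform(0.0, 1000.0 / rate_hz)


def simulate_recorded_rt(
    true_rt_ms: float,
    stimulus_request_time_s: float,
    device: DeviceModel,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Pass one true RT through the device delay chain.

    The stimulus requested at ``stimulus_request_time_s`` appears at the next
    monitor refresh tick; the response, physically issued ``true_rt_ms``
    later, is detected at the next USB poll tick plus a fixed latency plus a
    non-negative half-normal jitter.  The recorded RT is detection time minus
    the (refresh-accurate) onset timestamp, so it inflates the true RT by the
    poll/latency/jitter terms only.

    Returns ``(recorded_rt_ms, stimulus_onset_time_s)``.
    """
    if true_rt_ms < 0:
        raise ValueError("true_rt_ms must be >= 0")
    req_ms = stimulus_request_time_s * 1000.0
    onset_ms = quantize_to_next_tick(
        req_ms, device.refresh_hz,
        _phase_ms(device.refresh_phase_s, device.refresh_hz, rng))
    press_ms = onset_ms + true_rt_ms
    detect_ms = quantize_to_next_tick(
        press_ms, device.poll_hz,
        _phase_ms(device.poll_phase_s, device.poll_hz, rng))
    detect_ms += device.fixed_latency_ms
    if device.jitter_sd_ms > 0:
        detect_ms += abs(rng.normal(0.0, device.jitter_sd_ms))
    return detect_ms - onset_ms, onset_ms / 1000.0


def expected_mean_delay(device: DeviceModel) -> float:
    """Closed-form E[recorded - true] in ms, under uniformly random phases.

    The poll grid adds a delay uniform on ``[0, poll period)``, mean half the
    period; the fixed latency adds itself; the truncated-Gaussian jitter is
    half-normal with mean ``jitter_sd * sqrt(2/pi)``.  Refresh quantization
    delays the stimulus *event* but the onset is timestamped at the actual
    refresh tick, so it contributes no residual to the recorded RT (residual
    term exactly zero in this onset-timestamp model).
    """
    return (device.poll_period_ms / 2.0
            + device.fixed_latency_ms
            + device.jitter_sd_ms * _HALF_NORMAL_MEAN)
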