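"""Closed-loop device validation with Bland-Altman statistics.

The verification protocol pairs a zero-delay reference timestamp stream (the
role played physically by an external RT box with light and button sensors)
with the stream recorded by the device chain under test.  An operator sweeps
reaction times from the fastest plausible (~160 ms) to ~2000 ms over five
5-min sessions; per-trial differences (device minus reference) measure the
delay the device adds.  The differences are summarized two ways: a
Bland-Altman analysis (mean difference, SD, mean +/- 2 SD limits of
agreement) and a per-device min/mean/max/SD delay table sorted by mean.

A packaged fixture (``data/delay_benchmarks.csv``) carries published
closed-loop delay measurements of a gold-standard handheld PVT device and
six PC configurations with gaming and standard mice; it feeds the
cross-configuration arithmetic (e.g. the six gaming-mouse means average to
7.9 ms, about 3 % of a 240-ms rested RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig, run_session
from .timing import DeviceModel

__all__ = [
    "PairedRT",
    "BAStats",
    "DelaySummary",
    "OperatorSweep",
    "run_closed_loop",
    "bland_altman",
    "delay_summary_table",
    "cross_config_mean",
    "load_delay_benchmarks",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class PairedRT:
    """One reference-vs-device RT pair; ``diff_ms`` is device - reference."""

    reference_rt_ms: float
    device_rt_ms: float

    @property
    def diff_ms(self) -> float:
        return self.device_rt_ms - self.reference_rt_ms

    @property
    def mean_ms(self) -> float:
        return (self.device_rt_ms + self.reference_rt_ms) / 2.0


@dataclass(frozen=True)
class BAStats:
    """Bland-Altman summary: mean difference and mean +/- 2 SD limits."""

    n: int
    mean_diff_ms: float
    sd_diff_ms: float

    @property
    def loa_low_ms(self) -> float:
        return self.mean_diff_ms - 2.0 * self.sd_diff_ms

    @property
    def loa_high_ms(self) -> float:
        return self.mean_diff_ms + 2.0 * self.sd_diff_ms


@dataclass(frozen=True)
class DelaySummary:
    """Per-device descriptive statistics of the RT differences."""

    device_name: str
    n_rts: int
    min_ms: float
    mean_ms: float
    max_ms: float
    sd_ms: float


class OperatorSweep:
    """Operator standing in for a human during closed-loop testing.

    Emits true RTs log-uniform over ``rt_range_ms`` (covering fast responses
    densely while still reaching the slow end), no false starts, no lapse
    mixture.  Implements the subject interface of the protocol engine.
    """

    def __init__(self, rt_range_ms: tuple[float, float] = (160.0, 2000.0)):
        low, high = rt_range_ms
        if not (low >= 0 and low < high):
            raise ValueError("require 0 <= low < high for the RT range")
        self.rt_range_ms = (float(low), float(high))

    def alertness(self, t_awake_h: float, clock_h: float):
        return None

    def false_start_wait_s(self, state, rng) -> float:
        return math.inf

    def sample_rt_ms(self, state, rng: np.random.Generator) -> float:
        low, high = self.rt_range_ms
        return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def run_closed_loop(
    device: DeviceModel,
    n_sessions: int = 5,
    session_min: float = 5.0,
    operator_rt_range_ms: tuple[float, float] = (160.0, 2000.0),
    seed: int = 0,
) -> list[PairedRT]:
    """Run the closed-loop protocol against one device model.

    Five 5-min sessions by default; the operator's true RT is the reference
    stream and the device-chain output the test stream, paired per trial.
    The number of pairs emerges from the protocol engine (on the order of
    210 for the default sweep).
    """
    operator = OperatorSweep(operator_rt_range_ms)
    config = ProtocolConfig(session_duration_s=session_min * 60.0)
    seeds = np.random.SeedSequence(seed).generate_state(n_sessions)
    pairs: list[PairedRT] = []
    for s in seeds:
        session = run_session(operator, device, config, seed=int(s) % (2**31),
                              study_id="closed-loop", subject_id=device.name)
        for trial in session.trials:
            if trial.classification == "valid":
                pairs.append(PairedRT(reference_rt_ms=trial.true_rt_ms,
                                      device_rt_ms=trial.recorded_rt_ms))
    return pairs


def bland_altman(pairs: Iterable[PairedRT]) -> BAStats:
    """Bland-Altman statistics of the paired differences.

    The SD is the sample standard deviation (n-1 denominator); limits of
    agreement are mean +/- 2 SD.
    """
    diffs = np.array([p.diff_ms for p in pairs], dtype=float)
    if diffs.size < 2:
        raise ValueError("bland_altman requires at least two pairs")
    return BAStats(n=int(diffs.size),
                   mean_diff_ms=float(np.mean(diffs)),
                   sd_diff_ms=float(np.std(diffs, ddof=1)))


def delay_summary_table(
    runs: dict[str, list[PairedRT]],
) -> list[DelaySummary]:
    """Per-device min/mean/max/SD of the differences, sorted ascending by
    mean (stable).  A single-pair run reports SD 0 by convention."""
    summaries = []
    for name, pairs in runs.items():
        diffs = np.array([p.diff_ms for p in pairs], dtype=float)
        if diffs.size == 0:
            raise ValueError(f"device {name!r} has no RT pairs")
        sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
        summaries.append(DelaySummary(
            device_name=name, n_rts=int(diffs.size),
            min_ms=float(diffs.min()), mean_ms=float(np.mean(diffs)),
            max_ms=float(diffs.max()), sd_ms=sd))
    return sorted(summaries, key=lambda s: s.mean_ms)


def cross_config_mean(
    summaries: Iterable[DelaySummary],
    device_filter: Callable[[str], bool] = lambda name: True,
) -> float:
    """Unweighted mean of the per-device mean delays for selected devices,
    reported at 0.1-ms rounding (the convention of published delay tables)."""
    means = [s.mean_ms for s in summaries if device_filter(s.device_name)]
    if not means:
        raise ValueError("device filter selected no summaries")
    return round(float(np.mean(means)), 1)


def load_delay_benchmarks() -> pd.DataFrame:
    """Published closed-loop delay benchmarks (ms, vs an RT-box reference).

    Columns: device, n, min, mean, max, sd.  Rows cover a gold-standard
    handheld PVT device and six PC configurations each tested with a gaming
    mouse (G) and, for two of them, standard mice (S1/S2).
    """
    with resources.files("pvtsim.data").joinpath(
            "delay_benchmarks.csv").open("r") as fh:
        return pd.read_csv(fh, comment="#")


def benchmarks_as_summaries(df: pd.DataFrame | None = None) -> list[DelaySummary]:
    """The benchmark table as DelaySummary objects (sorted by mean)."""
    if df is None:
        df = load_delay_benchmarks()
    return sorted(
        (DelaySummary(device_name=r.device, n_rts=int(r.n), min_ms=r.min,
                      mean_ms=r.mean, max_ms=r.max, sd_ms=r.sd)
         for r in df.itertuples()),
        key=lambda s: s.mean_ms)


def bland_altman_plot(pairs: list[PairedRT], ax=None, title: str = ""):
    """Bland-Altman scatter (pair mean vs difference) with the mean line and
    +/- 2 SD limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stats = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    means = [p.mean_ms for p in pairs]
    diffs = [p.diff_ms for p in pairs]
    ax.scatter(means, diffs, s=8, alpha=0.6)
    ax.axhline(stats.mean_diff_ms, color="k",
               label=f"mean = {stats.mean_diff_ms:.1f} ms")
    for lim in (stats.loa_low_ms, stats.loa_high_ms):
        ax.axhline(lim, color="k", linestyle="--")
    ax.set_xlabel("mean of paired RTs (ms)")
    ax.set_ylabel("device - reference (ms)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    return ax
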