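"""Per-session PVT summary statistics.

The canonical analysis-window statistics: minor lapses (RTs > 500 ms), major
lapses (RTs above a larger configurable threshold), mean RT, speed (mean
reciprocal RT, in 1/s), the means of the fastest and slowest 10 % of RTs,
and an RT-distribution divergence against a baseline session.

Statistics are computed on the *recorded* (device-measured) RTs by default,
which is what a real testing platform observes; ``use_true_rts=True``
switches to the latent true RTs for oracle studies.  False starts and
no-responses carry no finite RT: they are counted but excluded from all
RT-based statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .protocol import Session

__all__ = [
    "SessionStats",
    "count_lapses",
    "mean_speed",
    "tail_means",
    "rt_divergence",
    "summarize",
]

#: histogram bin edges for the divergence surrogate: 20-ms bins over
#: [100, 1000] ms, with an underflow and an overflow bin.
_DIVERGENCE_EDGES = np.concatenate(
    [[-np.inf], np.arange(100.0, 1000.0 + 20.0, 20.0), [np.inf]])


@dataclass(frozen=True)
class SessionStats:
    """Summary-statistic vector for one session.

    RT-based fields are NaN when the session has no valid trials (counts are
    still reported).  ``divergence`` is NaN unless a baseline RT list was
    supplied to :func:`summarize`.
    """

    n_valid: int
    n_false_start: int
    n_no_response: int
    mean_rt_ms: float
    mean_speed_per_s: float
    minor_lapses: int
    major_lapses: int
    fastest10_mean_ms: float
    slowest10_mean_ms: float
    divergence: float


def count_lapses(rts: list[float] | np.ndarray, threshold_ms: float) -> int:
    """Number of RTs strictly greater than the threshold (lapses are
    RTs > 500 ms for the minor threshold)."""
    rts = np.asarray(rts, dtype=float)
    return int(np.sum(rts > threshold_ms))


def mean_speed(rts: list[float] | np.ndarray) -> float:
    """Mean reciprocal RT in 1/s: mean(1000 / rt_ms)."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("mean_speed requires at least one RT")
    if np.any(rts <= 0):
        raise ValueError("mean_speed requires strictly positive RTs")
    return float(np.mean(1000.0 / rts))


def tail_means(rts: list[float] | np.ndarray,
               fraction: float = 0.10) -> tuple[float, float]:
    """Means of the fastest and slowest ``fraction`` of RTs.

    The tail size is k = ceil(fraction * n); no interpolation.  Returns
    ``(fastest_mean, slowest_mean)``.
    """
    rts = np.sort(np.asarray(rts, dtype=float))
    n = rts.size
    if n == 0:
        raise ValueError("tail_means requires at least one RT")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(math.ceil(fraction * n))
    return float(np.mean(rts[:k])), float(np.mean(rts[-k:]))


def _histogram(rts: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(rts, bins=_DIVERGENCE_EDGES)
    return counts / counts.sum()


def rt_divergence(session_rts: list[float] | np.ndarray,
                  baseline_rts: list[float] | np.ndarray) -> float:
    """Divergence between two empirical RT distributions, in [0, 1].

    A surrogate for the RT-distribution divergence statistic used by
    raw-distribution analysis methods (whose exact published form is
    external to this package): the base-2 Jensen-Shannon divergence between
    histograms on fixed 20-ms bins over [100, 1000] ms with under/overflow
    bins.  Symmetric; 0 iff the histograms coincide; 1 for fully disjoint
    supports.
    """
    a = np.asarray(session_rts, dtype=float)
    b = np.asarray(baseline_rts, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rt_divergence requires two non-empty RT lists")
    js_dist = jensenshannon(_histogram(a), _histogram(b), base=2.0)
    if np.isnan(js_dist):  # identical degenerate histograms
        return 0.0
    return float(js_dist) ** 2


def summarize(session: Session,
              baseline_rts: list[float] | np.ndarray | None = None,
              *, use_true_rts: bool = False) -> SessionStats:
    """Compute the full analysis-window statistic vector for one session.

    Only valid trials enter the RT-based statistics; false starts and
    no-responses are counted.  With zero valid trials all RT fields are NaN.
    Invariant to trial order.
    """
    counts = session.counts()
    rts = np.asarray(
        session.true_rts() if use_true_rts else session.recorded_rts(),
        dtype=float)
    nan = float("nan")
    if rts.size == 0:
        return SessionStats(
            n_valid=0, n_false_start=counts["false_start"],
            n_no_response=counts["no_response"],
            mean_rt_ms=nan, mean_speed_per_s=nan,
            minor_lapses=0, major_lapses=0,
            fastest10_mean_ms=nan, slowest10_mean_ms=nan, divergence=nan)
    fastest, slowest = tail_means(rts)
    divergence = (rt_divergence(rts, baseline_rts)
                  if baseline_rts is not None and len(baseline_rts) else nan)
    return SessionStats(
        n_valid=counts["valid"],
        n_false_start=counts["false_start"],
        n_no_response=counts["no_response"],
        mean_rt_ms=float(np.mean(rts)),
        mean_speed_per_s=mean_speed(rts),
        minor_lapses=count_lapses(rts, session.config.minor_lapse_ms),
        major_lapses=count_lapses(rts, session.config.major_lapse_ms),
        fastest10_mean_ms=fastest,
        slowest10_mean_ms=slowest,
        divergence=divergence)
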