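"""CMAP parameter extraction: amplitude, latency, duration; recruitment.

The three parameters follow the standard cursor definitions for evoked
muscle potentials displayed in the positive-peak convention:

* **amplitude** — voltage difference between the baseline (zero after DC
  subtraction) and the positive peak, in mV;
* **latency** — time from the stimulus-artifact onset to the point where the
  trace rises through the zero line into the response, in ms;
* **duration** — time between the rising and falling zero crossings that
  bracket the main positive deflection, in ms.

Where a human operator places cursors on the crossings by eye, this module
interpolates linearly between the two samples straddling zero — the
reproducible analog, exact for piecewise-linear traces and sub-sample
accurate for smooth ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .core import Sweep, SweepSet
from .errors import ConfigError, DetectionError
from .preprocess import average_sweeps, normalize_polarity, subtract_baseline

__all__ = [
    "CmapMeasurement",
    "RecruitmentCurve",
    "detect_artifact_onset",
    "measure_cmap",
    "analyze_recruitment",
    "preprocess_sweepset",
    "measure_sweepset",
]

#: Default exclusion window after artifact onset, ms. Keeps the stimulus
#: artifact (100 us pulse plus amplifier recovery) out of the peak search.
DEFAULT_BLANKING_MS = 0.3


@dataclass(frozen=True)
class CmapMeasurement:
    """Measured CMAP parameters for one (averaged) sweep.

    Times are in ms on the sweep time base; undefined quantities (e.g.
    latency of a no-response trace) are NaN. ``flags`` may contain:

    * ``no_response`` — peak never exceeded the noise threshold;
    * ``clipped`` — the response had not returned to zero by the end of the
      search window, so the falling crossing is truncated;
    * ``noisy_baseline`` — the rising crossing could not be anchored at zero
      before the peak, or the noise threshold exceeds 20% of the peak.
    """

    amplitude: float
    latency: float
    duration: float
    peak_time: float
    onset_crossing_time: float
    offset_crossing_time: float
    flags: frozenset = field(default_factory=frozenset)

    @property
    def is_response(self) -> bool:
        return "no_response" not in self.flags


@dataclass(frozen=True)
class RecruitmentCurve:
    """Stimulus intensity -> amplitude series with plateau determination.

    ``supramaximal_intensity`` is the lowest tested intensity at which the
    amplitude has stopped growing (None if the series never plateaus).
    """

    points: tuple
    supramaximal_intensity: Optional[float]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def detect_artifact_onset(sweep: Sweep, mode: str = "configured", k: float = 8.0) -> float:
    """Locate the stimulus-artifact onset, in ms.

    ``configured`` returns ``meta.artifact_onset`` unchanged (the normal
    path: the operator knows the stimulator delay). ``auto`` scans the first
    difference of the trace for the earliest jump exceeding ``k`` robust
    standard deviations (1.4826 x MAD) of the pre-window differences, with
    the excursion sustained for at least 2 samples; it needs >= 0.5 ms of
    pre-stimulus baseline and raises :class:`DetectionError` if nothing
    crosses threshold, so callers can fall back to the configured value.
    """
    meta = sweep.meta
    if mode == "configured":
        if meta.artifact_onset is None:
            raise ConfigError("metadata has no artifact_onset")
        return float(meta.artifact_onset)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    n_pre = int(round(0.5 * meta.sampling_rate / 1000.0))
    if n_pre < 4:
        raise ConfigError("auto detection needs >= 0.5 ms of pre-stimulus baseline")
    x = sweep.samples
    d = np.diff(x)
    d_pre = d[: n_pre - 1]
    mad = np.median(np.abs(d_pre - np.median(d_pre)))
    thresh = max(k * 1.4826 * mad, 1e-12)
    med = np.median(x[:n_pre])
    dev = np.abs(x - med)
    dev_sd = max(1.4826 * np.median(np.abs(x[:n_pre] - med)), 1e-12)

    candidates = np.flatnonzero(np.abs(d) > thresh)
    for i in candidates:
        # sustained: the two samples after the jump both deviate from baseline
        j = i + 1
        if j + 1 < len(x) and dev[j] > 3 * dev_sd and dev[j + 1] > 3 * dev_sd:
            return j * meta.dt_ms
    raise DetectionError("no super-threshold excursion found")


def _interp_up_crossing(x: np.ndarray, k: int, dt: float) -> float:
    """Zero up-crossing time between samples k (<=0) and k+1 (>0)."""
    return (k + (0.0 - x[k]) / (x[k + 1] - x[k])) * dt


def _interp_down_crossing(x: np.ndarray, k: int, dt: float) -> float:
    """Zero down-crossing time between samples k-1 (>0) and k (<=0)."""
    return (k - 1 + (0.0 - x[k - 1]) / (x[k] - x[k - 1])) * dt


def measure_cmap(
    sweep: Sweep,
    search_window: Optional[Tuple[float, float]] = None,
    noise_threshold: Union[str, float] = "auto",
    artifact_blanking: float = DEFAULT_BLANKING_MS,
) -> CmapMeasurement:
    """Extract amplitude, latency and duration from a conditioned sweep.

    The sweep must already be baseline-subtracted and in the positive-peak
    convention (see :func:`measure_sweepset` for the composed pipeline).

    Parameters
    ----------
    search_window : (start_ms, end_ms), optional
        Peak-search interval. Defaults to ``[artifact_onset +
        artifact_blanking, sweep end]``.
    noise_threshold : float or "auto"
        Response criterion in mV. ``auto`` uses 3 x the sample SD of the
        pre-stimulus baseline. A peak at or below threshold yields the
        ``no_response`` flag with latency/duration undefined; pass an
        explicit low threshold to deliberately measure weak responses.
    artifact_blanking : float
        Portion of the sweep after artifact onset excluded from the peak
        search, ms.

    Notes
    -----
    The rising crossing is the *last* zero up-crossing before the peak from
    which the trace stays positive up to the peak — robust to small baseline
    oscillations that create spurious early crossings. The falling crossing
    is the first zero down-crossing after the peak. Both are linearly
    interpolated between the straddling samples.
    """
    meta = sweep.meta
    onset = meta.artifact_onset
    if onset is None:
        raise ConfigError("artifact onset is not set")
    dt = meta.dt_ms
    n = len(sweep)
    if search_window is None:
        search_window = (onset + artifact_blanking, meta.sweep_duration)
    t0, t1 = search_window
    if t0 < onset:
        raise ConfigError(
            f"search window starts at {t0} ms, before artifact onset {onset} ms"
        )
    i0 = int(np.ceil(t0 / dt - 1e-9))
    i1 = min(int(np.floor(t1 / dt + 1e-9)), n - 1)
    if not (0 <= i0 < i1 <= n - 1):
        raise ConfigError(f"search window {search_window} outside sweep")

    x = sweep.samples
    i_base = int(np.floor(onset / dt + 1e-9))
    if noise_threshold == "auto":
        baseline = x[:i_base]
        sd = float(baseline.std(ddof=1)) if len(baseline) >= 2 else 0.0
        threshold = 3.0 * sd
    else:
        threshold = float(noise_threshold)

    w = x[i0 : i1 + 1]
    j = i0 + int(np.argmax(w))
    peak_val = float(x[j])
    peak_time = j * dt

    if peak_val <= threshold:
        return CmapMeasurement(
            amplitude=max(peak_val, 0.0),
            latency=math.nan,
            duration=math.nan,
            peak_time=peak_time,
            onset_crossing_time=math.nan,
            offset_crossing_time=math.nan,
            flags=frozenset({"no_response"}),
        )

    flags = set()
    # walk back from the peak to the last non-positive sample; the search may
    # enter the blanking interval (the crossing itself can precede i0) but
    # not the artifact-onset sample.
    i_floor = int(np.ceil(onset / dt - 1e-9))
    k = j - 1
    while k >= i_floor and x[k] > 0.0:
        k -= 1
    if k >= i_floor:
        onset_cross = _interp_up_crossing(x, k, dt)
    else:
        onset_cross = i_floor * dt
        flags.add("noisy_baseline")

    k = j + 1
    while k <= i1 and x[k] > 0.0:
        k += 1
    if k <= i1:
        offset_cross = _interp_down_crossing(x, k, dt)
    else:
        offset_cross = i1 * dt
        flags.add("clipped")

    if threshold > 0.2 * peak_val:
        flags.add("noisy_baseline")

    return CmapMeasurement(
        amplitude=peak_val,
        latency=onset_cross - onset,
        duration=offset_cross - onset_cross,
        peak_time=peak_time,
        onset_crossing_time=onset_cross,
        offset_crossing_time=offset_cross,
        flags=frozenset(flags),
    )


def analyze_recruitment(
    measurements: Sequence[Tuple[float, Union[CmapMeasurement, float]]],
    plateau_tol: float = 0.05,
) -> RecruitmentCurve:
    """Determine the supramaximal intensity from an intensity series.

    CMAP amplitude grows with stimulus intensity until every motor axon is
    recruited, then plateaus. The plateau onset is the lowest intensity from
    which every subsequent amplitude increment stays below ``plateau_tol``
    times the running maximum amplitude; if the increments never settle the
    curve has no plateau and ``supramaximal_intensity`` is None.

    Parameters
    ----------
    measurements : sequence of (intensity_mA, CmapMeasurement or amplitude_mV)
        At least 3 points with strictly increasing intensities.
    """
    if len(measurements) < 3:
        raise ValueError("need >= 3 intensities to analyze recruitment")
    intensities = np.array([m[0] for m in measurements], dtype=float)
    if np.any(np.diff(intensities) <= 0):
        raise ValueError("intensities must be strictly increasing")
    amps = np.array(
        [m[1].amplitude if isinstance(m[1], CmapMeasurement) else float(m[1]) for m in measurements]
    )
    if np.any(amps < 0):
        raise ValueError("amplitudes must be >= 0")

    n = len(amps)
    increments = np.diff(amps)
    running_max = np.maximum.accumulate(amps)
    # small[j] is True when the increment arriving at point j+1 is negligible
    small = increments < plateau_tol * np.maximum(running_max[1:], 1e-300)
    supra = None
    for j0 in range(1, n):
        if np.all(small[j0 - 1 :]):
            supra = float(intensities[j0])
            break
    points = tuple((float(i), float(a)) for i, a in zip(intensities, amps))
    return RecruitmentCurve(points=points, supramaximal_intensity=supra)


def preprocess_sweepset(
    sweepset: SweepSet, selection: Optional[Sequence[int]] = None
) -> Sweep:
    """Condition a sweep set: polarity -> baseline subtraction -> average."""
    sweeps = [subtract_baseline(normalize_polarity(s)) for s in sweepset]
    return average_sweeps(SweepSet(sweeps), selection)


def measure_sweepset(
    sweepset: SweepSet,
    selection: Optional[Sequence[int]] = None,
    search_window: Optional[Tuple[float, float]] = None,
    noise_threshold: Union[str, float] = "auto",
    artifact_blanking: float = DEFAULT_BLANKING_MS,
) -> CmapMeasurement:
    """Full per-recording pipeline: condition the trials, then measure.

    Applies :func:`normalize_polarity`, :func:`subtract_baseline` (default
    pre-stimulus window), :func:`average_sweeps` over ``selection`` and
    :func:`measure_cmap` with the given options. Deterministic given inputs
    and configuration.
    """
    avg = preprocess_sweepset(sweepset, selection)
    return measure_cmap(
        avg,
        search_window=search_window,
        noise_threshold=noise_threshold,
        artifact_blanking=artifact_blanking,
    )
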