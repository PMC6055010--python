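"""Core containers: recording metadata, single sweeps and sweep sets.

A *sweep* is one triggered acquisition epoch, time-locked to the stimulus
trigger. Sample ``i`` of a sweep occurs at ``t = i / sampling_rate`` (0-based,
first sample at t = 0 relative to the trigger); the stimulus itself is
delivered ``artifact_onset`` milliseconds after the trigger. Every module in
the package uses this one index-to-time convention.

Voltages are in millivolts throughout. Times exposed through the API are in
milliseconds; sampling rate is in hertz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError, StructureError

__all__ = ["RecordingMeta", "Sweep", "SweepSet"]


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition metadata for a set of evoked-potential sweeps.

    Defaults mirror a typical evoked-EMG acquisition setup: 40 kHz sampling,
    20 ms triggered sweeps, stimulus delivered 1 ms after the trigger, and a
    2.0 mA supramaximal constant-current stimulus.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz).
    sweep_duration : float
        Length of one triggered sweep in milliseconds.
    stimulus_intensity : float
        Constant-current stimulus amplitude in mA.
    artifact_onset : float
        Time of the stimulus-artifact onset after the acquisition trigger (ms).
    polarity_inverted : bool
        True when the stored samples already follow the display convention in
        which the main CMAP deflection is positive. False means the samples
        are in raw recorded orientation and must be sign-flipped before
        measurement (see :func:`cmapkit.preprocess.normalize_polarity`).
    subject_id, group : str
        Labels carried through to summary tables.
    voltage_scale : float
        Multiplier applied at ingestion to convert stored sample values to
        millivolts (use 1000.0 for exports written in volts).
    """

    sampling_rate: float = 40_000.0
    sweep_duration: float = 20.0
    stimulus_intensity: float = 2.0
    artifact_onset: float = 1.0
    polarity_inverted: bool = True
    subject_id: str = ""
    group: str = ""
    voltage_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.sweep_duration > 0:
            raise ConfigError(f"sweep_duration must be > 0, got {self.sweep_duration}")
        if not (0 <= self.artifact_onset < self.sweep_duration):
            raise ConfigError(
                "artifact_onset must lie in [0, sweep_duration): "
                f"got {self.artifact_onset} with duration {self.sweep_duration}"
            )
        if self.stimulus_intensity < 0:
            raise ConfigError(
                f"stimulus_intensity must be >= 0, got {self.stimulus_intensity}"
            )
        if not self.voltage_scale > 0:
            raise ConfigError(f"voltage_scale must be > 0, got {self.voltage_scale}")

    @property
    def n_samples(self) -> int:
        """Number of samples in one sweep."""
        return int(round(self.sampling_rate * self.sweep_duration / 1000.0))

    @property
    def dt_ms(self) -> float:
        """Sample period in milliseconds."""
        return 1000.0 / self.sampling_rate

    def times_ms(self) -> np.ndarray:
        """Time axis of one sweep: ``t_i = i / sampling_rate`` in ms."""
        return np.arange(self.n_samples) * self.dt_ms

    def replace(self, **changes) -> "RecordingMeta":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class Sweep:
    """One triggered voltage trace (mV) with its recording metadata."""

    samples: np.ndarray
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise StructureError("sweep samples must be one-dimensional")
        if len(self.samples) != self.meta.n_samples:
            raise StructureError(
                f"sweep has {len(self.samples)} samples, metadata implies "
                f"{self.meta.n_samples} (= {self.meta.sampling_rate:g} Hz x "
                f"{self.meta.sweep_duration:g} ms)"
            )
        if not np.all(np.isfinite(self.samples)):
            raise StructureError("sweep contains non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    def times_ms(self) -> np.ndarray:
        return self.meta.times_ms()

    def with_samples(self, samples: np.ndarray) -> "Sweep":
        """New sweep with the same metadata and different samples."""
        return Sweep(samples=samples, meta=self.meta)


@dataclass
class SweepSet:
    """An ordered collection of sweeps sharing one time base and metadata."""

    sweeps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sweeps) < 1:
            raise StructureError("a SweepSet needs at least one sweep")
        meta0 = self.sweeps[0].meta
        for i, sw in enumerate(self.sweeps):
            if sw.meta != meta0:
                raise StructureError(f"sweep {i} has different metadata")
            if len(sw) != len(self.sweeps[0]):
                raise StructureError(f"sweep {i} has a different length")

    @property
    def meta(self) -> RecordingMeta:
        return self.sweeps[0].meta

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self) -> Iterator[Sweep]:
        return iter(self.sweeps)

    def __getitem__(self, i) -> Sweep:
        return self.sweeps[i]

    def to_matrix(self) -> np.ndarray:
        """Samples stacked as an (n_sweeps, n_samples) array."""
        return np.stack([sw.samples for sw in self.sweeps])

    def select(self, indices: Sequence[int]) -> "SweepSet":
        """Subset by sweep index (e.g. to drop trials hit by pulse noise)."""
        return SweepSet([self.sweeps[i] for i in indices])
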