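"""Shared containers, label sentinels, and error types.

A :class:`Trace` is the basic unit of raw data: one channel's sampled
extracellular voltage plus its sampling rate.  Cluster labels are plain
integers ``>= 0``; two negative sentinels are reserved:

* ``UNCLASSIFIED`` (−1): the sorter abstained (fuzzy membership below the
  defuzzification threshold, a feature outside the density map, or a pruned
  template cluster).
* ``NOISE_LABEL`` (−2): used only on the *ground-truth* side, marking a
  detected event that does not correspond to any simulated spike (a false
  positive of the detector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Label for spikes the classifier refused to assign.
UNCLASSIFIED: int = -1

#: Ground-truth label for detected events that are not true spikes.
NOISE_LABEL: int = -2


class InputError(ValueError):
    """Invalid argument values (band outside Nyquist, length mismatch, ...)."""


class ConvergenceError(RuntimeError):
    """An iterative search failed to reach its target."""


class PlacementError(ValueError):
    """A spike window does not fit inside the trace."""


class BoundaryError(ValueError):
    """A cutout window exceeds the trace bounds (streaming callers defer)."""


class TrainingError(RuntimeError):
    """Not enough data, or degenerate data, to train a model."""


class StateError(RuntimeError):
    """Operation requires a trained/initialised state that is missing."""


class ConfigError(ValueError):
    """Inconsistent run configuration."""


@dataclass
class Trace:
    """A sampled single-channel voltage signal."""

    samples: np.ndarray
    fs_hz: float
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs_hz <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs_hz}")
        if self.samples.ndim != 1:
            raise InputError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SpikeWaveform:
    """A fixed-length spike cutout.

    ``t_cross`` is the threshold-crossing sample in the source trace,
    ``t_start`` the first sample of the window, so the window covers
    ``[t_start, t_start + n)`` (half-open, 0-based).
    """

    samples: np.ndarray
    t_cross: int
    t_start: int
    channel_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def t_peak(self) -> int:
        """Sample index (in the source trace) of the largest |amplitude|."""
        return self.t_start + int(np.argmax(np.abs(self.samples)))

    def __len__(self) -> int:
        return len(self.samples)


def spike_window_samples(fs_hz: float) -> tuple[int, int]:
    """Pre / post lengths of the spike cutout window.

    The cutout spans 1 ms before the threshold crossing and 2 ms after it
    (3 ms total; 75 samples at 25 kHz).  Returns ``(n_pre, n_post)`` with the
    crossing sample being the first sample of the post segment.
    """
    return round(0.001 * fs_hz), round(0.002 * fs_hz)
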