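"""Shared in-memory containers for epoched recordings and forward/inverse operators.

Conventions
-----------
* Epoched data arrays are ``(n_channels, n_times, n_trials)``.
* EEG amplitudes are in microvolts, EMG in millivolts.
* Time axes are in milliseconds relative to the TMS pulse (t = 0).
* Source positions are MNI coordinates in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EpochedRecording:
    """Stimulus-locked epoched multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_times, n_trials)
        Signal amplitudes (µV for EEG, mV for EMG).
    fs : float
        Sampling rate in Hz.
    time_ms : ndarray, shape (n_times,)
        Time axis in ms relative to the pulse; strictly increasing.
    labels : list of str
        Channel names.
    role : {'eeg', 'emg'}
    """

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    labels: list[str]
    role: str = "eeg"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_times, n_trials)")
        if self.time_ms.ndim != 1 or len(self.time_ms) != self.data.shape[1]:
            raise ValueError("time_ms length must match data's time dimension")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match channel count")
        if self.role not in ("eeg", "emg"):
            raise ValueError("role must be 'eeg' or 'emg'")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            self.data.copy(), self.fs, self.time_ms.copy(), list(self.labels), self.role
        )


@dataclass
class LeadField:
    """Sensor-to-source forward map.

    ``gain`` is ``(n_sensors, n_sources, 3)`` for a free-orientation (vector)
    lead field, or ``(n_sensors, n_sources)`` after orientation reduction, in
    which case ``orientations`` stores the retained unit dipole orientation
    per source.
    """

    gain: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray | None = None
    sensor_positions: np.ndarray | None = None
    captured_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead-field gain contains non-finite values")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("source positions contain non-finite values")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sources, 3)")
        if self.gain.shape[1] != self.positions.shape[0]:
            raise ValueError("gain source dimension must match positions")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("reduced orientations must be unit norm")

    @property
    def is_scalar(self) -> bool:
        return self.gain.ndim == 2

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SpatialFilter:
    """Linear inverse operator mapping sensor data to source amplitudes.

    ``weights`` is ``(n_sources, n_sensors)``; ``voxel_weights`` holds the
    converged per-voxel weight diagonal of the iterative eLORETA scheme.
    """

    weights: np.ndarray
    regularization: float
    iterations_used: int
    converged: bool
    voxel_weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("spatial filter weights contain non-finite values")

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.weights.shape[1]
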