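"""EMG envelope extraction and trajectory smoothing.

Raw surface EMG is converted to a non-negative activation envelope by the
standard chain: high-pass (removes motion artefact and baseline drift),
full-wave rectification, then low-pass (extracts the slow amplitude
modulation that tracks muscle activation).  All filters are second-order
Butterworth.  Filtering is causal by default, matching a real-time visual
feedback loop; a zero-phase option is available for offline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Fixed channel order used throughout the package.
CHANNELS = ("FCR", "FCU", "ECRL", "ECU")

#: Default cut-off frequencies (Hz) of the envelope chain.
HIGHPASS_HZ = 20.0
LOWPASS_HZ = 5.0

#: Initial stretch treated as filter warm-up and excluded from averages (s).
WARMUP_S = 0.5


@dataclass
class EmgRecording:
    """Synchronised raw EMG (4 channels) and wrist force (2 axes).

    Force axes: X = flexion-extension (extension positive), Y = radial-ulnar
    deviation (radial positive).  EMG channels follow :data:`CHANNELS`.
    """

    time: np.ndarray          # (n,) seconds, uniform grid
    emg: np.ndarray           # (n, 4) raw EMG, arbitrary units
    force: np.ndarray         # (n, 2) force in N
    fs: float = 1000.0        # sampling rate, Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        n = self.time.shape[0]
        if self.emg.shape != (n, 4):
            raise ValueError(f"emg must be (n, 4); got {self.emg.shape}")
        if self.force.shape != (n, 2):
            raise ValueError(f"force must be (n, 2); got {self.force.shape}")
        for name, arr in (("emg", self.emg), ("force", self.force)):
            bad = ~np.isfinite(arr)
            if bad.any():
                ch = int(np.argwhere(bad.any(axis=0))[0][0])
                raise ValueError(f"non-finite samples in {name} channel {ch}")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EnvelopeRecording:
    """Non-negative EMG envelope alpha(t) with pass-through force f(t)."""

    time: np.ndarray          # (n,) seconds
    envelope: np.ndarray      # (n, 4) >= 0
    force: np.ndarray         # (n, 2) N
    fs: float = 1000.0
    warmup_s: float = WARMUP_S

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.envelope = np.atleast_2d(np.asarray(self.envelope, dtype=float))
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        if (self.envelope < 0).any():
            raise ValueError("envelope must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def analysis_slice(self) -> slice:
        """Samples past the filter warm-up."""
        return slice(int(round(self.warmup_s * self.fs)), None)

    def mean_envelope(self, window_s: float | None = None) -> np.ndarray:
        """Mean envelope over the final ``window_s`` seconds (post warm-up).

        With ``window_s=None`` the average runs over everything after the
        warm-up stretch.
        """
        if window_s is None:
            seg = self.envelope[self.analysis_slice()]
        else:
            n = int(round(window_s * self.fs))
            if n > self.n_samples:
                raise ValueError("window longer than recording")
            seg = self.envelope[-n:]
        return seg.mean(axis=0)

    def mean_force(self, window_s: float | None = None) -> np.ndarray:
        if window_s is None:
            seg = self.force[self.analysis_slice()]
        else:
            n = int(round(window_s * self.fs))
            if n > self.n_samples:
                raise ValueError("window longer than recording")
            seg = self.force[-n:]
        return seg.mean(axis=0)


def _butter_filter(x: np.ndarray, fs: float, cutoff: float, btype: str,
                   zero_phase: bool, order: int = 2) -> np.ndarray:
    if cutoff >= fs / 2:
        raise ValueError(f"cut-off {cutoff} Hz not below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=0)
    return signal.sosfilt(sos, x, axis=0)


def emg_envelope(raw: EmgRecording, *, zero_phase: bool = False) -> EnvelopeRecording:
    """Extract the EMG activation envelope from a raw recording.

    Per channel: second-order Butterworth high-pass at 20 Hz, full-wave
    rectification, second-order Butterworth low-pass at 5 Hz.  Small negative
    low-pass ringing is clipped to zero so the non-negativity the downstream
    cone construction relies on holds exactly.  Force channels pass through
    unchanged.
    """
    if raw.fs < 100.0:
        raise ValueError(f"sampling rate {raw.fs} Hz too low for 20 Hz high-pass")
    if raw.duration < 1.0:
        raise ValueError("need at least 1 s of samples")
    hp = _butter_filter(raw.emg, raw.fs, HIGHPASS_HZ, "highpass", zero_phase)
    rect = np.abs(hp)
    env = _butter_filter(rect, raw.fs, LOWPASS_HZ, "lowpass", zero_phase)
    np.clip(env, 0.0, None, out=env)
    return EnvelopeRecording(time=raw.time, envelope=env,
                             force=raw.force.copy(), fs=raw.fs)


def smooth_trajectory(trace: np.ndarray, fs: float, cutoff: float = 3.0,
                      *, zero_phase: bool = False) -> np.ndarray:
    """Low-pass a 2-D trajectory (second-order Butterworth, default 3 Hz).

    Applied to null-space cursor trajectories before speed-peak counting.
    The causal filter is initialised at the trace's first sample so a
    resting cursor produces no start-up transient (a constant trace passes
    through unchanged).
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    if trace.shape[0] < max(16, int(0.05 * fs)):
        raise ValueError("trace shorter than filter warm-up")
    if cutoff >= fs / 2:
        raise ValueError(f"cut-off {cutoff} Hz not below Nyquist {fs / 2} Hz")
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, trace, axis=0)
    zi = signal.sosfilt_zi(sos)  # (n_sections, 2)
    out = np.empty_like(trace)
    for j in range(trace.shape[1]):
        out[:, j], _ = signal.sosfilt(sos, trace[:, j],
                                      zi=zi * trace[0, j])
    return out
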