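"""Band-pass filtering, adaptive-threshold spike detection, and alignment.

The detector follows the classic adaptive scheme for extracellular data:
the signal is band-pass filtered (200–3000 Hz, 2nd-order Butterworth), a
robust noise level is re-estimated every second, and a spike event starts
whenever the signal crosses ``+k·σ`` or ``−k·σ`` (``k = 4`` by default).
All crossings within one 3 ms window collapse into a single event, so a
biphasic spike crossing both polarities is detected once.  Each event is
cut as a 3 ms window (1 ms before the crossing, 2 ms after; 75 samples at
25 kHz) and re-cut so the sample of maximum absolute amplitude sits exactly
1 ms into the window.

:class:`SpikeDetector` is incremental: it accepts filtered samples in
chunks of any size and emits each event exactly once, which makes the
off-line and block-streaming paths identical by construction.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import (
    BoundaryError,
    InputError,
    SpikeWaveform,
    Trace,
    spike_window_samples,
)

__all__ = [
    "bandpass",
    "noise_level",
    "robust_sd",
    "SpikeDetector",
    "detect_spikes",
    "detect_and_extract",
    "cut_window",
    "align_peak",
]


def bandpass_sos(fs_hz: float, low_hz: float = 200.0, high_hz: float = 3000.0,
                 order: int = 2) -> np.ndarray:
    """Second-order-sections of the detection band-pass filter."""
    nyq = fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InputError("filter band must lie inside (0, fs/2)")
    return sps.butter(order, [low_hz / nyq, high_hz / nyq],
                      btype="bandpass", output="sos")


def bandpass(trace: Trace, low_hz: float = 200.0, high_hz: float = 3000.0,
             order: int = 2, zero_phase: bool = False) -> Trace:
    """Band-pass filter a trace (causal by default, matching on-line use)."""
    sos = bandpass_sos(trace.fs_hz, low_hz, high_hz, order)
    if zero_phase:
        y = sps.sosfiltfilt(sos, trace.samples)
    else:
        y = sps.sosfilt(sos, trace.samples)
    return Trace(y, trace.fs_hz, trace.channel_id)


def robust_sd(x: np.ndarray) -> float:
    """MAD-based noise SD estimate, ``median(|x|) / 0.6745``.

    Robust to the heavy tails that spike transients add on top of the
    background noise; exact for zero-median Gaussian noise.
    """
    return float(np.median(np.abs(x)) / 0.6745)


def noise_level(trace: Trace, window_s: float = 1.0,
                estimator=robust_sd) -> np.ndarray:
    """Per-window noise SD estimates over consecutive windows."""
    win = int(round(window_s * trace.fs_hz))
    if len(trace) < win:
        raise InputError("trace shorter than one noise window")
    n_win = len(trace) // win
    blocks = trace.samples[: n_win * win].reshape(n_win, win)
    return np.array([estimator(b) for b in blocks])


class SpikeDetector:
    """Incremental dual-threshold detector with 1-second noise updates.

    Feed *filtered* samples with :meth:`process`; call :meth:`flush` at the
    end of the stream.  Both return the newly completed, peak-aligned
    :class:`SpikeWaveform` objects.  The noise level applied to a 1-second
    window is the estimate from the previous window (causal); the very
    first window uses its own estimate, which costs at most one second of
    start-up latency.
    """

    def __init__(self, fs_hz: float, k: float = 4.0, window_s: float = 1.0,
                 estimator=robust_sd, channel_id: int = 0):
        self.fs_hz = fs_hz
        self.k = k
        self.win = int(round(window_s * fs_hz))
        self.estimator = estimator
        self.channel_id = channel_id
        self.n_pre, self.n_post = spike_window_samples(fs_hz)
        self.n_win_samples = self.n_pre + self.n_post  # 3 ms dead time
        self.lookahead = 2 * self.n_post  # cut + re-cut both need 2 ms

        self._buf = np.empty(0, dtype=np.float64)
        self._buf_start = 0  # absolute index of _buf[0]
        self._n_seen = 0  # absolute count of samples received
        self._scanned_until = 0  # absolute index detection has covered
        self._sigma: float | None = None
        self._next_allowed = 0  # dead-time state (absolute)
        self._pending: list[int] = []  # crossings awaiting lookahead samples

    # ------------------------------------------------------------------
    def process(self, samples: np.ndarray) -> list[SpikeWaveform]:
        """Consume a chunk of filtered samples; return completed events."""
        samples = np.asarray(samples, dtype=np.float64)
        if samples.size:
            self._buf = np.concatenate([self._buf, samples])
            self._n_seen += len(samples)
        out = self._advance(final=False)
        self._trim()
        return out

    def flush(self) -> list[SpikeWaveform]:
        """Finish the stream: scan the last partial window, emit what fits."""
        return self._advance(final=True)

    # ------------------------------------------------------------------
    def _advance(self, final: bool) -> list[SpikeWaveform]:
        # complete full 1-s windows
        while self._n_seen - self._scanned_until >= self.win:
            lo = self._scanned_until
            hi = lo + self.win
            window = self._abs(lo, hi)
            sigma_here = self.estimator(window)
            if self._sigma is None:
                self._sigma = sigma_here  # first window: use its own estimate
            self._scan(lo, hi, self._sigma)
            self._sigma = sigma_here
            self._scanned_until = hi
        if final and self._n_seen > self._scanned_until:
            if self._sigma is None:
                # stream shorter than one window: estimate from what we have
                self._sigma = self.estimator(self._abs(self._scanned_until,
                                                       self._n_seen))
            self._scan(self._scanned_until, self._n_seen, self._sigma)
            self._scanned_until = self._n_seen
        return self._emit(final)

    def _abs(self, lo: int, hi: int) -> np.ndarray:
        return self._buf[lo - self._buf_start: hi - self._buf_start]

    def _scan(self, lo: int, hi: int, sigma: float) -> None:
        x = self._abs(lo, hi)
        thr = self.k * sigma
        if thr <= 0:
            return
        idx = np.flatnonzero(np.abs(x) >= thr)
        for i in idx:
            t = lo + int(i)
            if t < self._next_allowed:
                continue
            if t < self.n_pre:
                continue  # cannot cut the 1 ms pre-segment
            self._pending.append(t)
            self._next_allowed = t + self.n_win_samples

    def _emit(self, final: bool) -> list[SpikeWaveform]:
        out: list[SpikeWaveform] = []
        remaining: list[int] = []
        for t in self._pending:
            if t + self.lookahead <= self._n_seen:
                out.append(self._cut_aligned(t))
            elif final:
                pass  # too close to the end of the stream: dropped
            else:
                remaining.append(t)
        self._pending = remaining
        return out

    def _cut_aligned(self, t_cross: int) -> SpikeWaveform:
        start = t_cross - self.n_pre
        w = self._abs(start, start + self.n_win_samples)
        peak = start + int(np.argmax(np.abs(w)))  # earliest maximal |sample|
        new_start = peak - self.n_pre
        aligned = self._abs(new_start, new_start + self.n_win_samples)
        return SpikeWaveform(aligned.copy(), t_cross=t_cross,
                             t_start=new_start, channel_id=self.channel_id)

    def _trim(self) -> None:
        # keep enough history for pending events and the next re-cut
        keep_from = self._scanned_until - self.win - self.n_win_samples
        if self._pending:
            keep_from = min(keep_from, min(self._pending) - self.n_pre)
        keep_from = max(keep_from, self._buf_start)
        if keep_from > self._buf_start:
            self._buf = self._buf[keep_from - self._buf_start:]
            self._buf_start = keep_from


def detect_and_extract(trace: Trace, k: float = 4.0, window_s: float = 1.0,
                       estimator=robust_sd) -> list[SpikeWaveform]:
    """Detect spikes in a (filtered) trace; return aligned 3 ms waveforms."""
    det = SpikeDetector(trace.fs_hz, k=k, window_s=window_s,
                        estimator=estimator, channel_id=trace.channel_id)
    out = det.process(trace.samples)
    out.extend(det.flush())
    return out


def detect_spikes(trace: Trace, k: float = 4.0, window_s: float = 1.0,
                  estimator=robust_sd) -> np.ndarray:
    """Sorted threshold-crossing sample indices of the detected events."""
    waves = detect_and_extract(trace, k=k, window_s=window_s,
                               estimator=estimator)
    return np.asarray([w.t_cross for w in waves], dtype=np.int64)


def cut_window(trace: Trace, t_cross: int) -> SpikeWaveform:
    """Cut the 3 ms window around a threshold crossing (1 ms pre, 2 ms post)."""
    n_pre, n_post = spike_window_samples(trace.fs_hz)
    start = int(t_cross) - n_pre
    stop = int(t_cross) + n_post
    if start < 0 or stop > len(trace):
        raise BoundaryError(
            f"window [{start}, {stop}) exceeds trace bounds [0, {len(trace)})"
        )
    return SpikeWaveform(trace.samples[start:stop].copy(), t_cross=int(t_cross),
                         t_start=start, channel_id=trace.channel_id)


def align_peak(trace: Trace, waveform: SpikeWaveform) -> SpikeWaveform:
    """Re-cut a window so the maximum |amplitude| sample sits 1 ms in.

    The peak search is restricted to the original window; ties go to the
    earliest sample.  Idempotent for already-aligned waveforms.
    """
    n_pre, _ = spike_window_samples(trace.fs_hz)
    peak = waveform.t_start + int(np.argmax(np.abs(waveform.samples)))
    new_start = peak - n_pre
    stop = new_start + len(waveform)
    if new_start < 0 or stop > len(trace):
        raise BoundaryError("aligned window exceeds trace bounds")
    return SpikeWaveform(trace.samples[new_start:stop].copy(),
                         t_cross=waveform.t_cross, t_start=new_start,
                         channel_id=waveform.channel_id)
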