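"""Calcium-imaging forward model and spike re-extraction.

Spike trains are convolved with a rise/decay calcium response kernel
``A exp(-t/tau_decay) (1 - exp(-t/tau_rise))``, optionally corrupted with
white acquisition noise (sd given as a fraction of the kernel amplitude A),
down-sampled to the imaging frame interval, and binarized again with a
derivative-threshold onset/offset detector.  The binary raster — not the
fluorescence itself — is the input to the transfer-entropy stage, mimicking
the usual processing of cultured-network calcium recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .dynamics import SpikeTrainSet

__all__ = [
    "CalciumKernelParams",
    "CalciumRaster",
    "BinaryRaster",
    "calcium_kernel",
    "convolve_calcium",
    "add_noise",
    "downsample",
    "bin_spikes",
    "make_calcium_raster",
    "detect_spikes",
    "detection_accuracy",
]


@dataclass
class CalciumKernelParams:
    """Calcium response kernel: exponential rise and decay per spike."""

    amplitude: float = 1.0
    tau_rise: float = 10.0      # ms
    tau_decay: float = 700.0    # ms
    noise_sd_fraction: float = 0.1  # acquisition noise sd as fraction of amplitude

    def __post_init__(self):
        if not self.tau_rise < self.tau_decay:
            raise ValueError("require tau_rise < tau_decay")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")

    @property
    def peak_time(self) -> float:
        """Analytic argmax of the kernel: tau_rise * ln((tau_rise+tau_decay)/tau_rise)."""
        return self.tau_rise * np.log((self.tau_rise + self.tau_decay) / self.tau_rise)


@dataclass
class CalciumRaster:
    """Neurons x bins fluorescence matrix at the imaging bin size."""

    traces: np.ndarray
    bin_size: float  # ms
    noisy: bool = False

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_bins(self) -> int:
        return self.traces.shape[1]

    @property
    def network_average(self) -> np.ndarray:
        return self.traces.mean(axis=0)

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.traces, fmt="%.6g")


@dataclass
class BinaryRaster:
    """Neurons x bins 0/1 activity matrix."""

    states: np.ndarray
    bin_size: float  # ms
    provenance: str = "true_spikes"  # or detected_from_{deterministic,noisy}

    def __post_init__(self):
        self.states = np.asarray(self.states)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("binary raster entries must be 0 or 1")

    @property
    def n_neurons(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.states, fmt="%d")

    @classmethod
    def load(cls, path: str | Path, bin_size: float = np.nan, provenance: str = "loaded"):
        return cls(np.atleast_2d(np.loadtxt(path)).astype(np.int8), bin_size, provenance)


def calcium_kernel(t, params: CalciumKernelParams | None = None):
    """Evaluate the causal calcium kernel at times ``t`` (ms since spike)."""
    params = params or CalciumKernelParams()
    t = np.asarray(t, dtype=float)
    out = np.where(
        t >= 0,
        params.amplitude
        * np.exp(-t / params.tau_decay)
        * (1.0 - np.exp(-t / params.tau_rise)),
        0.0,
    )
    return out if out.ndim else float(out)


def _spike_impulses(spikes: SpikeTrainSet, dt: float) -> np.ndarray:
    """Spike trains as delta impulses on the integration grid."""
    n_samples = int(round(spikes.duration / dt))
    imp = np.zeros((spikes.n_neurons, n_samples))
    for i, st in enumerate(spikes.spike_times):
        idx = np.minimum(np.floor(st / dt + 1e-9).astype(int), n_samples - 1)
        np.add.at(imp[i], idx, 1.0)
    return imp


def convolve_calcium(
    spikes: SpikeTrainSet, kernel: CalciumKernelParams | None = None, dt: float | None = None
) -> np.ndarray:
    """Superpose one causal kernel per spike on the simulation grid.

    The kernel is the difference of two exponentials
    (``exp(-t/tau_decay) - exp(-t/(1/ (1/tau_decay + 1/tau_rise)))``), so the
    convolution is computed with two exact recursive exponential filters
    rather than an explicit kernel sum; on the spike grid this is exact.
    """
    kernel = kernel or CalciumKernelParams()
    dt = spikes.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    imp = _spike_impulses(spikes, dt)
    tau_fast = 1.0 / (1.0 / kernel.tau_decay + 1.0 / kernel.tau_rise)
    a_slow = np.exp(-dt / kernel.tau_decay)
    a_fast = np.exp(-dt / tau_fast)
    slow = lfilter([1.0], [1.0, -a_slow], imp, axis=1)
    fast = lfilter([1.0], [1.0, -a_fast], imp, axis=1)
    return kernel.amplitude * (slow - fast)


def add_noise(
    traces: np.ndarray,
    noise_sd_fraction: float,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add i.i.d. Gaussian acquisition noise N(0, (fraction*A)^2) per sample."""
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    if noise_sd_fraction == 0:
        return traces.copy()
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    return traces + rng.normal(0.0, noise_sd_fraction * amplitude, size=traces.shape)


def downsample(traces: np.ndarray, bin_size: float, dt: float) -> np.ndarray:
    """Decimate full-resolution traces to one sample per imaging bin.

    Bins are half-open ``[k*bin, (k+1)*bin)``; the retained sample is the
    last one inside each bin (frame captured at the end of the exposure), so
    a spike occurring anywhere in bin k is already visible in bin k's frame.
    """
    stride = bin_size / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"bin_size {bin_size} must be an integer multiple of dt {dt}")
    stride = int(round(stride))
    n_bins = traces.shape[1] // stride
    idx = np.arange(1, n_bins + 1) * stride - 1
    return traces[:, idx]


def bin_spikes(spikes: SpikeTrainSet, bin_size: float) -> BinaryRaster:
    """Binarize true spike trains: bin k is 1 iff >= 1 spike in [k*bin, (k+1)*bin)."""
    n_bins = int(spikes.duration // bin_size)
    states = np.zeros((spikes.n_neurons, n_bins), dtype=np.int8)
    for i, st in enumerate(spikes.spike_times):
        idx = (st / bin_size).astype(int)
        idx = idx[idx < n_bins]
        states[i, idx] = 1
    return BinaryRaster(states, bin_size, provenance="true_spikes")


def make_calcium_raster(
    spikes: SpikeTrainSet,
    bin_size: float,
    kernel: CalciumKernelParams | None = None,
    noisy: bool = False,
    seed: int = 0,
) -> CalciumRaster:
    """Full forward model: convolve, (optionally) add noise, down-sample.

    Processes one neuron at a time so the full-resolution trace is never
    materialized for the whole population.  White noise is i.i.d. per
    full-resolution sample, so adding it to the retained (decimated) samples
    is distributionally identical to adding it before decimation.
    """
    kernel = kernel or CalciumKernelParams()
    dt = spikes.dt
    stride = bin_size / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"bin_size {bin_size} must be an integer multiple of dt {dt}")
    stride = int(round(stride))
    n_samples = int(round(spikes.duration / dt))
    n_bins = n_samples // stride
    idx = np.arange(1, n_bins + 1) * stride - 1

    tau_fast = 1.0 / (1.0 / kernel.tau_decay + 1.0 / kernel.tau_rise)
    a_slow = np.exp(-dt / kernel.tau_decay)
    a_fast = np.exp(-dt / tau_fast)

    traces = np.empty((spikes.n_neurons, n_bins))
    row = np.zeros(n_samples)
    for i, st in enumerate(spikes.spike_times):
        row[:] = 0.0
        sp_idx = np.minimum(np.floor(st / dt + 1e-9).astype(int), n_samples - 1)
        np.add.at(row, sp_idx, 1.0)
        slow = lfilter([1.0], [1.0, -a_slow], row)
        fast = lfilter([1.0], [1.0, -a_fast], row)
        traces[i] = kernel.amplitude * (slow[idx] - fast[idx])
    if noisy:
        traces = add_noise(traces, kernel.noise_sd_fraction, kernel.amplitude, seed)
    return CalciumRaster(traces, bin_size, noisy=noisy)


def detect_spikes(
    calcium: CalciumRaster,
    onset_threshold: float,
    offset_threshold: float,
    confirm_bins: int = 0,
    sustain_threshold: float | None = None,
    backfill: bool = False,
) -> BinaryRaster:
    """Re-extract binary activity from coarse calcium by derivative thresholds.

    Scans the first difference of each down-sampled trace.  An onset opens
    an active segment when the derivative exceeds ``onset_threshold`` and
    stays positive for ``confirm_bins`` further bins (discarding isolated
    noise fluctuations); the segment closes at the first later bin whose
    derivative falls below ``sustain_threshold`` (or at the trace end), and
    every bin in [onset, offset) is labelled 1.

    With ``sustain_threshold=None`` the close criterion is
    ``offset_threshold`` (the classic two-threshold rule); that marks the
    whole rising phase of the fluorescence transient and so extends each
    activation by several bins beyond the spikes.  A positive
    ``sustain_threshold`` keeps a segment open only while the signal still
    rises fast, i.e. while the cell keeps spiking, which reconstructs the
    coarse spike train almost bin-for-bin.

    ``backfill`` additionally marks the bin preceding a confirmed onset when
    the signal was already rising there: a spike late in a frame deposits
    most of its fluorescence rise in the next frame, so the onset fires one
    bin after the true spike bin unless that partial rise is honoured.
    """
    if not (onset_threshold > 0 > offset_threshold):
        raise ValueError("require onset_threshold > 0 > offset_threshold")
    close_at = offset_threshold if sustain_threshold is None else sustain_threshold
    traces = calcium.traces
    n, n_bins = traces.shape
    states = np.zeros((n, n_bins), dtype=np.int8)
    diff = np.diff(traces, axis=1)  # diff[:, k] = trace[k+1] - trace[k]
    for i in range(n):
        d = diff[i]
        k = 0
        while k < len(d):
            if d[k] > onset_threshold and (d[k + 1 : k + 1 + confirm_bins] > 0).all():
                onset = k + 1  # first bin reflecting the rise
                start = onset - 1 if (backfill and k >= 1 and d[k - 1] > 0) else onset
                off = onset
                while off < len(d) and d[off] >= close_at:
                    off += 1
                states[i, start : off + 1] = 1
                k = off + 1
            else:
                k += 1
    prov = "detected_from_noisy" if calcium.noisy else "detected_from_deterministic"
    return BinaryRaster(states, calcium.bin_size, provenance=prov)


def detection_accuracy(detected: BinaryRaster, true_raster: BinaryRaster) -> float:
    """Fraction of true spike bins overlapped by detected-active bins.

    Spike-recovery (sensitivity-style) score: the detector marks whole
    rising-phase segments, so matching is asked only of the bins that truly
    contain spikes.
    """
    n_bins = min(detected.n_bins, true_raster.n_bins)
    det = detected.states[:, :n_bins].astype(bool)
    tru = true_raster.states[:, :n_bins].astype(bool)
    n_events = tru.sum()
    if n_events == 0:
        return float("nan")
    return float((det & tru).sum() / n_events)
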