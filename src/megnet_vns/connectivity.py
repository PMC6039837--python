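"""Phase-locking-value (PLV) functional connectivity.

The PLV between two channels is the magnitude of the time-averaged unit
phasor of their instantaneous phase difference,

    PLV = | E[ exp(j (phi_1(t) - phi_2(t))) ] |,

estimated per 3-s epoch and per narrow frequency bin, then averaged over
epochs and over the bins belonging to a canonical band.  PLV is 0 for
unrelated phases and 1 for perfect phase locking; being amplitude-blind it
captures weak synchronisation regimes where amplitudes are uncoupled.

Band-averaged PLV matrices are the substrate for the graph-topology stage:
connectivity here is sensor-space, with no source reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "DEFAULT_BIN_CENTERS",
    "TimeSeriesRun",
    "BandConnectivity",
    "segment_epochs",
    "bin_phase",
    "plv_pair",
    "band_plv_matrix",
    "all_band_plv_matrices",
    "bins_in_band",
]

#: Canonical band edges in Hz, half-open intervals [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

#: 25 one-Hz-wide analysis bins spanning 4-30 Hz (centers 4..28 Hz).
DEFAULT_BIN_CENTERS: np.ndarray = np.arange(4.0, 29.0)


@dataclass
class TimeSeriesRun:
    """One resting-state run: channels x samples array plus metadata."""

    data: np.ndarray
    fs_hz: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("a run needs at least 2 channels")
        if not np.isfinite(self.data).all():
            raise ValueError("run data contains NaN or infinite samples")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class BandConnectivity:
    """Symmetric PLV matrix for one run and band; zero diagonal by convention."""

    matrix: np.ndarray
    band: str
    n_epochs_used: int
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if m.min() < -1e-9 or m.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


def segment_epochs(run: TimeSeriesRun, epoch_len_s: float = 3.0) -> list[np.ndarray]:
    """Cut a run into consecutive non-overlapping epochs.

    The trailing partial epoch is discarded, so the count is
    ``floor(duration / epoch_len_s)``.  Raises if the run is shorter than a
    single epoch.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch length must be positive")
    n_per = int(round(epoch_len_s * run.fs_hz))
    if n_per < 1 or run.n_samples < n_per:
        raise ValueError(
            f"run of {run.duration_s:.2f}s is shorter than one {epoch_len_s}s epoch"
        )
    n_epochs = run.n_samples // n_per
    return [run.data[:, i * n_per : (i + 1) * n_per] for i in range(n_epochs)]


def _design_bandpass(fs_hz: float, center_hz: float, bandwidth_hz: float, order: int):
    lo = center_hz - bandwidth_hz / 2.0
    hi = center_hz + bandwidth_hz / 2.0
    nyq = fs_hz / 2.0
    if hi >= nyq or lo <= 0:
        raise ValueError(
            f"bin at {center_hz} Hz (width {bandwidth_hz}) outside (0, Nyquist={nyq})"
        )
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def bin_phase(
    epoch: np.ndarray,
    fs_hz: float,
    bin_center_hz: float,
    bandwidth_hz: float = 1.0,
    order: int = 2,
    trim_edges: int = 0,
) -> np.ndarray:
    """Instantaneous phase of each channel in a 1-Hz analysis bin.

    Zero-phase band-pass (Butterworth of order ``2*order`` via forward-backward
    filtering) around the bin center, followed by the analytic-signal phase in
    (-pi, pi].  ``trim_edges`` samples may be dropped from each end to discard
    filter transients when filtering short segments.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    sos = _design_bandpass(fs_hz, bin_center_hz, bandwidth_hz, order)
    filtered = sps.sosfiltfilt(sos, x, axis=-1)
    phase = np.angle(sps.hilbert(filtered, axis=-1))
    if trim_edges:
        if 2 * trim_edges >= phase.shape[-1]:
            raise ValueError("trim_edges removes the entire epoch")
        phase = phase[..., trim_edges:-trim_edges]
    return phase


def plv_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLV of two equal-length phase series: ``|mean(exp(j*(a-b)))|``."""
    a = np.asarray(phase_a, dtype=float).ravel()
    b = np.asarray(phase_b, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty phase series")
    if a.size != b.size:
        raise ValueError("phase series lengths differ")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def bins_in_band(band: str, bin_centers: np.ndarray | None = None) -> np.ndarray:
    """Bin centers assigned to a band (half-open interval on the bin center)."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    centers = DEFAULT_BIN_CENTERS if bin_centers is None else np.asarray(bin_centers, float)
    lo, hi = BANDS[band]
    chosen = centers[(centers >= lo) & (centers < hi)]
    if chosen.size == 0:
        raise ValueError(f"no analysis bins fall inside band {band!r}")
    return chosen


def _epoch_plv_matrices(phase: np.ndarray, n_per_epoch: int) -> np.ndarray:
    """Mean over epochs of per-epoch PLV matrices from a channels x samples phase array."""
    n_ch, n_samp = phase.shape
    n_epochs = n_samp // n_per_epoch
    acc = np.zeros((n_ch, n_ch))
    phasor = np.exp(1j * phase)
    for e in range(n_epochs):
        seg = phasor[:, e * n_per_epoch : (e + 1) * n_per_epoch]
        acc += np.abs(seg @ seg.conj().T) / n_per_epoch
    return acc / n_epochs


def all_band_plv_matrices(
    run: TimeSeriesRun,
    bands: list[str] | None = None,
    epoch_len_s: float = 3.0,
    bin_centers: np.ndarray | None = None,
    bandwidth_hz: float = 1.0,
    order: int = 2,
) -> dict[str, BandConnectivity]:
    """PLV matrices for several bands in one pass over the analysis bins.

    Each bin is band-passed and phase-extracted on the continuous run (one
    zero-phase filter per bin rather than one per epoch, which avoids
    narrow-band transients dominating 3-s segments); the phase series is then
    segmented into epochs, PLV is computed per epoch, averaged over epochs,
    and finally averaged over the bins of each band.  That order — epochs
    first, then bins — is fixed.
    """
    bands = list(BANDS) if bands is None else bands
    centers = DEFAULT_BIN_CENTERS if bin_centers is None else np.asarray(bin_centers, float)
    band_bins = {band: bins_in_band(band, centers) for band in bands}

    n_per = int(round(epoch_len_s * run.fs_hz))
    if run.n_samples < n_per:
        raise ValueError("run shorter than one epoch")
    n_epochs = run.n_samples // n_per

    needed = sorted({float(c) for bs in band_bins.values() for c in bs})
    per_bin: dict[float, np.ndarray] = {}
    for c in needed:
        phase = bin_phase(run.data, run.fs_hz, c, bandwidth_hz=bandwidth_hz, order=order)
        per_bin[c] = _epoch_plv_matrices(phase, n_per)

    out: dict[str, BandConnectivity] = {}
    for band, bs in band_bins.items():
        m = np.mean([per_bin[float(c)] for c in bs], axis=0)
        m = np.clip((m + m.T) / 2.0, 0.0, 1.0)
        out[band] = BandConnectivity(
            matrix=m, band=band, n_epochs_used=n_epochs,
            channel_names=list(run.channel_names),
        )
    return out


def band_plv_matrix(
    run: TimeSeriesRun,
    band: str,
    epoch_len_s: float = 3.0,
    bin_centers: np.ndarray | None = None,
    **kwargs,
) -> BandConnectivity:
    """PLV matrix for a single band (see :func:`all_band_plv_matrices`)."""
    return all_band_plv_matrices(
        run, bands=[band], epoch_len_s=epoch_len_s, bin_centers=bin_centers, **kwargs
    )[band]
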