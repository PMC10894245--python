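"""Time-series feature extraction for the spectral analysis pipeline.

Covers the data-preparation steps upstream of model fitting: segmentation of
continuous recordings into 2200 ms epochs tagged by recording condition
(pre / bolus / infusion), Welch cross-spectral estimation on those epochs,
the seven-band zero-phase Butterworth filter bank, and Hilbert amplitude
envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .spectral import SpectralData

__all__ = [
    "Band",
    "BAND_TABLE",
    "band_table_frame",
    "EpochedSeries",
    "epoch",
    "welch_csd",
    "band_filter",
    "hilbert_envelope_mean",
    "load_timeseries",
]

EPOCH_MS = 2200.0
CONDITIONS = ("pre", "bolus", "infusion")


@dataclass(frozen=True)
class Band:
    name: str
    lo: float  # Hz
    hi: float  # Hz


# Seven analysis bands, chosen to avoid MR slice-artifact harmonics.
BAND_TABLE = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("low_beta", 15.0, 26.0),
    Band("high_beta", 28.0, 40.0),
    Band("low_gamma", 42.0, 53.0),
    Band("high_gamma", 55.0, 67.0),
)


def band_table_frame():
    """The band table as a DataFrame (exportable to CSV)."""
    import pandas as pd
    return pd.DataFrame([(b.name, b.lo, b.hi) for b in BAND_TABLE],
                        columns=["band", "lo_hz", "hi_hz"])


@dataclass
class EpochedSeries:
    """Non-overlapping 2200 ms epochs with a condition label per epoch."""

    data: np.ndarray          # (n_epochs, n_channels, n_samples)
    rate: float               # Hz
    conditions: np.ndarray    # (n_epochs,) str labels

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, condition: str) -> "EpochedSeries":
        mask = self.conditions == condition
        return EpochedSeries(self.data[mask], self.rate, self.conditions[mask])


def epoch(series: np.ndarray, rate: float,
          condition_boundaries: dict[str, tuple[float, float]] | None = None
          ) -> EpochedSeries:
    """Cut a (channels, samples) series into consecutive 2200 ms epochs.

    ``condition_boundaries`` maps a condition label to its (start, end) time
    in seconds; an epoch straddling a boundary is assigned to the earlier
    condition when at least half of its samples precede the boundary.  The
    trailing partial segment is discarded.
    """
    series = np.atleast_2d(np.asarray(series, float))
    n_samp = series.shape[1]
    per = rate * EPOCH_MS / 1000.0
    if abs(per - round(per)) > 1.0:
        raise ValueError(
            f"sampling rate {rate} Hz does not give an integer number of "
            "samples per 2200 ms epoch")
    per = int(round(per))
    n_ep = n_samp // per
    if n_ep < 1:
        raise ValueError("series shorter than one 2200 ms epoch")
    data = series[:, :n_ep * per].reshape(series.shape[0], n_ep, per)
    data = np.transpose(data, (1, 0, 2))

    if condition_boundaries is None:
        labels = np.array(["pre"] * n_ep)
    else:
        order = sorted(condition_boundaries, key=lambda k: condition_boundaries[k][0])
        labels = np.empty(n_ep, object)
        for i in range(n_ep):
            mid = (i + 0.5) * per / rate  # epoch midpoint, s
            lab = None
            for name in order:
                start, end = condition_boundaries[name]
                # >= half of the samples before `end` keeps the epoch in the
                # earlier condition
                if mid <= end:
                    lab = name
                    break
            labels[i] = lab if lab is not None else order[-1]
        labels = labels.astype(str)
    return EpochedSeries(data=data, rate=rate, conditions=labels)


def welch_csd(epochs: EpochedSeries, channels: tuple[int, int] = (0, 1),
              grid=None, min_epochs: int = 8) -> SpectralData:
    """Epoch-averaged Hann-tapered cross-spectra, interpolated to ``grid``.

    Each 2200 ms epoch is one (non-overlapping) Welch segment; the averaged
    periodogram cross-spectra are linearly interpolated onto the analysis
    frequency grid.  Output is Hermitian with real diagonals by construction.
    """
    if epochs.n_epochs < min_epochs:
        raise ValueError(
            f"need at least {min_epochs} epochs, got {epochs.n_epochs}")
    x = epochs.data[:, list(channels), :]   # (E, 2, T)
    n_ch = x.shape[1]
    T = x.shape[2]
    win = signal.get_window("hann", T)
    scale = 1.0 / (epochs.rate * (win ** 2).sum())
    xw = (x - x.mean(axis=2, keepdims=True)) * win[None, None, :]
    X = np.fft.rfft(xw, axis=2)
    freqs = np.fft.rfftfreq(T, d=1.0 / epochs.rate)
    # one-sided cross-spectral density, averaged over epochs
    S = np.einsum("eit,ejt->ijt", X, np.conj(X)) / epochs.n_epochs
    S = S * scale
    S[..., 1:] *= 2.0
    if T % 2 == 0:
        S[..., -1] /= 2.0
    S = np.transpose(S, (2, 0, 1))          # (F, 2, 2)
    if grid is None:
        keep = freqs > 0
        return SpectralData(freqs=freqs[keep], S=S[keep]).hermitize()
    grid = np.asarray(grid, float)
    out = np.empty((grid.size, n_ch, n_ch), complex)
    for i in range(n_ch):
        for j in range(n_ch):
            out[:, i, j] = (np.interp(grid, freqs, S[:, i, j].real)
                            + 1j * np.interp(grid, freqs, S[:, i, j].imag))
    return SpectralData(freqs=grid, S=out).hermitize()


def band_filter(series: np.ndarray, band: Band | tuple[float, float],
                rate: float) -> np.ndarray:
    """Fourth-order bidirectional (zero-phase) Butterworth band-pass."""
    lo, hi = (band.lo, band.hi) if isinstance(band, Band) else band
    nyq = rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, float), axis=-1)


def hilbert_envelope_mean(series: np.ndarray, trim: float = 0.1) -> float:
    """Mean of the analytic-signal modulus, with 10% edge-trimming per side."""
    x = np.asarray(series, float).ravel()
    if x.size < 256:
        raise ValueError(f"need at least 256 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    env = np.abs(signal.hilbert(x))
    k = int(round(trim * x.size))
    return float(env[k:x.size - k].mean())


def load_timeseries(path, channels=None):
    """Load a (channels, samples) array plus rate from EDF or delimited text.

    Text files are whitespace/comma-delimited with one channel per column and
    the sampling rate on a ``# rate: <Hz>`` header line.
    """
    path = str(path)
    if path.lower().endswith(".edf"):
        import mne  # optional dependency, only needed for EDF input
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data(picks=channels)
        return data, float(raw.info["sfreq"])
    rate = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "rate" in line:
                rate = float(line.split(":")[1])
            if not line.startswith("#"):
                break
    if rate is None:
        raise ValueError(f"no '# rate: <Hz>' header in {path}")
    arr = np.loadtxt(path, delimiter="," if "," in open(path).readlines()[-1]
                     else None)
    data = np.atleast_2d(arr).T
    if channels is not None:
        data = data[list(channels)]
    return data, rate
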