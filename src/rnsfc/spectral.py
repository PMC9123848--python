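"""Epoch handling, band-pass filtering and imaginary-coherence estimation.

Imaginary coherence (ImCoh) between two signals is the magnitude of the
imaginary part of their coherency -- the cross-spectral density normalized
by the geometric mean of the auto-spectra:

    C(f) = Sxy(f) / sqrt(Sxx(f) * Syy(f)),     ImCoh_band = mean_{f in band} |Im C(f)|

Because any purely instantaneous (zero-lag) linear mixing of sources
produces a real-valued coherency, ImCoh is insensitive to volume
conduction / field spread, which is why it is the connectivity measure of
choice for source-space MEG.

Spectra are Welch estimates (Hann windows, mean-detrended segments).  The
default treats the concatenated 90 s resting segment as continuous with
1 s windows at 50% overlap; an alternative mode estimates per 15 s epoch
and averages.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .bands import BandSpec, CANONICAL_BANDS, get_band
from .containers import EPOCH_LEN_S, ConnectivityRecord, RoiTimeSeries

__all__ = [
    "segment_epochs",
    "select_resting_segment",
    "bandpass",
    "cross_spectra",
    "imaginary_coherence",
    "roi_connectivity",
]


# ---------------------------------------------------------------------------
# epochs

def segment_epochs(ts: RoiTimeSeries, epoch_len: float = EPOCH_LEN_S) -> list[np.ndarray]:
    """Split a recording into consecutive non-overlapping epochs.

    Returns a list of (n_rois, epoch_samples) arrays; a trailing remainder
    shorter than ``epoch_len`` is discarded.
    """
    n_per = int(round(epoch_len * ts.sampling_rate))
    n_epochs = ts.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {ts.duration:.1f} s is shorter than one "
            f"{epoch_len:.0f} s epoch"
        )
    return [ts.data[:, i * n_per : (i + 1) * n_per] for i in range(n_epochs)]


def select_resting_segment(
    epochs: list[np.ndarray], flags: np.ndarray, n: int = 6
) -> np.ndarray:
    """Concatenate the first ``n`` clean epochs in temporal order.

    ``flags`` marks epochs as clean (True).  With 15 s epochs and the
    default ``n=6`` this yields the 90 s resting-state segment.
    """
    flags = np.asarray(flags, dtype=bool)[: len(epochs)]
    clean = np.flatnonzero(flags)
    if len(clean) < n:
        raise ValueError(
            f"need {n} clean epochs but only {len(clean)} are flagged clean "
            f"(short by {n - len(clean)})"
        )
    return np.concatenate([epochs[i] for i in clean[:n]], axis=1)


# ---------------------------------------------------------------------------
# filtering

def _bandpass_sos(band: BandSpec, fs: float) -> np.ndarray:
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_hi} Hz reaches the Nyquist "
            f"frequency {fs / 2:.1f} Hz at sampling rate {fs} Hz"
        )
    return signal.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(series: np.ndarray, band: str | BandSpec, fs: float) -> np.ndarray:
    """Zero-phase band-pass (Butterworth order 4, forward-backward).

    The two-pass application doubles the effective attenuation and cancels
    phase distortion, which would otherwise corrupt the imaginary part of
    the coherency.
    """
    band = get_band(band)
    sos = _bandpass_sos(band, fs)
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# spectra

def _welch_params(fs: float, window_len: float, overlap: float, n_samples: int):
    nperseg = int(round(window_len * fs))
    if nperseg < 2 or nperseg > n_samples:
        raise ValueError(
            f"window of {window_len} s ({nperseg} samples) does not fit the "
            f"{n_samples}-sample series"
        )
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    return nperseg, int(nperseg * overlap)


def cross_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_len: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Welch auto- and cross-spectral densities of two equal-length signals.

    Returns ``(freqs, Sxx, Syy, Sxy)`` with ``Sxy = E[conj(X) Y]`` scaled
    as a one-sided density (Hann window, mean-detrended segments).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("input series contain non-finite samples")
    nperseg, noverlap = _welch_params(fs, window_len, overlap, x.size)
    kw = dict(fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
              detrend="constant", scaling="density")
    freqs, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    _, sxy = signal.csd(x, y, **kw)
    return freqs, sxx, syy, sxy


def _band_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    # closed interval: edge bins shared by adjacent bands belong to both
    return (freqs >= band.f_lo) & (freqs <= band.f_hi)


def _imcoh_from_coherency(im_c: np.ndarray, mode: str, axis: int = 0) -> np.ndarray:
    if mode == "abs_per_bin":
        return np.mean(np.abs(im_c), axis=axis)
    if mode == "abs_of_mean":
        return np.abs(np.mean(im_c, axis=axis))
    raise ValueError(f"mode must be 'abs_per_bin' or 'abs_of_mean', got {mode!r}")


def imaginary_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: str | BandSpec,
    window_len: float = 1.0,
    overlap: float = 0.5,
    mode: str = "abs_per_bin",
) -> float:
    """Band-averaged imaginary coherence of two signals, in [0, 1].

    ``mode='abs_per_bin'`` (default) averages |Im C(f)| over the band's
    frequency bins; ``'abs_of_mean'`` takes the absolute value after
    averaging the signed imaginary parts.
    """
    band = get_band(band)
    freqs, sxx, syy, sxy = cross_spectra(x, y, fs, window_len, overlap)
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise ValueError(f"no frequency bins fall inside band {band.name!r}")
    if np.any(sxx[mask] <= 0) or np.any(syy[mask] <= 0):
        raise ValueError(
            f"zero power in band {band.name!r}: coherency is undefined"
        )
    coh = sxy[mask] / np.sqrt(sxx[mask] * syy[mask])
    return float(np.clip(_imcoh_from_coherency(coh.imag, mode), 0.0, 1.0))


# ---------------------------------------------------------------------------
# multichannel estimation

def _windowed_fft(
    data: np.ndarray, fs: float, window_len: float, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, mean-detrended segment FFTs of all channels.

    Returns ``(freqs, X)`` with ``X`` of shape (n_segments, n_bins,
    n_channels); the same segmentation conventions as the Welch estimator
    in :func:`cross_spectra`, so normalized quantities (coherency) agree
    exactly between the pairwise and matrix paths.
    """
    n_ch, n = data.shape
    nperseg, noverlap = _welch_params(fs, window_len, overlap, n)
    step = nperseg - noverlap
    n_seg = 1 + (n - nperseg) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = data[:, idx]  # (ch, seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = signal.get_window("hann", nperseg)
    spec = np.fft.rfft(segs * win, axis=-1)  # (ch, seg, bins)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.moveaxis(spec, 0, -1)  # (seg, bins, ch)


def _band_imcoh_matrix(
    x_spec: np.ndarray, freqs: np.ndarray, band: BandSpec, mode: str
) -> np.ndarray:
    """ImCoh matrix over all channel pairs from segment spectra."""
    mask = _band_mask(freqs, band)
    if not mask.any():
        raise ValueError(f"no frequency bins fall inside band {band.name!r}")
    xb = x_spec[:, mask, :]  # (seg, bins, ch)
    cross = np.einsum("sfi,sfj->fij", np.conj(xb), xb) / xb.shape[0]
    power = np.einsum("fii->fi", cross).real
    if np.any(power <= 0):
        raise ValueError(f"zero power in band {band.name!r}: coherency is undefined")
    denom = np.sqrt(power[:, :, None] * power[:, None, :])
    im_c = cross.imag / denom
    return np.clip(_imcoh_from_coherency(im_c, mode, axis=0), 0.0, 1.0)


def roi_connectivity(
    ts: RoiTimeSeries,
    bands: dict[str, BandSpec] | None = None,
    window_len: float = 1.0,
    overlap: float = 0.5,
    mode: str = "abs_per_bin",
    per_epoch: bool = False,
) -> list[ConnectivityRecord]:
    """All-pairs ROI-level imaginary coherence, one record per band.

    ``ts.data`` is treated as the analysis segment (epoch selection happens
    upstream).  With ``per_epoch=True`` the estimate is computed separately
    per 15 s epoch and averaged, instead of treating the concatenated
    segment as continuous.
    """
    if ts.n_rois < 2:
        raise ValueError("connectivity needs at least 2 ROIs")
    bands = dict(bands) if bands is not None else dict(CANONICAL_BANDS)
    if per_epoch:
        n_per = int(round(EPOCH_LEN_S * ts.sampling_rate))
        chunks = [
            ts.data[:, i * n_per : (i + 1) * n_per]
            for i in range(ts.n_samples // n_per)
        ]
    else:
        chunks = [ts.data]
    mats: dict[str, list[np.ndarray]] = {name: [] for name in bands}
    for chunk in chunks:
        freqs, spec = _windowed_fft(chunk, ts.sampling_rate, window_len, overlap)
        for name, band in bands.items():
            mats[name].append(_band_imcoh_matrix(spec, freqs, get_band(band), mode))
    records = []
    for name in bands:
        m = np.mean(mats[name], axis=0)
        np.fill_diagonal(m, np.nan)  # self-coherency has no imaginary part
        records.append(
            ConnectivityRecord(
                subject_id=ts.subject_id,
                band=name,
                level="roi",
                ids=list(ts.roi_ids),
                values=m,
            )
        )
    return records
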