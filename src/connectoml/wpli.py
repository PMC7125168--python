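"""Weighted phase lag index (wPLI) estimation from epoched signals.

The wPLI quantifies lagged phase synchrony between two signals from the
imaginary part of their cross-spectrum:

    wPLI = | sum_k Im(Sxy_k) | / sum_k | Im(Sxy_k) |

where the sum runs over epochs and frequency bins ``k`` inside the band and
``Sxy = X(f) * conj(Y(f))`` is the per-epoch cross-spectrum. The estimate
lies in [0, 1], is insensitive to zero-lag (volume-conduction-like) coupling
— a purely real cross-spectrum gives no imaginary mass, which we define as
wPLI = 0 — and reaches 1 when the imaginary part has a consistent sign
across all epochs and bins.
"""

from __future__ import annotations

import numpy as np

from .edges import EdgeIndex, devectorize

__all__ = ["compute_wpli", "wpli_matrix"]


def _band_cross_spectra(epochs: np.ndarray, sfreq: float, band) -> np.ndarray:
    """rfft of (n_epochs, n_channels, n_times) restricted to band bins."""
    f_low, f_high = float(band[0]), float(band[1])
    if not 0 < f_low < f_high:
        raise ValueError(f"invalid band ({f_low}, {f_high})")
    if f_high > sfreq / 2:
        raise ValueError(
            f"band upper edge {f_high} Hz exceeds the Nyquist frequency {sfreq / 2} Hz"
        )
    n_times = epochs.shape[-1]
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    sel = (freqs >= f_low) & (freqs <= f_high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band ({f_low}, {f_high}) Hz")
    return np.fft.rfft(epochs, axis=-1)[..., sel]


def _wpli_from_im(sxy: np.ndarray) -> float:
    im = sxy.imag.copy()
    # floating-point residue of a purely real cross-spectrum must not count
    # as lagged synchrony: drop imaginary mass below 1e-10 of the largest
    # cross-spectral magnitude
    scale = np.abs(sxy).max() if sxy.size else 0.0
    im[np.abs(im) <= 1e-10 * scale] = 0.0
    denom = np.abs(im).sum()
    if denom == 0.0:  # no imaginary cross-spectral mass = no lagged synchrony
        return 0.0
    return float(np.abs(im.sum()) / denom)


def compute_wpli(epochs, sfreq: float, band) -> float:
    """wPLI between two channels over a frequency band.

    Parameters
    ----------
    epochs
        Array of shape ``(n_epochs, 2, n_times)``: at least two epochs of the
        two signals.
    sfreq
        Sampling rate in Hz.
    band
        ``(f_low, f_high)`` in Hz, inside the Nyquist range.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 3 or x.shape[1] != 2:
        raise ValueError(f"expected epochs of shape (n_epochs, 2, n_times), got {x.shape}")
    if x.shape[0] < 2:
        raise ValueError("wPLI needs at least 2 epochs")
    spec = _band_cross_spectra(x, sfreq, band)
    sxy = spec[:, 0, :] * np.conj(spec[:, 1, :])
    return _wpli_from_im(sxy)


def wpli_matrix(epochs, sfreq: float, band, edge_index: EdgeIndex | None = None) -> np.ndarray:
    """All-pairs wPLI for multichannel epochs ``(n_epochs, n_channels, n_times)``.

    Returns a symmetric ``(n_channels, n_channels)`` matrix with zero
    diagonal. ``edge_index`` (if given) only validates the channel count.
    """
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected (n_epochs, n_channels, n_times), got {x.shape}")
    if x.shape[0] < 2:
        raise ValueError("wPLI needs at least 2 epochs")
    n_ch = x.shape[1]
    if edge_index is not None and edge_index.n_regions != n_ch:
        raise ValueError(f"edge index expects {edge_index.n_regions} channels, got {n_ch}")
    spec = _band_cross_spectra(x, sfreq, band)
    iu, ju = np.triu_indices(n_ch, k=1)
    vals = np.empty(len(iu))
    for e, (i, j) in enumerate(zip(iu, ju)):
        vals[e] = _wpli_from_im(spec[:, i, :] * np.conj(spec[:, j, :]))
    if edge_index is not None:
        return devectorize(vals, edge_index)
    m = np.zeros((n_ch, n_ch))
    m[iu, ju] = vals
    m[ju, iu] = vals
    return m
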