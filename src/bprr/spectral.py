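"""Multitaper power spectral estimation and referential rebasing.

Power spectra are estimated on 1 s windows with DPSS (Slepian) tapers,
time–bandwidth NW = 3 and 5 tapers by default (≈3 Hz half-bandwidth),
on a 2–200 Hz grid in 1 Hz steps.  Averaging across windows is the
arithmetic mean on the linear-power scale.

Rebasing removes subject-specific offsets for cross-subject comparison:
all curves are converted to log10 power and a single per-subject scalar
— the median over 2–10 Hz of the electrode-averaged referential
log-spectrum — is subtracted from every curve.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

__all__ = ["SpectrumSet", "BandTable", "DEFAULT_BANDS", "multitaper_psd",
           "multitaper_spectra", "rebase_spectra"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (2, 4),
    "theta": (4, 8),
    "alpha": (8, 13),
    "beta": (13, 25),
    "gamma": (25, 50),
    "high_gamma": (50, 200),
}


@dataclass
class BandTable:
    """Canonical frequency bands, band name → (f_low, f_high) Hz."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if hi <= lo:
                raise ValueError(f"band {name} is empty: ({lo}, {hi})")

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        return (freqs >= lo) & (freqs <= hi)


@dataclass
class SpectrumSet:
    """Power per channel-or-pair × frequency on the 2–200 Hz 1 Hz grid.

    ``scale`` records the transform applied: 'linear' (µV²/Hz), 'log10',
    'sqrt', 'zscore', or 'rebased_log'.
    """

    power: np.ndarray
    frequencies: np.ndarray
    scale: str = "linear"
    n_windows_averaged: int = 1
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, float))
        self.frequencies = np.asarray(self.frequencies, float)
        df = np.diff(self.frequencies)
        if len(df) and not np.all(df > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.scale in ("linear", "sqrt") and np.any(self.power < 0):
            raise ValueError(f"negative power on {self.scale} scale")

    def to_tsv(self, path) -> None:
        cols = [f"f{int(f)}" if float(f).is_integer() else f"f{f}" for f in self.frequencies]
        ids = self.channel_ids or [str(i) for i in range(self.power.shape[0])]
        pd.DataFrame(self.power, index=ids, columns=cols).to_csv(
            path, sep="\t", index_label="channel")


def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    tapers = dpss(n, nw, Kmax=k)
    # unit-energy tapers -> |FFT|^2 * 2/fs is a one-sided density
    return tapers / np.sqrt(np.sum(tapers**2, axis=-1, keepdims=True))


def multitaper_spectra(
    data: np.ndarray,
    fs: float,
    fmin: float = 2.0,
    fmax: float = 200.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    demean: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window multitaper PSD without averaging.

    ``data`` is (..., n_samples) with n_samples = fs (1 s windows);
    returns (psd, freqs) with psd shaped (..., n_freqs) in µV²/Hz on the
    1 Hz grid from ``fmin`` to ``fmax``.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    if n < int(round(fs)):
        raise ValueError(f"window of {n} samples is shorter than 1 s at fs={fs}")
    if n_tapers > 2 * nw - 1:
        raise ValueError("n_tapers must be <= 2*NW - 1")
    if demean:
        data = data - data.mean(axis=-1, keepdims=True)
    tapers = _dpss_tapers(n, nw, n_tapers)           # (k, n)
    spec = np.fft.rfft(data[..., None, :] * tapers, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) * (2.0 / fs)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd[..., 0] /= 2.0                                # DC is not doubled
    if n % 2 == 0:
        psd[..., -1] /= 2.0                           # nor Nyquist
    step = max(int(round(1.0 / (freqs[1] - freqs[0]))), 1)
    sel = slice(int(round(fmin)) * step, int(round(fmax)) * step + 1, step)
    return psd[..., sel], freqs[sel]


def multitaper_psd(
    windows: np.ndarray,
    fs: float,
    fmin: float = 2.0,
    fmax: float = 200.0,
    nw: float = 3.0,
    n_tapers: int = 5,
    demean: bool = True,
    channel_ids: list[str] | None = None,
) -> SpectrumSet:
    """Window-averaged multitaper PSD.

    ``windows`` is (n_windows, n_channels, n_samples) or a single
    (n_channels, n_samples) block; averaging across windows is the
    arithmetic mean of linear power.
    """
    windows = np.asarray(windows, float)
    single = windows.ndim == 2
    if single:
        windows = windows[None]
    psd, freqs = multitaper_spectra(windows, fs, fmin, fmax, nw, n_tapers, demean)
    return SpectrumSet(psd.mean(axis=0), freqs, scale="linear",
                       n_windows_averaged=windows.shape[0], channel_ids=channel_ids)


def rebase_spectra(
    spectra: list[SpectrumSet] | SpectrumSet,
    referential: SpectrumSet,
) -> list[SpectrumSet] | SpectrumSet:
    """Convert to log10 power and subtract the subject's referential anchor.

    The anchor is the median over 2–10 Hz of the referential log-power
    averaged across all electrodes of the subject.  Multiplying all
    linear powers by a constant therefore leaves rebased curves
    unchanged, and power differences between curves are preserved.
    """
    if referential.power.size == 0:
        raise ValueError("empty referential spectrum set")
    if referential.scale != "linear":
        raise ValueError("referential spectra must be on the linear scale")
    f = referential.frequencies
    band = (f >= 2) & (f <= 10)
    if not band.any():
        raise ValueError("referential spectra must cover 2-10 Hz")
    anchor = np.median(np.log10(referential.power).mean(axis=0)[band])

    def _one(s: SpectrumSet) -> SpectrumSet:
        if s.scale != "linear":
            raise ValueError("rebase_spectra expects linear-scale input")
        return replace(s, power=np.log10(s.power) - anchor, scale="rebased_log")

    if isinstance(spectra, SpectrumSet):
        return _one(spectra)
    return [_one(s) for s in spectra]
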