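"""Stimulus-vs-baseline spectral contrast over frequency × distance.

Per-window bipolar spectra (restricted to a designated electrode subset,
e.g. superior temporal gyrus contacts, and to pairs up to 40 mm) are log
transformed, averaged within distance bins, and z-scored by frequency
across bins.  The contrast is the stimulus-mean minus baseline-mean map;
significance is assessed with a two-sided cluster-based permutation test
over the frequency × bin grid, and the classic high-gamma summary is the
50–200 Hz row average per bin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .maps import DistanceFrequencyMap
from .montage import BipolarPairSet, apply_bipolar
from .preprocess import WindowSet
from .spectral import multitaper_spectra
from .stats import ClusterResult, cluster_permutation_test

logger = logging.getLogger(__name__)

__all__ = ["ConditionContrast", "window_bin_features", "condition_difference_map",
           "cluster_permutation_map", "high_gamma_metric", "restrict_pairs"]


@dataclass
class ConditionContrast:
    """Stimulus-minus-baseline contrast and its significance mask."""

    diff_map: DistanceFrequencyMap
    features: np.ndarray          # (n_windows, n_freq, n_bins) per-window maps
    labels: np.ndarray
    frequencies: np.ndarray
    bin_centers_mm: np.ndarray
    sig_mask: DistanceFrequencyMap | None = None


def restrict_pairs(pairs: BipolarPairSet, array_table, subset_column: str = "subset",
                   max_distance_mm: float = 40.0) -> BipolarPairSet:
    """Keep pairs whose both contacts carry the subset flag, within max distance."""
    flag = array_table[subset_column].astype(bool).to_numpy()
    p = pairs.pairs
    keep = (flag[p["anode"].to_numpy(int)] & flag[p["cathode"].to_numpy(int)]
            & (p["distance_mm"].to_numpy(float) <= max_distance_mm))
    return BipolarPairSet(p.loc[keep].reset_index(drop=True),
                          bin_width_mm=pairs.bin_width_mm,
                          distance_range_mm=pairs.distance_range_mm)


def window_bin_features(windows: WindowSet, pairs: BipolarPairSet,
                        zscore: bool = True, **psd_kw) -> tuple[np.ndarray, np.ndarray]:
    """Per-window frequency × bin feature maps of log10 bipolar power.

    Each window's bipolar spectra are averaged within distance bins on
    the log10 scale and, if ``zscore``, z-scored by frequency across the
    occupied bins of that window.  Returns (features, frequencies) with
    features shaped (n_windows, n_freq, n_bins); unoccupied bins are NaN.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs after subset/distance restriction")
    bip = apply_bipolar(windows.data, pairs)
    psd, freqs = multitaper_spectra(bip, windows.fs, **psd_kw)
    logp = np.log10(psd)                       # (n_win, n_pairs, n_freq)
    bins = pairs.pairs["bin_index"].to_numpy(int)
    n_bins = pairs.n_bins
    feats = np.full((logp.shape[0], logp.shape[2], n_bins), np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            feats[:, :, b] = logp[:, sel, :].mean(axis=1)
    if zscore:
        occ = ~np.isnan(feats[0, 0])
        mu = feats[:, :, occ].mean(axis=2, keepdims=True)
        sd = feats[:, :, occ].std(axis=2, keepdims=True)
        feats[:, :, occ] = (feats[:, :, occ] - mu) / np.where(sd > 0, sd, 1.0)
    return feats, freqs


def condition_difference_map(windows: WindowSet, pairs: BipolarPairSet,
                             zscore: bool = True, **psd_kw) -> ConditionContrast:
    """Mean stimulus map minus mean baseline map of z-scored log power."""
    for label in ("stimulus", "baseline"):
        if not np.any(windows.labels == label):
            raise ValueError(f"no {label} windows present")
    feats, freqs = window_bin_features(windows, pairs, zscore=zscore, **psd_kw)
    stim = feats[windows.labels == "stimulus"]
    base = feats[windows.labels == "baseline"]
    diff = stim.mean(axis=0) - base.mean(axis=0)
    counts = np.bincount(pairs.pairs["bin_index"].to_numpy(int), minlength=pairs.n_bins)
    diff[:, counts == 0] = np.nan
    dmap = DistanceFrequencyMap(diff, freqs, pairs.bin_centers_mm, counts,
                                "condition_difference")
    return ConditionContrast(dmap, feats, windows.labels, freqs, pairs.bin_centers_mm)


def cluster_permutation_map(contrast: ConditionContrast, n_perm: int = 1000,
                            alpha: float = 0.05, seed=None) -> ClusterResult:
    """Two-sided cluster permutation test of the stimulus/baseline contrast.

    Window labels are permuted; clusters are 4-connected components of
    supra-threshold t values in the frequency × bin grid; cluster mass is
    the summed t, tested against the permutation-max null.
    """
    stim = contrast.features[contrast.labels == "stimulus"]
    base = contrast.features[contrast.labels == "baseline"]
    if min(len(stim), len(base)) < 20:
        logger.warning("fewer than 20 windows in a condition; permutation test underpowered")
    occ = ~np.isnan(contrast.features[0]).all(axis=0)
    res = cluster_permutation_test(stim[..., occ], base[..., occ],
                                   n_perm=n_perm, alpha=alpha, seed=seed)
    # re-embed masks into the full grid
    full_shape = contrast.features.shape[1:]
    def embed(mask):
        out = np.zeros(full_shape, bool)
        out[..., occ] = mask
        return out
    res.clusters = [embed(c) for c in res.clusters]
    t_full = np.zeros(full_shape)
    t_full[..., occ] = res.t_obs
    res.t_obs = t_full
    contrast.sig_mask = DistanceFrequencyMap(
        np.where(np.isnan(contrast.diff_map.values), np.nan, res.sig_mask.astype(float)),
        contrast.frequencies, contrast.bin_centers_mm,
        contrast.diff_map.n_pairs_per_bin, "significance_mask")
    return res


def high_gamma_metric(contrast: ConditionContrast,
                      band: tuple[float, float] = (50.0, 200.0)) -> np.ndarray:
    """Per-bin mean of the contrast over the high-gamma rows (50–200 Hz)."""
    f = contrast.frequencies
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError("contrast does not cover the high-gamma band")
    return contrast.diff_map.values[mask].mean(axis=0)
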