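"""Distance-frequency relation maps and band-level statistics.

The central outputs of the analysis: how bipolar-derived spectral power
depends jointly on frequency and inter-electrode distance.

* :func:`sqrt_zscore_map` — per distance bin, the mean √power across
  contributing pairs, then z-scored by frequency across bins.  This is
  the representation in which the characteristic crescent shape appears:
  low frequencies attenuated at short distances, all frequencies
  enhanced at long distances.
* :func:`percent_change_map` — per pair, the percent change of the
  bipolar spectrum relative to the mean of the two contributing
  referential spectra, averaged within distance bins.  Positive values
  mean bipolar power exceeds referential.
* :func:`band_summary_tests` — subject-level paired Wilcoxon signed-rank
  comparisons of bipolar vs referential band power at each ordinal
  distance, BH-FDR corrected across the band × distance family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import BipolarPairSet
from .spectral import BandTable, SpectrumSet
from .stats import bh_fdr, paired_wilcoxon

logger = logging.getLogger(__name__)

__all__ = ["DistanceFrequencyMap", "sqrt_zscore_map", "percent_change_map",
           "band_summary_tests", "average_maps", "plot_map"]


@dataclass
class DistanceFrequencyMap:
    """Frequency × distance-bin matrix of a chosen statistic.

    Bins without enough contributing pairs hold NaN (never 0 — an empty
    bin is missing data, not a null effect).
    """

    values: np.ndarray            # (n_freq, n_bins)
    frequencies: np.ndarray
    bin_centers_mm: np.ndarray
    n_pairs_per_bin: np.ndarray
    stat: str                     # zscored_sqrt_power | percent_change | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        empty = self.n_pairs_per_bin == 0
        if empty.any() and not np.all(np.isnan(self.values[:, empty])):
            raise ValueError("empty bins must hold NaN")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values,
                          index=[f"{f:g}" for f in self.frequencies],
                          columns=[f"{c:g}" for c in self.bin_centers_mm])
        df.to_csv(path, sep="\t", index_label="freq_hz", na_rep="NA",
                  float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, stat: str = "unknown") -> "DistanceFrequencyMap":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        values = df.to_numpy(float)
        n_pairs = np.where(np.all(np.isnan(values), axis=0), 0, 1)
        return cls(values, df.index.to_numpy(float),
                   np.array([float(c) for c in df.columns]), n_pairs, stat)


def _bin_means(per_pair: np.ndarray, bins: np.ndarray, n_bins: int,
               min_pairs: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Mean over pairs within each distance bin; (n_freq, n_bins) + counts."""
    n_freq = per_pair.shape[1]
    out = np.full((n_freq, n_bins), np.nan)
    counts = np.zeros(n_bins, int)
    for b in range(n_bins):
        sel = bins == b
        counts[b] = sel.sum()
        if counts[b] >= min_pairs:
            with np.errstate(invalid="ignore"):
                out[:, b] = np.nanmean(per_pair[sel], axis=0)
    return out, counts


def sqrt_zscore_map(bipolar_spectra: SpectrumSet, pairs: BipolarPairSet,
                    min_pairs: int = 1) -> DistanceFrequencyMap:
    """Square-root-transformed power, z-scored by frequency across bins.

    Per bin: mean over contributing pairs of √power (already averaged
    over windows).  Per frequency row: z-score across the non-empty bins
    with the population (ddof=0) standard deviation, so any valid row
    has mean 0 and sd 1 over its bins.
    """
    if "bin_index" not in pairs.pairs.columns:
        raise ValueError("pairs must be binned first (bin_pairs_by_distance)")
    if bipolar_spectra.scale != "linear":
        raise ValueError("expected linear-power spectra")
    bins = pairs.pairs["bin_index"].to_numpy(int)
    vals, counts = _bin_means(np.sqrt(bipolar_spectra.power), bins,
                              pairs.n_bins, min_pairs)
    occupied = ~np.all(np.isnan(vals), axis=0)
    if occupied.sum() < 2:
        raise ValueError("z-score undefined with fewer than 2 non-empty bins")
    row_mean = np.nanmean(vals[:, occupied], axis=1, keepdims=True)
    row_sd = np.nanstd(vals[:, occupied], axis=1, keepdims=True)
    z = np.full_like(vals, np.nan)
    with np.errstate(invalid="ignore"):
        z[:, occupied] = np.where(row_sd > 0, (vals[:, occupied] - row_mean) / row_sd, 0.0)
    return DistanceFrequencyMap(z, bipolar_spectra.frequencies,
                                pairs.bin_centers_mm, counts, "zscored_sqrt_power")


def percent_change_map(
    bipolar_spectra: SpectrumSet,
    referential_spectra: SpectrumSet,
    pairs: BipolarPairSet,
    scale: str = "sqrt",
    min_pairs: int = 5,
    legacy_sign: bool = False,
) -> DistanceFrequencyMap:
    """Percent change of bipolar power relative to referential, by bin.

    Per pair and frequency: ``100 × (B − R) / R`` where B is the bipolar
    spectrum and R the arithmetic mean of the two contributing
    referential spectra, both on the √-power scale by default
    (``scale='linear'`` switches to raw power).  Positive means bipolar
    exceeds referential; ``legacy_sign`` flips the sign to the
    referential-minus-bipolar convention.  Bins with fewer than
    ``min_pairs`` pairs are reported as NaN.
    """
    if scale not in ("sqrt", "linear"):
        raise ValueError("scale must be 'sqrt' or 'linear'")
    if "bin_index" not in pairs.pairs.columns:
        raise ValueError("pairs must be binned first (bin_pairs_by_distance)")
    if not np.array_equal(bipolar_spectra.frequencies, referential_spectra.frequencies):
        raise ValueError("bipolar and referential spectra must share a frequency grid")
    tr = np.sqrt if scale == "sqrt" else np.asarray
    b = tr(bipolar_spectra.power)
    ref = tr(referential_spectra.power)
    a_idx = pairs.pairs["anode"].to_numpy(int)
    c_idx = pairs.pairs["cathode"].to_numpy(int)
    r = 0.5 * (ref[a_idx] + ref[c_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 100.0 * (b - r) / r
    if np.any(r == 0):
        logger.warning("zero referential power at some frequencies; cells excluded")
        pc[r == 0] = np.nan
    if legacy_sign:
        pc = -pc
    bins = pairs.pairs["bin_index"].to_numpy(int)
    vals, counts = _bin_means(pc, bins, pairs.n_bins, min_pairs)
    return DistanceFrequencyMap(vals, bipolar_spectra.frequencies,
                                pairs.bin_centers_mm, counts, "percent_change")


def plot_map(dmap: DistanceFrequencyMap, path, cmap: str = "RdBu_r",
             vlim: float | None = None) -> None:
    """Heat-map image export of a distance-frequency map (missing cells blank)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    v = vlim if vlim is not None else np.nanmax(np.abs(dmap.values))
    mesh = ax.pcolormesh(dmap.bin_centers_mm, dmap.frequencies, dmap.values,
                         cmap=cmap, vmin=-v, vmax=v, shading="nearest")
    ax.set_xlabel("bipolar distance (mm)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(dmap.stat.replace("_", " "))
    fig.colorbar(mesh, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def average_maps(maps: list[DistanceFrequencyMap]) -> DistanceFrequencyMap:
    """Equal-weight average of per-subject maps (cells missing anywhere stay NaN-robust)."""
    if not maps:
        raise ValueError("no maps to average")
    stacked = np.stack([m.values for m in maps])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    counts = np.sum([m.n_pairs_per_bin for m in maps], axis=0)
    mean[:, counts == 0] = np.nan
    m0 = maps[0]
    return DistanceFrequencyMap(mean, m0.frequencies, m0.bin_centers_mm, counts, m0.stat)


def band_summary_tests(
    bipolar_by_subject: dict[str, dict[float, SpectrumSet]],
    referential_by_subject: dict[str, SpectrumSet],
    bands: BandTable | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Band × ordinal-distance table of paired bipolar-vs-referential tests.

    For each subject, band-mean power is averaged across electrodes
    (referential) or pairs (bipolar, per ordinal distance).  Each
    band × distance cell is a paired Wilcoxon signed-rank test of the
    subject-level bipolar vs referential values, BH-FDR corrected across
    the whole family.  With a single subject, statistics are suppressed
    and only descriptives are returned.
    """
    from .spectral import DEFAULT_BANDS
    bands = bands or BandTable(DEFAULT_BANDS)
    subjects = sorted(bipolar_by_subject)
    if set(subjects) != set(referential_by_subject):
        raise ValueError("subject keys must match between bipolar and referential inputs")
    distances = sorted({d for s in subjects for d in bipolar_by_subject[s]})

    rows = []
    for band in bands.bands:
        for dist in distances:
            bip_vals, ref_vals = [], []
            for s in subjects:
                if dist not in bipolar_by_subject[s]:
                    continue
                bs = bipolar_by_subject[s][dist]
                rs = referential_by_subject[s]
                mask = bands.mask(bs.frequencies, band)
                bip_vals.append(bs.power[:, mask].mean())
                ref_vals.append(rs.power[:, mask].mean())
            bip_arr, ref_arr = np.array(bip_vals), np.array(ref_vals)
            diff = bip_arr - ref_arr
            row = {
                "band": band, "distance_mm": dist, "n_subjects": len(diff),
                "median_diff": float(np.median(diff)) if len(diff) else np.nan,
                "iqr_diff": float(np.subtract(*np.percentile(diff, [75, 25]))) if len(diff) else np.nan,
            }
            if len(diff) >= 2:
                w = paired_wilcoxon(bip_arr, ref_arr)
                row.update(effect_size=w["effect_size"], p=w["p"])
            else:
                row.update(effect_size=np.nan, p=np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["p_fdr"] = np.nan
    table["significant"] = False
    if tested.any():
        reject, p_adj = bh_fdr(table.loc[tested, "p"].to_numpy(), q=q)
        table.loc[tested, "p_fdr"] = p_adj
        table.loc[tested, "significant"] = reject
    return table
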