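"""End-to-end pipeline orchestration with deterministic, manifest-tracked runs.

``run_pipeline`` chains: simulate (optional) → preprocess → montage →
spectra → distance maps → task contrast (optional) → IED analysis
(optional), writing every table as TSV/JSON into a fresh run directory
together with a manifest recording the configuration and seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ied import (build_density_schemes, compare_density_conditions,
                  ied_channel_cluster_test, ied_extent_metrics, subject_included)
from .io import read_recording, write_binary_recording
from .maps import percent_change_map, sqrt_zscore_map
from .montage import (ElectrodeArray, apply_bipolar, bin_pairs_by_distance,
                      enumerate_omnidirectional_pairs)
from .preprocess import (AnnotationTable, Recording, center_ied_windows,
                         lowpass_downsample, notch_line_noise, parse_baseline_windows)
from .simulate import (FieldConfig, IedConfig, inject_ieds, make_geometry,
                       reference_field_config, simulate_field)
from .spectral import multitaper_psd
from .task import (cluster_permutation_map, condition_difference_map,
                   high_gamma_metric, restrict_pairs)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_map_tsv"]


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline run."""

    # simulate stage (used when no input recording is given)
    simulate: bool = True
    geometry: str = "grid1x16"
    pitch_mm: float | None = None
    duration_s: float = 120.0
    sim_fs: float = 3052.0
    n_ieds: int = 0
    seed: int = 0
    # preprocess
    lowpass_hz: float = 255.0
    target_fs: float = 512.0
    notch_base_hz: float = 60.0
    # montage / maps
    bin_width_mm: float = 2.0
    distance_range_mm: tuple[float, float] = (2.0, 60.0)
    min_pairs_per_bin: int = 5
    percent_change_scale: str = "sqrt"
    # optional stages
    run_task: bool = False
    run_ied: bool = False
    n_perm: int = 1000
    max_task_distance_mm: float = 40.0
    # inputs (when simulate is False)
    recording_path: str | None = None
    electrodes_path: str | None = None
    annotations_path: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if d.get("distance_range_mm") is not None:
            d["distance_range_mm"] = tuple(d["distance_range_mm"])
        return cls(**d)


def write_map_tsv(dmap, path) -> None:
    """TSV export: bin-center header, frequency first column, NaN as 'NA'."""
    dmap.to_tsv(path)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages; returns the run directory.

    The run directory is created fresh (a numeric suffix is appended if
    it exists) and receives every stage output plus ``manifest.json``.
    """
    out = Path(out_dir)
    base = out
    i = 1
    while out.exists():
        out = base.with_name(f"{base.name}.{i}")
        i += 1
    out.mkdir(parents=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        array = make_geometry(config.geometry, config.pitch_mm, seed=config.seed)
        fcfg = reference_field_config(seed=config.seed)
        rec = simulate_field(array, fcfg, config.duration_s, fs=config.sim_fs)
        ann = AnnotationTable.empty()
        if config.n_ieds > 0:
            rec, ann = inject_ieds(rec, array, IedConfig(
                n_events=config.n_ieds, center_contact=array.n_contacts // 2,
                seed=config.seed + 1))
        array.to_tsv(out / "electrodes.tsv")
        ann.to_tsv(out / "annotations.tsv")
        write_binary_recording(rec, out / "referential.bin")
    else:
        if not (config.recording_path and config.electrodes_path):
            raise ValueError("recording_path and electrodes_path required when simulate=False")
        rec = read_recording(config.recording_path)
        array = ElectrodeArray.from_tsv(config.electrodes_path)
        ann = (AnnotationTable.from_tsv(config.annotations_path)
               if config.annotations_path else AnnotationTable.empty())

    # --- preprocess -------------------------------------------------------
    rec = lowpass_downsample(rec, cutoff=config.lowpass_hz, target_fs=config.target_fs)
    rec = notch_line_noise(rec, base=config.notch_base_hz)
    windows = parse_baseline_windows(rec, ann)
    base_win = windows.data[windows.labels == "baseline"]
    logger.info("parsed %d baseline windows", len(base_win))

    # --- montage + spectra ------------------------------------------------
    pairs = enumerate_omnidirectional_pairs(array)
    pairs = bin_pairs_by_distance(pairs, config.bin_width_mm, config.distance_range_mm)
    pairs.to_tsv(out / "pairs.tsv")
    bip = apply_bipolar(base_win, pairs)
    bip_spec = multitaper_psd(bip, rec.fs)
    ref_spec = multitaper_psd(base_win, rec.fs, channel_ids=rec.channel_ids)
    ref_spec.to_tsv(out / "referential_spectra.tsv")
    bip_spec.to_tsv(out / "bipolar_spectra.tsv")

    # --- distance-frequency maps ------------------------------------------
    zmap = sqrt_zscore_map(bip_spec, pairs)
    zmap.to_tsv(out / "map_zscored_sqrt_power.tsv")
    pcmap = percent_change_map(bip_spec, ref_spec, pairs,
                               scale=config.percent_change_scale,
                               min_pairs=config.min_pairs_per_bin)
    pcmap.to_tsv(out / "map_percent_change.tsv")
    np.savetxt(out / "n_pairs_per_bin.tsv", pcmap.n_pairs_per_bin[None, :],
               fmt="%d", delimiter="\t")

    # --- optional task stage ----------------------------------------------
    if config.run_task:
        if "subset" not in array.table.columns:
            raise ValueError("task stage needs a 'subset' electrode column")
        tpairs = restrict_pairs(pairs, array.table,
                                max_distance_mm=config.max_task_distance_mm)
        contrast = condition_difference_map(windows, tpairs)
        cluster_permutation_map(contrast, n_perm=config.n_perm, seed=config.seed)
        contrast.diff_map.to_tsv(out / "task_diff_map.tsv")
        contrast.sig_mask.to_tsv(out / "task_sig_mask.tsv")
        hg = high_gamma_metric(contrast)
        np.savetxt(out / "task_high_gamma.tsv", hg[None, :], delimiter="\t")

    # --- optional IED stage -----------------------------------------------
    if config.run_ied:
        ied_win = center_ied_windows(rec, ann)
        if not subject_included(ied_win.n_windows):
            logger.info("IED stage skipped by inclusion rule")
        else:
            high, low = build_density_schemes(array)
            rng = np.random.default_rng(config.seed)
            rows = []
            for name, scheme in (("high", high), ("low", low)):
                res = ied_channel_cluster_test(
                    apply_bipolar(ied_win.data, scheme),
                    apply_bipolar(base_win, scheme),
                    rec.fs, n_perm=config.n_perm, seed=rng)
                ext = ied_extent_metrics(res, name)
                rows.append(ext)
            comp = compare_density_conditions([rows[0]], [rows[1]])
            comp.to_csv(out / "ied_density_comparison.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "config_sha1": hashlib.sha1(config.to_json().encode()).hexdigest(),
        "n_baseline_windows": int(len(base_win)),
        "n_pairs": int(len(pairs)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
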