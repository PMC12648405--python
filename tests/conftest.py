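"""Shared fixtures: small electrode arrays and a session-cached reference run.

Everything is generated programmatically; the heavier reference-pipeline
products (a 2-minute synthetic recording pushed through preprocessing,
montage, and spectra) are computed once per session and reused.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bprr
from bprr.montage import ElectrodeArray
from bprr.preprocess import AnnotationTable, parse_baseline_windows
from bprr.montage import enumerate_omnidirectional_pairs, bin_pairs_by_distance, apply_bipolar
from bprr.preprocess import lowpass_downsample, notch_line_noise
from bprr.spectral import multitaper_psd

#: single fixed seed for every stochastic fixture in the suite
SEED = 0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


def line_array(n: int, pitch: float, ctype: str = "depth") -> ElectrodeArray:
    return ElectrodeArray(pd.DataFrame({
        "contact_id": [f"C{i}" for i in range(n)],
        "x_mm": np.arange(n) * pitch, "y_mm": 0.0, "z_mm": 0.0,
        "component_id": "c0", "component_type": ctype,
        "pitch_mm": pitch, "row_id": "", "bad": 0,
    }))


@pytest.fixture
def depth10() -> ElectrodeArray:
    return bprr.make_geometry("depth10")


@pytest.fixture
def grid_row16() -> ElectrodeArray:
    """One 16-contact grid row at 4 mm pitch (colinear with wave propagation)."""
    return bprr.make_geometry("grid1x16")


@pytest.fixture(scope="session")
def reference_run():
    """Reference synthetic configuration through preprocess + montage + spectra.

    Returns a dict with the downsampled recording, baseline windows,
    binned omnidirectional pairs, and bipolar/referential spectra.
    """
    array = bprr.make_geometry("grid1x16")
    cfg = bprr.reference_field_config(seed=SEED)
    rec = bprr.simulate_field(array, cfg, 120.0, fs=3052.0)
    rec = notch_line_noise(lowpass_downsample(rec))
    windows = parse_baseline_windows(rec, AnnotationTable.empty())
    pairs = bin_pairs_by_distance(enumerate_omnidirectional_pairs(array))
    base = windows.data[windows.labels == "baseline"]
    bip_spec = multitaper_psd(apply_bipolar(base, pairs), rec.fs)
    ref_spec = multitaper_psd(base, rec.fs)
    return {"array": array, "recording": rec, "windows": windows,
            "pairs": pairs, "bipolar_spectra": bip_spec, "referential_spectra": ref_spec}
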