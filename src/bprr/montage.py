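"""Electrode geometry and bipolar montage construction.

A bipolar montage derives each channel by subtracting one contact's
referential trace from another's.  Two pairing schemes are supported:

* **linear ordinal** — pairs formed along the linear axis of a component
  (a depth probe, a strip, or one row of a grid), with the recorded
  distance expressed as ``skip × manufactured pitch`` (non-Euclidean);
* **omnidirectional** — every unordered within-component pair, with the
  straight-line 3D distance between the contact coordinates.

Pairs are never formed between components (different contact sizes and
materials would confound the comparison), and contacts flagged bad are
excluded before any enumeration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeArray",
    "BipolarPairSet",
    "InvalidGeometryError",
    "MontageError",
    "euclidean_distance",
    "enumerate_linear_ordinal_pairs",
    "enumerate_omnidirectional_pairs",
    "bin_pairs_by_distance",
    "apply_bipolar",
]

ELECTRODE_COLUMNS = [
    "contact_id", "x_mm", "y_mm", "z_mm",
    "component_id", "component_type", "pitch_mm", "row_id", "bad",
]

COMPONENT_TYPES = {"grid", "depth", "strip"}


class InvalidGeometryError(ValueError):
    """Raised for non-finite coordinates or inconsistent geometry."""


class MontageError(KeyError):
    """Raised when a bipolar pair references a channel not in the recording."""


@dataclass
class ElectrodeArray:
    """Named contacts with 3D positions (mm) and component membership.

    ``table`` columns: contact_id, x_mm, y_mm, z_mm, component_id,
    component_type (grid/depth/strip), pitch_mm, row_id (grids; contacts
    ordered within a row), bad (0/1).  Extra columns (e.g. a task-subset
    flag) are preserved.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ELECTRODE_COLUMNS if c not in self.table.columns]
        if missing:
            raise InvalidGeometryError(f"electrode table missing columns {missing}")
        pos = self.positions
        if not np.all(np.isfinite(pos)):
            raise InvalidGeometryError("electrode positions must be finite")
        if not np.all(self.table["pitch_mm"].to_numpy(float) > 0):
            raise InvalidGeometryError("pitch_mm must be positive")
        bad_type = set(self.table["component_type"]) - COMPONENT_TYPES
        if bad_type:
            raise InvalidGeometryError(f"unknown component types {bad_type}")
        grids = self.table["component_type"] == "grid"
        if grids.any() and self.table.loc[grids, "row_id"].isna().any():
            raise InvalidGeometryError("every grid contact needs a row_id")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_contacts(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    @property
    def contact_ids(self) -> list[str]:
        return self.table["contact_id"].astype(str).tolist()

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of contacts not flagged bad."""
        return ~self.table["bad"].astype(bool).to_numpy()

    def lines(self) -> list[np.ndarray]:
        """Index arrays of the linear runs of usable contacts.

        Depth probes and strips form one line each; each grid row is its
        own line.  Contacts keep their table order within a line; bad
        contacts are dropped (a gap does not split the line — ordinal
        distance still counts the manufactured positions skipped).
        """
        out: list[np.ndarray] = []
        t = self.table
        for comp_id, comp in t.groupby("component_id", sort=False):
            if comp["component_type"].iloc[0] == "grid":
                for _, row in comp.groupby("row_id", sort=False):
                    out.append(row.index.to_numpy())
            else:
                out.append(comp.index.to_numpy())
        return out

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeArray":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class BipolarPairSet:
    """Electrode index pairs with distances and optional distance bins.

    ``pairs`` columns: anode, cathode (integer row indices into the
    electrode table), anode_id, cathode_id, component_id, distance_mm,
    scheme ('ordinal' | 'euclidean'), ordinal_skip (NaN for euclidean),
    and — after :func:`bin_pairs_by_distance` — bin_index.
    """

    pairs: pd.DataFrame
    bin_width_mm: float | None = None
    distance_range_mm: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_bins(self) -> int:
        if self.bin_width_mm is None:
            raise ValueError("pairs are not binned")
        lo, hi = self.distance_range_mm
        return int(np.ceil((hi - lo) / self.bin_width_mm))

    @property
    def bin_centers_mm(self) -> np.ndarray:
        lo = self.distance_range_mm[0]
        w = self.bin_width_mm
        return lo + w * (np.arange(self.n_bins) + 0.5)

    def to_tsv(self, path) -> None:
        cols = ["anode_id", "cathode_id", "distance_mm", "scheme", "ordinal_skip"]
        if "bin_index" in self.pairs.columns:
            cols.append("bin_index")
        out = self.pairs[cols].rename(columns={"anode_id": "anode", "cathode_id": "cathode"})
        out.to_csv(path, sep="\t", index=False)


def euclidean_distance(a, b) -> float:
    """Straight-line 3D distance (mm) between two contact positions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidGeometryError("non-finite coordinates")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _pair_frame(array: ElectrodeArray, anode, cathode, distance, scheme, skip) -> pd.DataFrame:
    t = array.table
    anode = np.asarray(anode, int)
    cathode = np.asarray(cathode, int)
    return pd.DataFrame(
        {
            "anode": anode,
            "cathode": cathode,
            "anode_id": t["contact_id"].to_numpy()[anode],
            "cathode_id": t["contact_id"].to_numpy()[cathode],
            "component_id": t["component_id"].to_numpy()[anode],
            "distance_mm": np.asarray(distance, float),
            "scheme": scheme,
            "ordinal_skip": skip,
        }
    )


def enumerate_linear_ordinal_pairs(array: ElectrodeArray, max_skip: int) -> BipolarPairSet:
    """Pairs (i, i+s) along each linear run for skips s = 1..max_skip.

    Distance is ``s × pitch`` exactly (the ordinal, non-Euclidean
    convention used in clinical montages).  Bad contacts are excluded and
    count as skipped positions.
    """
    if max_skip < 1:
        raise ValueError("max_skip must be >= 1")
    frames = []
    usable = array.usable
    pitch = array.table["pitch_mm"].to_numpy(float)
    for line in array.lines():
        # position along the manufactured line, counting bad contacts
        for s in range(1, max_skip + 1):
            for j in range(len(line) - s):
                i0, i1 = line[j], line[j + s]
                if usable[i0] and usable[i1]:
                    frames.append((i0, i1, s * pitch[i0], s))
    if not frames:
        empty = _pair_frame(array, [], [], [], "ordinal", [])
        return BipolarPairSet(empty)
    a, c, d, s = zip(*frames)
    return BipolarPairSet(_pair_frame(array, a, c, d, "ordinal", list(s)))


def enumerate_omnidirectional_pairs(array: ElectrodeArray) -> BipolarPairSet:
    """All unordered within-component pairs of usable contacts.

    Euclidean 3D distances are attached; cross-component pairs are never
    formed.  Pairs are canonically ordered (lower table index first), so
    the sign of the derived channel is deterministic.
    """
    frames = []
    usable = array.usable
    pos = array.positions
    for _, comp in array.table.groupby("component_id", sort=False):
        idx = comp.index.to_numpy()
        idx = idx[usable[idx]]
        if len(idx) < 2:
            continue
        ii, jj = np.triu_indices(len(idx), k=1)
        a, c = idx[ii], idx[jj]
        d = np.sqrt(np.sum((pos[a] - pos[c]) ** 2, axis=1))
        frames.append(_pair_frame(array, a, c, d, "euclidean", np.nan))
    if not frames:
        return BipolarPairSet(_pair_frame(array, [], [], [], "euclidean", []))
    return BipolarPairSet(pd.concat(frames, ignore_index=True))


def bin_pairs_by_distance(
    pairs: BipolarPairSet,
    bin_width_mm: float = 2.0,
    distance_range_mm: tuple[float, float] = (2.0, 60.0),
) -> BipolarPairSet:
    """Drop pairs outside ``distance_range_mm`` and assign distance bins.

    Bins are half-open ``[low, low + w)`` starting at the lower range
    edge; the range itself is treated as the closed interval [lo, hi], so
    a pair exactly at the upper edge lands in the last bin.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    lo, hi = distance_range_mm
    if hi <= lo:
        raise ValueError(f"inverted distance range {distance_range_mm}")
    d = pairs.pairs["distance_mm"].to_numpy(float)
    keep = (d >= lo) & (d <= hi)
    kept = pairs.pairs.loc[keep].reset_index(drop=True)
    out = BipolarPairSet(kept, bin_width_mm=bin_width_mm, distance_range_mm=(lo, hi))
    bins = np.floor((kept["distance_mm"].to_numpy(float) - lo) / bin_width_mm).astype(int)
    bins = np.minimum(bins, out.n_bins - 1)  # closed upper edge
    kept["bin_index"] = bins
    return out


def apply_bipolar(samples: np.ndarray, pairs: BipolarPairSet, n_channels: int | None = None) -> np.ndarray:
    """Derive bipolar channels: sample-wise anode − cathode.

    ``samples`` has channels on the second-to-last axis (so both
    ``(n_channels, n_times)`` continuous blocks and
    ``(n_windows, n_channels, n_times)`` window stacks work).  Returns an
    array with one derived channel per pair on that axis.
    """
    nch = samples.shape[-2]
    a = pairs.pairs["anode"].to_numpy(int)
    c = pairs.pairs["cathode"].to_numpy(int)
    if len(a) and (a.max() >= nch or c.max() >= nch):
        i = int(np.argmax(np.maximum(a, c) >= nch))
        raise MontageError(
            f"pair ({pairs.pairs['anode_id'].iloc[i]}, {pairs.pairs['cathode_id'].iloc[i]}) "
            f"references a channel outside the {nch}-channel recording"
        )
    return samples[..., a, :] - samples[..., c, :]
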