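"""Per-cell fluorescence and spatial quantification of tissue sections.

Works on already-extracted per-cell records (intensity, per-section
background, normalized tissue depth). The depth coordinate runs from 0 at the
apical/ventricular surface to 1 at the basal/pial surface. Laminar bins are
reported basal-to-apical (bin 1 most basal), matching the convention used for
cortical-plate histograms; zone schemes (VZ/SVZ/IZ/CP or UL/LL) are
user-supplied boundary fractions on the same axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZoneScheme",
    "BinHistogram",
    "corrected_mfi",
    "mfi_group_summary",
    "bin_distribution",
    "zone_fractions",
    "colocalization_fraction",
]

INTENSITY_MAX = 255.0


@dataclass(frozen=True)
class ZoneScheme:
    """Ordered depth boundaries naming len(boundaries)+1 zones, apical first.

    Example: boundaries=(0.25, 0.5, 0.75), names=("VZ","SVZ","IZ","CP").
    split_first_zone adds an equal inner/outer sub-split of the first zone
    (the IVZ/OVZ convention for the ventricular zone).
    """

    boundaries: tuple
    names: tuple
    split_first_zone: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size + 1 != len(self.names):
            raise ValueError("need len(boundaries) + 1 zone names")
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= 1):
            raise ValueError("boundaries must be strictly increasing within (0, 1)")


@dataclass
class BinHistogram:
    """Laminar histogram: counts and percentages, bin 1 = most basal."""

    n_bins: int
    counts: np.ndarray
    percentages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        total = self.counts.sum()
        self.percentages = 100.0 * self.counts / total


def corrected_mfi(raw_intensity, background):
    """Background-corrected mean fluorescence intensity in percent.

    ((raw - background) / (255 - background)) * 100 on the 0-255 a.u. scale.
    Values where raw < background come out negative; they are preserved (not
    clipped, which would bias group means) and flagged with a warning.
    """
    raw = np.asarray(raw_intensity, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(bg >= INTENSITY_MAX) or np.any(bg < 0):
        raise ValueError("background must lie in [0, 255)")
    if np.any(raw < 0) or np.any(raw > INTENSITY_MAX):
        raise ValueError("raw intensity must lie in [0, 255]")
    out = (raw - bg) / (INTENSITY_MAX - bg) * 100.0
    if np.any(out < 0):
        warnings.warn("corrected MFI below zero for some cells (raw < background)")
    if out.ndim == 0:
        return float(out)
    return out


def mfi_group_summary(records: pd.DataFrame, *, freq_bin_width: float = 5.0) -> dict:
    """Per-group MFI summaries with the animal as the averaging unit.

    `records` needs columns group, animal_id, raw_intensity, background.
    Returns, per group: animal means, group mean and SEM over animal means
    (SEM is None for a single animal), and the all-cell frequency distribution
    of corrected MFI (percent of cells per intensity bin).
    """
    required = {"group", "animal_id", "raw_intensity", "background"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    out = {}
    for group, sub in records.groupby("group", sort=True):
        if len(sub) == 0:
            raise ValueError(f"group {group!r} has zero cells")
        mfi = np.atleast_1d(corrected_mfi(sub["raw_intensity"], sub["background"]))
        animal_means = (
            pd.Series(mfi, index=sub.index).groupby(sub["animal_id"]).mean()
        )
        n_animals = len(animal_means)
        sem = (
            float(animal_means.std(ddof=1) / np.sqrt(n_animals))
            if n_animals > 1
            else None
        )
        lo = min(0.0, np.floor(mfi.min() / freq_bin_width) * freq_bin_width)
        edges = np.arange(lo, 100.0 + freq_bin_width, freq_bin_width)
        counts, edges = np.histogram(mfi, bins=edges)
        out[group] = {
            "animal_means": animal_means.to_dict(),
            "mean": float(animal_means.mean()),
            "sem": sem,
            "n_animals": n_animals,
            "n_cells": len(sub),
            "frequency": {
                "bin_edges": edges.tolist(),
                "percent": (100.0 * counts / counts.sum()).tolist(),
            },
        }
    return out


def _bin_index(depths: np.ndarray, n_bins: int) -> np.ndarray:
    # bin = n_bins - floor(depth * n_bins); depth 0 (apical) -> bin n_bins,
    # depth -> 1 (basal) -> bin 1; depth exactly 1 closed into bin 1.
    idx = n_bins - np.floor(depths * n_bins).astype(int)
    idx[depths >= 1.0] = 1
    return idx


def bin_distribution(depths, n_bins: int = 10) -> BinHistogram:
    """Equal-width laminar bin histogram on the depth axis.

    Bins are half-open on depth with the last (most basal) bin closed; bin 1
    is the most basal, bin n_bins the most apical.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    if np.any(depths < 0) or np.any(depths > 1):
        raise ValueError("depths must lie in [0, 1]")
    idx = _bin_index(depths, n_bins)
    counts = np.bincount(idx, minlength=n_bins + 1)[1:]
    return BinHistogram(n_bins=n_bins, counts=counts)


def zone_fractions(depths, scheme: ZoneScheme) -> dict:
    """Percentage of cells per zone; optional inner/outer split of zone 1.

    Zones are half-open [a, b) on depth, the last zone closed at 1.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    if np.any(depths < 0) or np.any(depths > 1):
        raise ValueError("depths must lie in [0, 1]")
    edges = np.concatenate(([0.0], np.asarray(scheme.boundaries, float), [1.0]))
    idx = np.searchsorted(edges, depths, side="right") - 1
    idx = np.clip(idx, 0, len(scheme.names) - 1)
    counts = np.bincount(idx, minlength=len(scheme.names))
    result = {
        name: 100.0 * c / depths.size for name, c in zip(scheme.names, counts)
    }
    if scheme.split_first_zone:
        mid = (edges[0] + edges[1]) / 2.0
        in_first = idx == 0
        inner = np.sum(in_first & (depths < mid))
        outer = np.sum(in_first) - inner
        first = scheme.names[0]
        result[f"I{first}"] = 100.0 * inner / depths.size
        result[f"O{first}"] = 100.0 * outer / depths.size
    return result


def colocalization_fraction(flags_a, flags_b) -> float:
    """Percent of flag-a-positive cells that are also flag-b positive."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must have equal length")
    n_a = a.sum()
    if n_a == 0:
        raise ValueError("no positive cells in the reference flag vector")
    return float(100.0 * np.sum(a & b) / n_a)
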