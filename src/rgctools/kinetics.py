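"""Dual-pulse thymidine-analog estimators of cell-cycle kinetics.

Two analogs (BrdU, then EdU one interval later, sacrifice a short chase
afterwards) partition labelled S-phase cells into classes whose ratios give
the S-phase duration Ts; combining Ts with the instantaneous S-phase fraction
and a proliferation-marker growth fraction (GF) gives the total cycle length
Tc:

    Ts = (BrdU+EdU+ / BrdU+EdU-) * interval
    Tc = Ts / (EdU+ / (GFP+ * GF))
    GF = (GFP+ marker+) / GFP+          (marker: Mcm2 or Ki67)

Counts may be supplied directly or derived from a per-cell table, which by
default is restricted to electroporated (gfp) cells in the ventricular zone.
Uncertainty is a cell-level bootstrap (percentile CIs); the animal-level SEM
used in publications requires per-animal data and is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PulseDesign",
    "CountSummary",
    "KineticsEstimate",
    "counts_from_table",
    "growth_fraction",
    "estimate_ts",
    "estimate_tc",
    "exit_fractions",
    "bootstrap_kinetics",
]


class EstimatorUndefinedError(ValueError):
    """A count class required by a plug-in estimator is empty."""


@dataclass(frozen=True)
class PulseDesign:
    """Injection schedule: hours between the two pulses and chase to sacrifice."""

    interval: float = 1.0
    chase: float = 0.5

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.chase < 0:
            raise ValueError("chase must be >= 0")


@dataclass(frozen=True)
class CountSummary:
    """Cell counts of the labelled VZ population by staining class."""

    n_gfp: int
    n_brdu_edu: int
    n_brdu_only: int
    n_edu: int
    n_marker: int
    marker: str = "mcm2"
    n_ki67_brdu: int = 0
    n_ki67neg_brdu: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_gfp, self.n_brdu_edu, self.n_brdu_only, self.n_edu,
            self.n_marker, self.n_ki67_brdu, self.n_ki67neg_brdu,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_brdu_edu + self.n_brdu_only > self.n_gfp:
            raise ValueError("BrdU classes exceed the labelled population")
        if self.n_marker > self.n_gfp:
            raise ValueError("marker-positive count exceeds the labelled population")


@dataclass
class KineticsEstimate:
    ts_hours: float
    tc_hours: float
    growth_fraction: float
    marker_used: str
    n_cells: int
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: Optional[int] = None
    n_dropped_resamples: int = 0


def counts_from_table(
    table: pd.DataFrame,
    marker: str = "mcm2",
    zone: Optional[str] = "VZ",
    require_gfp: bool = True,
) -> CountSummary:
    """Tally staining classes from a per-cell table.

    The default filter keeps gfp-positive cells in the VZ, the population the
    dual-pulse design quantifies.
    """
    if marker not in ("mcm2", "ki67"):
        raise ValueError("marker must be 'mcm2' or 'ki67'")
    sub = table
    if zone is not None:
        sub = sub[sub["zone"] == zone]
    if require_gfp:
        sub = sub[sub["gfp"].astype(bool)]
    brdu = sub["brdu"].astype(bool)
    edu = sub["edu"].astype(bool)
    ki67 = sub["ki67"].astype(bool)
    return CountSummary(
        n_gfp=len(sub),
        n_brdu_edu=int((brdu & edu).sum()),
        n_brdu_only=int((brdu & ~edu).sum()),
        n_edu=int(edu.sum()),
        n_marker=int(sub[marker].astype(bool).sum()),
        marker=marker,
        n_ki67_brdu=int((ki67 & brdu).sum()),
        n_ki67neg_brdu=int((~ki67 & brdu).sum()),
    )


def growth_fraction(counts: CountSummary) -> float:
    """Marker-positive fraction of the labelled population, in [0, 1]."""
    if counts.n_gfp == 0:
        raise EstimatorUndefinedError("no labelled cells: growth fraction undefined")
    return counts.n_marker / counts.n_gfp


def estimate_ts(counts: CountSummary, design: PulseDesign) -> float:
    """S-phase duration: double-labelled over single-labelled cells x interval."""
    if counts.n_brdu_only == 0:
        raise EstimatorUndefinedError(
            "no BrdU+EdU- cells: Ts estimator undefined "
            "(interval too long relative to Ts, or sample too small)"
        )
    return counts.n_brdu_edu / counts.n_brdu_only * design.interval


def estimate_tc(ts: float, counts: CountSummary, gf: float) -> float:
    """Total cycle length: Ts over the GF-corrected S-phase fraction."""
    if counts.n_edu == 0:
        raise EstimatorUndefinedError("no EdU+ cells: Tc estimator undefined")
    if not 0 < gf <= 1:
        raise ValueError("growth fraction must lie in (0, 1]")
    return ts / (counts.n_edu / (counts.n_gfp * gf))


def exit_fractions(counts: CountSummary) -> tuple:
    """(cycling retained, exited) fractions among labelled cells.

    Retained = Ki67+BrdU+ / GFP+; exited = Ki67-BrdU+ / GFP+. With a long
    chase after a single BrdU pulse, the Ki67- labelled class counts cells
    that incorporated the analog and then left the cycle.
    """
    if counts.n_gfp == 0:
        raise EstimatorUndefinedError("no labelled cells")
    return counts.n_ki67_brdu / counts.n_gfp, counts.n_ki67neg_brdu / counts.n_gfp


def bootstrap_kinetics(
    table: pd.DataFrame,
    design: PulseDesign,
    marker: str = "mcm2",
    n_boot: int = 2000,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    zone: Optional[str] = "VZ",
) -> KineticsEstimate:
    """Point estimates plus percentile CIs from resampling cells.

    Point estimates are the plug-in formulas on the full (filtered) table.
    Resamples on which an estimator is undefined (an empty count class) are
    dropped and counted; more than 20% drops triggers a warning.
    """
    sub = table
    if zone is not None:
        sub = sub[sub["zone"] == zone]
    sub = sub[sub["gfp"].astype(bool)].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("empty table after VZ/gfp restriction")

    def _point(t: pd.DataFrame) -> tuple:
        c = counts_from_table(t, marker=marker, zone=None, require_gfp=False)
        gf = growth_fraction(c)
        ts = estimate_ts(c, design)
        tc = estimate_tc(ts, c, gf)
        return ts, tc, gf

    ts0, tc0, gf0 = _point(sub)
    est = KineticsEstimate(
        ts_hours=ts0, tc_hours=tc0, growth_fraction=gf0,
        marker_used=marker, n_cells=len(sub), n_boot=n_boot, seed=seed,
    )
    if n_boot <= 0:
        return est

    rng = np.random.default_rng(seed)
    n = len(sub)
    samples = {"ts_hours": [], "tc_hours": [], "growth_fraction": []}
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ts, tc, gf = _point(sub.iloc[idx])
        except (EstimatorUndefinedError, ValueError):
            dropped += 1
            continue
        samples["ts_hours"].append(ts)
        samples["tc_hours"].append(tc)
        samples["growth_fraction"].append(gf)
    if dropped > 0.2 * n_boot:
        warnings.warn(
            f"{dropped}/{n_boot} bootstrap resamples hit an undefined estimator"
        )
    alpha = (1 - ci_level) / 2
    est.n_dropped_resamples = dropped
    for key, vals in samples.items():
        vals = np.asarray(vals)
        if vals.size:
            lo, hi = np.quantile(vals, [alpha, 1 - alpha])
            est.ci[key] = (float(lo), float(hi))
    return est
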