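"""Seeded generators for every input the analysis stages consume.

Three generators stand in for the study's raw microscopy and sequencing data:

* ``simulate_population`` — an asynchronous steady-state cycling population
  (uniform cycle position) with an optional quiescent fraction, dual
  thymidine-analog pulses, proliferation-marker scoring rules (Ki67 negative
  in G0 and early G1; Mcm2 positive in cycling and a configurable share of
  quiescent cells), and per-division cycle exit.
* ``simulate_counts`` — a negative-binomial gene x cell count matrix with
  three cell types (RGC/IP/EN), planted marker genes, and two promoter-group
  labels of differing composition.
* ``simulate_regnet`` — expression with planted monotone TF->target
  dependencies for regulon-recovery experiments.

All generators are deterministic under a fixed seed (one ``default_rng``
stream per call, draws in fixed order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "CycleSimConfig",
    "ScSimConfig",
    "RegNetSimConfig",
    "simulate_population",
    "simulate_counts",
    "simulate_regnet",
    "CANONICAL_MARKERS",
]

# Cell-type marker genes of the embryonic neocortex used for annotation:
# radial glia, intermediate progenitors, early neurons.
CANONICAL_MARKERS = {
    "RGC": ("Hes5", "Pax6", "Nes"),
    "IP": ("Eomes", "Hes6"),
    "EN": ("Neurod6", "Tubb3", "Dcx", "Snap25"),
}

_PHASES = ("G1", "S", "G2", "M")


@dataclass(frozen=True)
class CycleSimConfig:
    """Ground truths and design of the dual-pulse labelling simulation.

    Times are hours. ``pulse_times`` lists injections as hours before
    sacrifice, strictly decreasing (default BrdU 1.5 h, EdU 0.5 h before
    sacrifice, i.e. a 1 h interval and 0.5 h chase). ``label_windows`` gives
    each analog's availability after injection; None selects the "bridge"
    default in which each analog stays available until the next injection and
    the last is instantaneous — the availability pattern under which the
    printed plug-in estimators are unbiased.
    """

    seed: int = 0
    n_cells: int = 10_000
    t_g1: float = 7.0
    t_s: float = 5.31
    t_g2: float = 2.0
    t_m: float = 0.83
    growth_fraction: float = 1.0
    quiescent_mcm2_fraction: float = 1.0
    early_g1_ki67_negative_window: float = 2.0
    pulse_times: Sequence[float] = (1.5, 0.5)
    label_windows: Optional[Sequence[float]] = None
    exit_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for name in ("t_g1", "t_s", "t_g2", "t_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_cycle <= 0:
            raise ValueError("total cycle length must be positive")
        for name in ("growth_fraction", "quiescent_mcm2_fraction", "exit_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.early_g1_ki67_negative_window < 0:
            raise ValueError("early_g1_ki67_negative_window must be >= 0")
        pt = tuple(self.pulse_times)
        if not pt or any(t <= 0 for t in pt):
            raise ValueError("pulse_times must be positive (hours before sacrifice)")
        if any(a <= b for a, b in zip(pt, pt[1:])):
            raise ValueError("pulse_times must be strictly decreasing")
        if self.label_windows is not None:
            lw = tuple(self.label_windows)
            if len(lw) != len(pt):
                raise ValueError("need one label window per pulse")
            if any(w < 0 for w in lw):
                raise ValueError("label windows must be >= 0")

    @property
    def total_cycle(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2 + self.t_m

    def resolved_label_windows(self) -> tuple:
        if self.label_windows is not None:
            return tuple(float(w) for w in self.label_windows)
        pt = tuple(self.pulse_times)
        return tuple(
            pt[j] - pt[j + 1] if j + 1 < len(pt) else 0.0 for j in range(len(pt))
        )


def _phase_of(position: np.ndarray, config: CycleSimConfig) -> np.ndarray:
    edges = np.cumsum([config.t_g1, config.t_s, config.t_g2, config.t_m])
    return np.searchsorted(edges, position, side="right").clip(max=3)


def simulate_population(config: CycleSimConfig) -> pd.DataFrame:
    """Simulate per-cell label/marker flags at sacrifice.

    Cycling cells get a cycle position uniform over [0, Tc) at the time of
    the first injection (steady-state asynchrony) and are advanced
    deterministically to sacrifice; at each division the tracked daughter
    leaves the cycle with ``exit_probability``. Analog j labels a cell iff it
    is in S phase, and still cycling, at some instant of
    [injection_j, injection_j + window_j]. Metadata (seed, resolved windows,
    structural warnings) is attached to ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    tc = config.total_cycle
    pulses = tuple(config.pulse_times)
    windows = config.resolved_label_windows()
    horizon = pulses[0]  # first injection -> sacrifice, in simulation time

    cycling0 = rng.random(n) < config.growth_fraction
    age = rng.uniform(0.0, tc, n)  # cycle position at first injection

    # Divisions between first injection and sacrifice; exit is decided per
    # division on the tracked daughter, so each input cell yields one row.
    exit_time = np.full(n, np.inf)
    if config.exit_probability > 0:
        max_div = int(horizon // tc) + 1
        for d in range(max_div + 1):
            t_div = tc - age + d * tc
            at_risk = cycling0 & np.isinf(exit_time) & (t_div <= horizon)
            exits = at_risk & (rng.random(n) < config.exit_probability)
            exit_time[exits] = t_div[exits]

    s_start, s_end = config.t_g1, config.t_g1 + config.t_s
    n_cycles = int(np.ceil(horizon / tc)) + 2
    labels = []
    for j, inj in enumerate(pulses):
        lo = horizon - inj  # injection time on the simulation clock
        hi = min(lo + windows[j], horizon)
        hi_eff = np.minimum(hi, exit_time)
        lab = np.zeros(n, dtype=bool)
        if config.t_s > 0:
            # half-open S occurrences [start, end) per cycle k overlap the
            # availability window [lo, hi_eff] iff start <= hi_eff and lo < end
            for k in range(n_cycles):
                start = k * tc + s_start - age
                end = k * tc + s_end - age
                lab |= (start <= hi_eff) & (lo < end)
        labels.append(lab & cycling0)

    exited = np.isfinite(exit_time)
    cycling = cycling0 & ~exited
    position = np.mod(age + horizon, tc)
    phase_idx = _phase_of(position, config)
    phase = np.where(
        cycling, np.asarray(_PHASES, dtype=object)[phase_idx], "G0"
    ).astype(object)

    early_g1 = (
        cycling
        & (phase == "G1")
        & (position < config.early_g1_ki67_negative_window)
    )
    ki67 = cycling & ~early_g1
    quiescent = ~cycling  # initial G0 plus exited daughters
    mcm2 = cycling | (quiescent & (rng.random(n) < config.quiescent_mcm2_fraction))
    pvim = np.asarray(phase == "M")

    brdu = labels[0]
    edu = labels[1] if len(labels) > 1 else np.zeros(n, dtype=bool)

    table = pd.DataFrame(
        {
            "cell_id": [f"cell{idx:06d}" for idx in range(n)],
            "gfp": True,
            "cycling": cycling,
            "phase_at_sacrifice": phase,
            "brdu": brdu,
            "edu": edu,
            "ki67": ki67,
            "mcm2": mcm2,
            "pvim": pvim,
            "depth": rng.uniform(0.0, 0.25, n),
            "zone": "VZ",
        }
    )
    warnings_list = []
    if cycling0.any() and not (brdu & ~edu).any():
        warnings_list.append(
            "BrdU+EdU- class is empty: no cell left S phase between the "
            "injections (vanishing S phase, extreme label windows, or too "
            "small a sample); Ts is not estimable from this table"
        )
    table.attrs["config"] = config
    table.attrs["label_windows"] = windows
    table.attrs["warnings"] = warnings_list
    return table


@dataclass(frozen=True)
class ScSimConfig:
    """Three-type NB count matrix with two promoter groups.

    Default group sizes and type compositions follow the study design this
    generator emulates: the Notch-reporter (Hes5+) group is dominated by
    radial-glia profiles while the ubiquitous-promoter (CAG+) group is mostly
    early neurons.
    """

    seed: int = 0
    n_genes: int = 2000
    n_cells_per_group: dict = field(
        default_factory=lambda: {"CAG": 384, "Hes5": 731}
    )
    type_proportions: dict = field(
        default_factory=lambda: {
            "CAG": {"RGC": 0.1484, "IP": 0.1979, "EN": 0.6537},
            "Hes5": {"RGC": 0.7729, "IP": 0.1792, "EN": 0.0479},
        }
    )
    n_markers_per_type: int = 25
    marker_logfc: float = 2.0
    nb_dispersion: float = 2.0
    library_size_lognormal: tuple = (np.log(10_000.0), 0.35)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_markers_per_type < 0:
            raise ValueError("gene counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for group, props in self.type_proportions.items():
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise ValueError(f"type proportions for {group!r} must sum to 1")
            if set(props) != {"RGC", "IP", "EN"}:
                raise ValueError("type proportions must cover RGC/IP/EN")
        if 3 * self.n_markers_per_type > self.n_genes:
            raise ValueError("too many marker genes for n_genes")


def _marker_gene_names(config: ScSimConfig) -> dict:
    sets = {}
    for ctype in ("RGC", "IP", "EN"):
        canon = list(CANONICAL_MARKERS[ctype])[: config.n_markers_per_type]
        extra = [
            f"{ctype.capitalize()}m{i:03d}"
            for i in range(config.n_markers_per_type - len(canon))
        ]
        sets[ctype] = canon + extra
    return sets


def simulate_counts(config: ScSimConfig) -> AnnData:
    """Integer NB counts (cells x genes) with truth labels in ``obs``.

    Marker genes of each type are elevated by ``marker_logfc`` (log2) in
    cells of that type. ``uns['marker_sets']`` records the planted markers.
    """
    rng = np.random.default_rng(config.seed)
    marker_sets = _marker_gene_names(config)
    marker_genes = [g for ctype in ("RGC", "IP", "EN") for g in marker_sets[ctype]]
    n_background = config.n_genes - len(marker_genes)
    genes = marker_genes + [f"Gene{i:04d}" for i in range(n_background)]

    base = rng.lognormal(0.0, 1.0, config.n_genes)
    types = ("RGC", "IP", "EN")
    profiles = {}
    for ctype in types:
        rel = base.copy()
        idx = [genes.index(g) for g in marker_sets[ctype]]
        rel[idx] *= 2.0 ** config.marker_logfc
        profiles[ctype] = rel / rel.sum()

    groups, cell_types = [], []
    for group in sorted(config.n_cells_per_group):
        n_cells = config.n_cells_per_group[group]
        props = config.type_proportions[group]
        drawn = rng.choice(
            types, size=n_cells, p=[props[t] for t in types]
        )
        groups.extend([group] * n_cells)
        cell_types.extend(drawn.tolist())

    n_total = len(groups)
    mu_lib, sd_lib = config.library_size_lognormal
    libs = rng.lognormal(mu_lib, sd_lib, n_total)
    X = np.empty((n_total, config.n_genes), dtype=np.int64)
    theta = config.nb_dispersion
    for i in range(n_total):
        mu = libs[i] * profiles[cell_types[i]]
        lam = rng.gamma(theta, mu / theta)
        X[i] = rng.poisson(lam)

    adata = AnnData(
        X=X,
        obs=pd.DataFrame(
            {
                "group": pd.Categorical(groups),
                "true_type": pd.Categorical(cell_types),
            },
            index=[f"cell{i:05d}" for i in range(n_total)],
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.uns["marker_sets"] = {k: list(v) for k, v in marker_sets.items()}
    adata.uns["sim_seed"] = config.seed
    return adata


@dataclass(frozen=True)
class RegNetSimConfig:
    """Planted TF->target network on otherwise independent expression."""

    seed: int = 0
    n_tfs: int = 10
    targets_per_tf: int = 10
    n_cells: int = 500
    dependence_strength: float = 0.8
    noise_sd: float = 0.5
    n_background_genes: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.dependence_strength <= 1:
            raise ValueError("dependence_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_tfs, self.targets_per_tf, self.n_cells) <= 0:
            raise ValueError("sizes must be positive")


def simulate_regnet(config: RegNetSimConfig) -> tuple:
    """(expression genes x cells, true regulon map tf -> target list).

    Each TF is drawn independently standard normal; each of its targets is
    ``strength * tf + noise_sd * eps`` (a monotone dependence, so planted
    edges carry positive mutual information while non-edges carry none).
    Background genes are independent noise. Planted regulons are disjoint.
    """
    rng = np.random.default_rng(config.seed)
    tf_names = [f"TF{i:02d}" for i in range(config.n_tfs)]
    rows, names = [], []
    truth = {}
    for i, tf in enumerate(tf_names):
        tf_expr = rng.normal(0.0, 1.0, config.n_cells)
        rows.append(tf_expr)
        names.append(tf)
        targets = []
        for j in range(config.targets_per_tf):
            name = f"TG{i:02d}_{j:02d}"
            eps = rng.normal(0.0, 1.0, config.n_cells)
            rows.append(config.dependence_strength * tf_expr + config.noise_sd * eps)
            names.append(name)
            targets.append(name)
        truth[tf] = targets
    for k in range(config.n_background_genes):
        rows.append(rng.normal(0.0, 1.0, config.n_cells))
        names.append(f"BG{k:03d}")
    expr = pd.DataFrame(
        np.vstack(rows),
        index=names,
        columns=[f"cell{i:04d}" for i in range(config.n_cells)],
    )
    return expr, truth
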