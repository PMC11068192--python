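"""In-silico unilateral stimulation of a fitted whole-brain model.

Each brain area's local bifurcation parameter is shifted away from the
baseline (a = -0.02) while all other areas stay at baseline: positively in
the *synchronization* protocol (toward a stable limit cycle; default grid
-0.02 to 0.18 in steps of 0.01) and negatively in the *noise* protocol
(toward a deeper fixed point; default grid -0.02 to -0.22 in steps of
-0.02).  Each (area, intensity) cell is simulated ``n_reps`` times (default
10), the per-repetition PMS vectors are averaged, and the symmetrized KL
distance of the averaged PMS to the target state's PMS is recorded.  The
(area, intensity) cell with the minimum KL is the optimal transition; the
per-area best KL is a sensitivity map over the brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from . import hopf, leida
from ._seeds import derive_seed
from .fitting import kl_distance, simulated_pms
from .signals import DEFAULT_BAND_HZ

__all__ = [
    "PerturbationProtocol",
    "PerturbationMap",
    "TransitionReport",
    "perturb_sweep",
    "transition_report",
    "compare_sensitivity_maps",
    "repeated_optimal_stimulation",
]

BASELINE_BIFURCATION = hopf.DEFAULT_BIFURCATION  # -0.02


@dataclass(frozen=True)
class PerturbationProtocol:
    """A named sweep of bifurcation values, ordered baseline -> strongest."""

    name: str  # "synchronization" or "noise"
    intensities: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", vals)
        if vals.size == 0:
            raise ValueError("intensity grid must be non-empty")
        if self.name == "synchronization":
            if vals[0] < BASELINE_BIFURCATION - 1e-12 or np.any(np.diff(vals) <= 0):
                raise ValueError(
                    "synchronization intensities must increase strictly from "
                    f"the baseline {BASELINE_BIFURCATION}"
                )
        elif self.name == "noise":
            if vals[0] > BASELINE_BIFURCATION + 1e-12 or np.any(np.diff(vals) >= 0):
                raise ValueError(
                    "noise intensities must decrease strictly from the "
                    f"baseline {BASELINE_BIFURCATION}"
                )
        else:
            raise ValueError("protocol name must be 'synchronization' or 'noise'")

    @classmethod
    def synchronization(cls, intensities=None) -> "PerturbationProtocol":
        """Default grid -0.02 to 0.18 in steps of 0.01."""
        if intensities is None:
            intensities = np.round(np.linspace(-0.02, 0.18, 21), 10)
        return cls(name="synchronization", intensities=intensities)

    @classmethod
    def noise(cls, intensities=None) -> "PerturbationProtocol":
        """Default grid -0.02 to -0.22 in steps of -0.02."""
        if intensities is None:
            intensities = np.round(np.linspace(-0.02, -0.22, 11), 10)
        return cls(name="noise", intensities=intensities)


@dataclass(frozen=True)
class PerturbationMap:
    """KL landscape over (stimulated area, intensity) for one protocol."""

    kl: np.ndarray  # (nodes, intensities)
    protocol: PerturbationProtocol
    n_reps: int
    baseline_kl: float
    pms: np.ndarray | None = None  # (nodes, intensities, k) averaged PMS

    def to_frame(self) -> pd.DataFrame:
        nodes, n_int = self.kl.shape
        rows = [
            {"node": n + 1, "intensity": float(self.protocol.intensities[j]),
             "kl": float(self.kl[n, j])}
            for n in range(nodes)
            for j in range(n_int)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransitionReport:
    """Per-area optimal stimulation and the global best transition."""

    per_node_best: pd.DataFrame  # columns: node, intensity, kl
    global_best: tuple  # (node, intensity, kl)
    achieved: bool
    baseline_kl: float


def perturb_sweep(
    spec: hopf.HopfModelSpec,
    protocol: PerturbationProtocol,
    target_pms: np.ndarray,
    centroids: leida.CentroidSet,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    t_points: int = 295,
    n_reps: int = 10,
    seed: int = 0,
    *,
    transient_trs: float = 100.0,
    average: str = "pms",
) -> PerturbationMap:
    """Stimulate every area at every intensity and map the KL landscape.

    For each (area, intensity): the area's bifurcation parameter is set to
    the intensity, all others stay at the spec's baseline; ``n_reps``
    independently seeded simulations are run, their PMS vectors averaged
    (``average="pms"``, the default) or their KLs averaged
    (``average="kl"``), and the symmetrized KL distance to ``target_pms``
    recorded.  ``baseline_kl`` is the same quantity for the unperturbed
    model.  Per-cell seeds derive from (seed, area, intensity index, rep),
    so the map is independent of evaluation order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if average not in ("pms", "kl"):
        raise ValueError("average must be 'pms' or 'kl'")
    target_pms = np.asarray(target_pms, dtype=float)
    if target_pms.shape != (centroids.k,):
        raise ValueError("target_pms length must equal the number of centroids")

    def _cell(cell_spec, keys):
        pms_reps = np.stack([
            simulated_pms(
                cell_spec, centroids, band=band, t_points=t_points, n_runs=1,
                seed=derive_seed(seed, *keys, rep), transient_trs=transient_trs,
            )
            for rep in range(n_reps)
        ])
        mean_pms = pms_reps.mean(axis=0)
        if average == "pms":
            kl = kl_distance(mean_pms, target_pms)
        else:
            kl = float(np.mean([kl_distance(p, target_pms) for p in pms_reps]))
        return kl, mean_pms

    baseline_kl, _ = _cell(spec, (0,))
    n = spec.n_nodes
    n_int = protocol.intensities.size
    kl = np.empty((n, n_int))
    pms = np.empty((n, n_int, centroids.k))
    for node in range(n):
        for j, intensity in enumerate(protocol.intensities):
            cell_spec = spec.with_bifurcation(float(intensity), node=node)
            kl[node, j], pms[node, j] = _cell(cell_spec, (1, node, j))
    return PerturbationMap(
        kl=kl, protocol=protocol, n_reps=n_reps,
        baseline_kl=float(baseline_kl), pms=pms,
    )


def transition_report(
    pmap: PerturbationMap, achievement_threshold: float = 0.1
) -> TransitionReport:
    """Per-area and global optima of a KL landscape.

    Ties resolve to the weaker stimulation (intensity closer to baseline),
    then to the lower area index.  ``achieved`` flags whether the global
    best KL improves on the unperturbed baseline and falls below the
    threshold; it never affects the argmin itself.
    """
    kl = pmap.kl
    best_j = np.argmin(kl, axis=1)  # first occurrence = weaker intensity
    rows = [
        {"node": n + 1,
         "intensity": float(pmap.protocol.intensities[best_j[n]]),
         "kl": float(kl[n, best_j[n]])}
        for n in range(kl.shape[0])
    ]
    table = pd.DataFrame(rows)
    best_node = int(np.argmin(table["kl"].to_numpy()))  # first = lower index
    gb = (best_node + 1, float(table.loc[best_node, "intensity"]),
          float(table.loc[best_node, "kl"]))
    achieved = gb[2] < pmap.baseline_kl and gb[2] < achievement_threshold
    return TransitionReport(
        per_node_best=table, global_best=gb, achieved=bool(achieved),
        baseline_kl=pmap.baseline_kl,
    )


def compare_sensitivity_maps(a: TransitionReport, b: TransitionReport) -> tuple[float, float]:
    """Pearson correlation between two per-area best-KL sensitivity maps."""
    ka = a.per_node_best["kl"].to_numpy()
    kb = b.per_node_best["kl"].to_numpy()
    if ka.size != kb.size:
        raise ValueError("reports must cover the same node set")
    if np.ptp(ka) == 0 or np.ptp(kb) == 0:
        raise ValueError("correlation undefined for a constant sensitivity map")
    r, p = sst.pearsonr(ka, kb)
    return float(r), float(p)


def repeated_optimal_stimulation(
    spec: hopf.HopfModelSpec,
    node: int,
    intensity: float,
    target_pms: np.ndarray,
    centroids: leida.CentroidSet,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    t_points: int = 295,
    n_iter: int = 30,
    seed: int = 0,
    *,
    transient_trs: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent repetitions of one area's stimulation at one intensity.

    Returns (kl_samples, pms_samples) with one row per iteration, for
    downstream rank-based comparisons between candidate areas.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    target_pms = np.asarray(target_pms, dtype=float)
    cell_spec = spec.with_bifurcation(float(intensity), node=node)
    pms_samples = np.stack([
        simulated_pms(
            cell_spec, centroids, band=band, t_points=t_points, n_runs=1,
            seed=derive_seed(seed, node, it), transient_trs=transient_trs,
        )
        for it in range(n_iter)
    ])
    kl_samples = np.array([kl_distance(p, target_pms) for p in pms_samples])
    return kl_samples, pms_samples
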