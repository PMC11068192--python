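"""Fitting the Hopf model to an empirical PMS and optimizing connectivity.

The working point is found by sweeping the global coupling G over a grid
(default 0 to 0.5 in steps of 0.01), computing the model's PMS at each G
through the same filtering / phase / leading-eigenvector path as the
empirical data (assigned to the empirical centroids), and minimizing the
symmetrized Kullback-Leibler distance

    KL(P, Q) = 0.5 * (sum_i P_i ln(P_i / Q_i) + sum_i Q_i ln(Q_i / P_i)).

The structural coupling is then promoted to an effective connectivity by a
fixed-step gradient rule on the grand-average phase-coherence FC,
``C_ij <- C_ij + eps * (FC_emp_ij - FC_mod_ij)`` with eps = 0.01, clamped
non-negative and re-symmetrized, until the mean absolute off-diagonal FC
discrepancy falls below 0.001 or an iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hopf, leida
from ._seeds import derive_seed
from .signals import DEFAULT_BAND_HZ, PhaseSeries, bandpass_filter, instantaneous_phase

__all__ = [
    "FitResult",
    "GrandAverageFC",
    "EcOptimizationResult",
    "DEFAULT_G_GRID",
    "kl_distance",
    "simulated_pms",
    "fit_global_coupling",
    "grand_average_fc",
    "optimize_effective_connectivity",
]

#: G sweep: 0 to 0.5 in steps of 0.01.
DEFAULT_G_GRID = np.round(np.arange(0, 0.5 + 1e-9, 0.01), 10)

_KL_FLOOR = 1e-6


@dataclass(frozen=True)
class FitResult:
    """Outcome of the global-coupling grid fit."""

    g_grid: np.ndarray
    kl_curve: np.ndarray
    g_best: float
    pms_sim_best: np.ndarray


@dataclass(frozen=True)
class GrandAverageFC:
    """Time-averaged phase-coherence matrix <cos(phi_j - phi_i)>_t."""

    fc: np.ndarray  # (N, N), symmetric, unit diagonal

    def __post_init__(self) -> None:
        fc = np.asarray(self.fc, dtype=float)
        object.__setattr__(self, "fc", fc)
        if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
            raise ValueError("fc must be square")
        if not np.allclose(fc, fc.T, atol=1e-9):
            raise ValueError("fc must be symmetric")


@dataclass(frozen=True)
class EcOptimizationResult:
    """Best effective connectivity found by the gradient iteration."""

    ec: np.ndarray
    discrepancy_history: np.ndarray
    converged: bool
    iterations: int


def kl_distance(p: np.ndarray, q: np.ndarray, floor: float = _KL_FLOOR) -> float:
    """Symmetrized KL distance between two substate probability vectors.

    Entries below ``floor`` are raised to it and both vectors renormalized
    before the logarithms (the divergence is undefined at exact zeros).
    Symmetric, non-negative, zero iff the smoothed vectors are equal.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1) > 1e-9 or abs(q.sum() - 1) > 1e-9:
        raise ValueError("p and q must each sum to 1 within 1e-9")
    ps = np.maximum(p, floor)
    qs = np.maximum(q, floor)
    ps = ps / ps.sum()
    qs = qs / qs.sum()
    return float(0.5 * (np.sum(ps * np.log(ps / qs)) + np.sum(qs * np.log(qs / ps))))


def simulated_pms(
    spec: hopf.HopfModelSpec,
    centroids: leida.CentroidSet,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    t_points: int = 295,
    n_runs: int = 10,
    seed: int = 0,
    *,
    transient_trs: float = 100.0,
) -> np.ndarray:
    """Model PMS: pooled centroid occupancies over n_runs simulations.

    Each run is simulated, band-pass filtered, Hilbert phase-transformed,
    reduced to leading eigenvectors, and assigned to the (empirical)
    centroids; labels are pooled over runs before computing occupancies.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    counts = np.zeros(centroids.k, dtype=int)
    for run in range(n_runs):
        result = hopf.simulate(
            spec, t_points, derive_seed(seed, run), transient_trs=transient_trs
        )
        filt = bandpass_filter(result.x, spec.tr_seconds, band)
        phases = instantaneous_phase(filt, spec.tr_seconds)
        vecs = leida._stream_vectors(phases)
        labels = leida.assign_to_centroids(vecs, centroids)
        counts += np.bincount(labels, minlength=centroids.k)
    return counts / counts.sum()


def fit_global_coupling(
    pms_emp: np.ndarray,
    centroids: leida.CentroidSet,
    frequencies,
    connectome: np.ndarray,
    g_grid: np.ndarray = DEFAULT_G_GRID,
    t_points: int = 295,
    n_runs: int = 10,
    seed: int = 0,
    *,
    tr_seconds: float = 2.0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
) -> FitResult:
    """Grid search for the G minimizing the KL distance to the empirical PMS.

    Each grid point gets an independent seed derived from (seed, index), so
    the KL curve does not depend on evaluation order.  Ties resolve to the
    smaller G (the grid must be sorted ascending).
    """
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size == 0:
        raise ValueError("g_grid must be non-empty")
    if np.any(np.diff(g_grid) < 0):
        raise ValueError("g_grid must be sorted ascending")
    pms_emp = np.asarray(pms_emp, dtype=float)
    kl_curve = np.empty(g_grid.size)
    pms_all = np.empty((g_grid.size, centroids.k))
    for i, g in enumerate(g_grid):
        spec = hopf.default_spec(frequencies, connectome, g, tr_seconds=tr_seconds)
        pms = simulated_pms(
            spec, centroids, band=band, t_points=t_points,
            n_runs=n_runs, seed=derive_seed(seed, i),
        )
        pms_all[i] = pms
        kl_curve[i] = kl_distance(pms_emp, pms)
    best = int(np.argmin(kl_curve))
    return FitResult(
        g_grid=g_grid,
        kl_curve=kl_curve,
        g_best=float(g_grid[best]),
        pms_sim_best=pms_all[best],
    )


def grand_average_fc(phase_sets) -> GrandAverageFC:
    """Grand-average phase coherence FC_ij = <cos(phi_j - phi_i)> over time.

    Accepts one PhaseSeries or an iterable of them; all timepoints of all
    series are pooled into the average.
    """
    if isinstance(phase_sets, PhaseSeries):
        phase_sets = [phase_sets]
    phase_sets = list(phase_sets)
    if not phase_sets:
        raise ValueError("phase_sets must be non-empty")
    n = phase_sets[0].n_nodes
    acc = np.zeros((n, n))
    total = 0
    for ps in phase_sets:
        if ps.n_nodes != n:
            raise ValueError("all phase series must share the node count")
        z = np.exp(1j * ps.phases)  # (N, T)
        acc += np.real(z @ z.conj().T)
        total += ps.t_points
    fc = acc / total
    fc = (fc + fc.T) / 2
    np.fill_diagonal(fc, 1.0)
    return GrandAverageFC(fc=fc)


def optimize_effective_connectivity(
    spec: hopf.HopfModelSpec,
    fc_emp: GrandAverageFC,
    epsilon: float = 0.01,
    tol: float = 0.001,
    max_iter: int = 200,
    *,
    t_points: int = 295,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    transient_trs: float = 100.0,
    seed: int = 0,
) -> EcOptimizationResult:
    """Fixed-step gradient adjustment of C toward the empirical phase FC.

    Per iteration: simulate with the current C, compute the model's
    grand-average phase-coherence FC through the band-pass + Hilbert path,
    measure the mean absolute off-diagonal discrepancy, then update every
    off-diagonal pair by ``eps * (FC_emp - FC_mod)``, clamp at zero and
    re-symmetrize.  Stops when the discrepancy drops below ``tol`` or after
    ``max_iter`` iterations; the iterate with the lowest discrepancy is
    returned.  Ten consecutive discrepancy increases raise an error.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = spec.n_nodes
    off = ~np.eye(n, dtype=bool)
    c = spec.coupling_matrix.copy()
    history = []
    best_c = c.copy()
    best_disc = np.inf
    converged = False
    rising = 0
    for it in range(max_iter):
        result = hopf.simulate(
            spec.with_coupling_matrix(c), t_points, derive_seed(seed, it),
            transient_trs=transient_trs,
        )
        filt = bandpass_filter(result.x, spec.tr_seconds, band)
        phases = instantaneous_phase(filt, spec.tr_seconds)
        fc_mod = grand_average_fc(phases).fc
        disc = float(np.mean(np.abs(fc_emp.fc[off] - fc_mod[off])))
        history.append(disc)
        if disc < best_disc:
            best_disc = disc
            best_c = c.copy()
        rising = rising + 1 if len(history) > 1 and disc > history[-2] else 0
        if rising >= 10:
            raise RuntimeError(
                "effective-connectivity optimization diverged "
                f"(10 consecutive increases); history = {history}"
            )
        if disc < tol:
            converged = True
            break
        delta = epsilon * (fc_emp.fc - fc_mod)
        c = c + np.where(off, delta, 0.0)
        c = np.maximum((c + c.T) / 2, 0.0)
        np.fill_diagonal(c, 0.0)
    return EcOptimizationResult(
        ec=best_c,
        discrepancy_history=np.asarray(history),
        converged=converged,
        iterations=len(history),
    )
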