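"""Synthetic connectomes and multi-group BOLD-like cohorts.

The empirical inputs of this kind of study — parcellated resting-state BOLD
series for three groups (healthy controls and two disorders-of-consciousness
groups with graded loss of whole-brain phase synchrony) plus a DTI-derived
structural connectome — are emulated here with known ground truth so every
downstream stage is testable.

Connectomes are connected random graphs with right-skewed (exponential)
edge weights, mirroring the heavy tail of streamline-count matrices, scaled
so the maximum entry equals a normalization ceiling (default 0.2).  Group
differences are induced primarily through the global coupling G of the Hopf
generator: stronger coupling yields higher whole-brain phase synchrony, the
ordering observed empirically across control > MCS > UWS groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hopf
from ._seeds import derive_seed, rng_for
from .signals import DEFAULT_BAND_HZ

__all__ = [
    "SyntheticConnectome",
    "GroupRegime",
    "BoldCohort",
    "make_structural_connectome",
    "make_group_cohort",
    "make_benchmark_scene",
    "BENCHMARK_COUPLINGS",
]

#: Normalization ceiling for structural weights.
DEFAULT_CEILING = 0.2

#: Generating global couplings of the three benchmark regimes.  Strong,
#: intermediate, and weak long-range coupling produce the graded
#: whole-brain synchrony ordering control-like > MCS-like > UWS-like.
BENCHMARK_COUPLINGS = {"control": 0.5, "mcs_like": 0.2, "uws_like": 0.02}


@dataclass(frozen=True)
class SyntheticConnectome:
    """Symmetric non-negative structural coupling matrix with zero diagonal."""

    weights: np.ndarray  # (N, N)
    n_nodes: int
    density: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("weights shape does not match n_nodes")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")


@dataclass(frozen=True)
class GroupRegime:
    """Ground-truth generating parameters of one subject group."""

    label: str
    n_subjects: int
    coupling: float  # global coupling G of the generator
    noise_sd: float = hopf.DEFAULT_NOISE_SD  # beta
    bifurcation_profile: np.ndarray | None = None  # per-node a_n; default -0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.coupling < 0:
            raise ValueError("coupling must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def bifurcation(self, n_nodes: int) -> np.ndarray:
        if self.bifurcation_profile is None:
            return np.full(n_nodes, hopf.DEFAULT_BIFURCATION)
        a = np.asarray(self.bifurcation_profile, dtype=float)
        if a.shape != (n_nodes,):
            raise ValueError("bifurcation_profile length does not match n_nodes")
        return a


@dataclass(frozen=True)
class BoldCohort:
    """Per-subject region-by-time series with group labels and TR."""

    series: tuple  # of (N, T) float arrays
    tr_seconds: float
    group_labels: tuple  # of str, one per subject
    node_ids: tuple  # of str, one per node
    subject_ids: tuple = ()  # of str; defaults to sub-001, ...

    def __post_init__(self) -> None:
        series = tuple(np.asarray(s, dtype=float) for s in self.series)
        object.__setattr__(self, "series", series)
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if not series:
            raise ValueError("cohort must contain at least one subject")
        n = series[0].shape[0]
        for i, s in enumerate(series):
            if s.ndim != 2 or s.shape[0] != n:
                raise ValueError(f"subject {i} does not share the node count {n}")
            if s.shape[1] < 20:
                raise ValueError(f"subject {i} has fewer than 20 timepoints")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"subject {i} contains non-finite values")
        if len(self.group_labels) != len(series):
            raise ValueError("one group label per subject required")
        if len(self.node_ids) != n:
            raise ValueError("one node id per node required")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.subject_ids:
            object.__setattr__(
                self,
                "subject_ids",
                tuple(f"sub-{i + 1:03d}" for i in range(len(series))),
            )
        elif len(self.subject_ids) != len(series):
            raise ValueError("one subject id per subject required")
        else:
            object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_nodes(self) -> int:
        return self.series[0].shape[0]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.group_labels))

    def discard_initial_volumes(self, n_discard: int) -> "BoldCohort":
        """Drop the first ``n_discard`` volumes of every subject.

        Emulates the standard removal of initial acquisition volumes
        (e.g. 300 acquired, first 5 discarded, 295 retained).
        """
        if n_discard < 0:
            raise ValueError("n_discard must be non-negative")
        return BoldCohort(
            series=tuple(s[:, n_discard:] for s in self.series),
            tr_seconds=self.tr_seconds,
            group_labels=self.group_labels,
            node_ids=self.node_ids,
            subject_ids=self.subject_ids,
        )


def make_structural_connectome(
    n_nodes: int,
    density: float = 0.35,
    ceiling: float = DEFAULT_CEILING,
    seed: int = 0,
) -> SyntheticConnectome:
    """Connected random graph with exponential weights, max scaled to ceiling.

    A random spanning tree guarantees a single connected component; extra
    edges are added uniformly at random until the target density is reached.
    Edge weights are Exponential(1) draws (right-skewed, like streamline
    counts), symmetrized, and rescaled so the maximum entry equals
    ``ceiling``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    max_edges = n_nodes * (n_nodes - 1) // 2
    m_target = int(round(density * max_edges))
    if m_target < n_nodes - 1:
        raise ValueError(
            f"density {density} gives {m_target} edges; at least "
            f"{n_nodes - 1} are needed for a connected graph on "
            f"{n_nodes} nodes"
        )
    rng = rng_for(seed)
    order = rng.permutation(n_nodes)
    edges = set()
    for i in range(1, n_nodes):  # random spanning tree
        j = rng.integers(0, i)
        a, b = int(order[i]), int(order[j])
        edges.add((min(a, b), max(a, b)))
    if m_target > len(edges):
        candidates = [
            (i, j)
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if (i, j) not in edges
        ]
        extra = rng.choice(len(candidates), size=m_target - len(edges), replace=False)
        edges.update(candidates[e] for e in extra)
    w = np.zeros((n_nodes, n_nodes))
    for i, j in sorted(edges):
        w[i, j] = w[j, i] = rng.exponential(1.0)
    w *= ceiling / w.max()
    return SyntheticConnectome(weights=w, n_nodes=n_nodes, density=density)


def make_group_cohort(
    connectome: SyntheticConnectome,
    regimes: list[GroupRegime],
    t_points: int,
    tr_seconds: float = 2.0,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
) -> BoldCohort:
    """Simulate one BOLD-like series per subject per regime.

    Node natural frequencies are drawn once, uniformly within the analysis
    band, and shared by all subjects (they stand for the common parcellation
    of a single scanner protocol).  Subject s (global index across regimes,
    in regime order) is simulated with a seed derived from (seed, 1, s), so
    appending subjects or regimes never changes earlier subjects' data.
    """
    if not regimes:
        raise ValueError("regimes must be non-empty")
    if t_points < 20:
        raise ValueError("t_points must be at least 20")
    n = connectome.n_nodes
    f_hz = rng_for(seed, 0).uniform(band[0], band[1], size=n)
    omega = 2 * np.pi * f_hz
    series, labels = [], []
    g_index = 0
    for regime in regimes:
        a = regime.bifurcation(n)
        spec = hopf.HopfModelSpec(
            n_nodes=n,
            a=a,
            omega=omega,
            coupling_matrix=connectome.weights,
            global_coupling=regime.coupling,
            noise_sd=regime.noise_sd,
            tr_seconds=tr_seconds,
        )
        for _ in range(regime.n_subjects):
            sub_seed = derive_seed(seed, 1, g_index)
            try:
                result = hopf.simulate(spec, t_points, sub_seed)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"simulation diverged for subject {g_index} "
                    f"(group {regime.label!r}): {err}"
                ) from err
            series.append(result.x)
            labels.append(regime.label)
            g_index += 1
    node_ids = [f"node-{i + 1:03d}" for i in range(n)]
    return BoldCohort(
        series=tuple(series),
        tr_seconds=tr_seconds,
        group_labels=tuple(labels),
        node_ids=tuple(node_ids),
    )


def make_benchmark_scene(
    n_nodes: int = 20,
    seed: int = 0,
    *,
    n_subjects_per_group: int = 4,
    t_points: int = 295,
    tr_seconds: float = 2.0,
    density: float = 0.35,
) -> tuple[BoldCohort, SyntheticConnectome, dict]:
    """Three-group benchmark with strictly ordered generating couplings.

    Returns the cohort, the connectome, and the ground-truth regimes keyed
    by group label, with couplings control-like > MCS-like > UWS-like.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be at least 10")
    connectome = make_structural_connectome(n_nodes, density=density, seed=derive_seed(seed, 100))
    regimes = [
        GroupRegime(label=label, n_subjects=n_subjects_per_group, coupling=g)
        for label, g in BENCHMARK_COUPLINGS.items()
    ]
    cohort = make_group_cohort(
        connectome, regimes, t_points=t_points, tr_seconds=tr_seconds, seed=seed
    )
    ground_truth = {r.label: r for r in regimes}
    return cohort, connectome, ground_truth
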