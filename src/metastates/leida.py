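"""Leading Eigenvector Dynamics Analysis (LEiDA).

At every repetition time the pairwise BOLD phase coherence
``dFC(n, p, t) = cos(theta(n, t) - theta(p, t))`` forms a symmetric matrix
with unit diagonal.  Its leading eigenvector V1(t) captures the dominant
phase-locking pattern; the pooled eigenvectors from all subjects and
timepoints are clustered with K-means into k recurrent metastable
substates.  The probability of occurrence of each substate per group — the
fraction of epochs assigned to its cluster — is the Probabilistic
Metastable Substate (PMS) space characterizing that group's brain state.

The module also provides the Kuramoto order parameter (instantaneous global
phase synchrony) and permutation rank-sum statistics with
Benjamini-Hochberg FDR correction for group comparisons of substate
occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sst
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_seed
from .signals import DEFAULT_BAND_HZ, PhaseSeries, bandpass_filter, instantaneous_phase

__all__ = [
    "LeadingEigenvectorStream",
    "CentroidSet",
    "PmsProfile",
    "SynchronyProfile",
    "phase_coherence_at",
    "phase_coherence_matrices",
    "leading_eigenvector",
    "fix_eigenvector_sign",
    "build_eigenvector_stream",
    "cluster_eigenvectors",
    "assign_to_centroids",
    "occupancy",
    "subject_occupancies",
    "kuramoto_order",
    "group_difference_test",
    "pairwise_occupancy_tests",
    "recommend_k",
]


@dataclass(frozen=True)
class LeadingEigenvectorStream:
    """Pooled unit-norm leading eigenvectors with provenance labels."""

    vectors: np.ndarray  # (S, N)
    subject_of: np.ndarray  # (S,) int
    time_of: np.ndarray  # (S,) int
    group_of: np.ndarray  # (S,) str

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen = dict.fromkeys(self.group_of.tolist())
        return list(seen)


@dataclass(frozen=True)
class CentroidSet:
    """K-means cluster centroids V_c: the substate repertoire."""

    centroids: np.ndarray  # (k, N)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "centroids", c)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValueError("centroids must be a (k, N) array")
        if not np.all(np.isfinite(c)):
            raise ValueError("centroids must be finite")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.centroids.shape[1]


@dataclass(frozen=True)
class PmsProfile:
    """Per-group substate occurrence probabilities (the PMS space)."""

    groups: list[str]
    counts: dict  # group -> (k,) int array
    probabilities: dict  # group -> (k,) float array

    def probability_vector(self, group: str) -> np.ndarray:
        return self.probabilities[group]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for i, (c, p) in enumerate(zip(self.counts[g], self.probabilities[g])):
                rows.append({"group": g, "substate": i + 1, "count": int(c),
                             "probability": float(p)})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SynchronyProfile:
    """Kuramoto order parameter r(t) of one phase series."""

    r_t: np.ndarray  # (T,)
    mean_r: float
    sd_r: float


def phase_coherence_at(phases: PhaseSeries, t: int) -> np.ndarray:
    """Phase-coherence matrix cos(theta_n - theta_p) at timepoint t."""
    if not 0 <= t < phases.t_points:
        raise IndexError(f"t = {t} outside [0, {phases.t_points})")
    theta = phases.phases[:, t]
    return np.cos(theta[:, None] - theta[None, :])


def phase_coherence_matrices(phases: PhaseSeries) -> np.ndarray:
    """All T phase-coherence matrices as a (T, N, N) array.

    Uses cos(a - b) = cos a cos b + sin a sin b, so each matrix is the
    rank-2 sum of outer products of the cosine and sine node vectors.
    """
    c = np.cos(phases.phases)  # (N, T)
    s = np.sin(phases.phases)
    mats = np.einsum("nt,pt->tnp", c, c) + np.einsum("nt,pt->tnp", s, s)
    return mats


def fix_eigenvector_sign(v: np.ndarray) -> np.ndarray:
    """Apply the sign convention: at most half the components strictly positive.

    If exactly half are positive, flip so the largest-magnitude component is
    negative.  Idempotent.
    """
    v = np.asarray(v, dtype=float)
    n_pos = int(np.sum(v > 0))
    n = v.size
    if 2 * n_pos > n:
        return -v
    if 2 * n_pos == n and v[np.argmax(np.abs(v))] > 0:
        return -v
    return v


def leading_eigenvector(coherence: np.ndarray) -> np.ndarray:
    """Unit-norm eigenvector of the largest eigenvalue, sign-fixed.

    The input must be symmetric to within 1e-9 and finite.
    """
    m = np.asarray(coherence, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("input must be finite")
    if np.max(np.abs(m - m.T)) > 1e-9:
        raise ValueError("input must be symmetric (asymmetry beyond 1e-9)")
    n = m.shape[0]
    _, vec = sla.eigh(m, subset_by_index=[n - 1, n - 1])
    return fix_eigenvector_sign(vec[:, 0])


def _stream_vectors(phases: PhaseSeries) -> np.ndarray:
    """Leading eigenvectors of every timepoint's coherence matrix, (T, N)."""
    mats = phase_coherence_matrices(phases)
    _, vecs = np.linalg.eigh(mats)  # batched; eigenvalues ascending
    top = vecs[:, :, -1]
    # vectorized sign convention over rows
    n = top.shape[1]
    n_pos = np.sum(top > 0, axis=1)
    flip = 2 * n_pos > n
    tie = 2 * n_pos == n
    if np.any(tie):
        idx = np.argmax(np.abs(top), axis=1)
        tie_pos = top[np.arange(top.shape[0]), idx] > 0
        flip = flip | (tie & tie_pos)
    top[flip] *= -1
    return top


def build_eigenvector_stream(
    cohort, band: tuple[float, float] = DEFAULT_BAND_HZ
) -> LeadingEigenvectorStream:
    """Filter, phase-transform, and reduce every subject-timepoint to V1(t)."""
    vectors, subject_of, time_of, group_of = [], [], [], []
    for s, series in enumerate(cohort.series):
        filt = bandpass_filter(series, cohort.tr_seconds, band)
        phases = instantaneous_phase(filt, cohort.tr_seconds)
        vecs = _stream_vectors(phases)
        t = vecs.shape[0]
        vectors.append(vecs)
        subject_of.append(np.full(t, s, dtype=int))
        time_of.append(np.arange(t, dtype=int))
        group_of.append(np.full(t, cohort.group_labels[s], dtype=object))
    return LeadingEigenvectorStream(
        vectors=np.vstack(vectors),
        subject_of=np.concatenate(subject_of),
        time_of=np.concatenate(time_of),
        group_of=np.concatenate(group_of),
    )


def cluster_eigenvectors(
    stream: LeadingEigenvectorStream,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    *,
    reference_group: str | None = None,
) -> tuple[CentroidSet, np.ndarray]:
    """K-means clustering of the pooled eigenvectors into k substates.

    Euclidean distance, ``n_restarts`` initializations, 300-iteration cap.
    Clusters are relabeled by descending occupancy in ``reference_group``
    (default: the stream's first group), so substate 1 is the pattern most
    visited by the reference (control-like) group.
    """
    s = stream.n_samples
    if not 2 <= k <= s:
        raise ValueError(f"k must be in [2, {s}]")
    n_distinct = np.unique(stream.vectors, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k = {k} exceeds the {n_distinct} distinct stream rows")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=300,
        random_state=derive_seed(seed, k),
    )
    labels = km.fit_predict(stream.vectors)
    centroids = km.cluster_centers_

    ref = reference_group if reference_group is not None else stream.groups[0]
    in_ref = stream.group_of == ref
    ref_counts = np.bincount(labels[in_ref], minlength=k)
    order = np.argsort(-ref_counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return CentroidSet(centroids=centroids[order]), relabel[labels]


def assign_to_centroids(stream, centroids: CentroidSet) -> np.ndarray:
    """Nearest-centroid (Euclidean) hard assignment; ties to the lowest index."""
    vectors = stream.vectors if hasattr(stream, "vectors") else np.asarray(stream)
    if vectors.shape[1] != centroids.n_nodes:
        raise ValueError(
            f"stream dimension {vectors.shape[1]} does not match centroid "
            f"dimension {centroids.n_nodes}"
        )
    d2 = (
        np.sum(vectors**2, axis=1)[:, None]
        - 2 * vectors @ centroids.centroids.T
        + np.sum(centroids.centroids**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def occupancy(labels: np.ndarray, group_of: np.ndarray, k: int) -> PmsProfile:
    """Per-group substate counts and occurrence probabilities."""
    labels = np.asarray(labels)
    group_of = np.asarray(group_of, dtype=object)
    if labels.size != group_of.size:
        raise ValueError("labels and group_of must have equal length")
    if labels.size == 0:
        raise ValueError("empty label vector")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    groups = list(dict.fromkeys(group_of.tolist()))
    counts, probs = {}, {}
    for g in groups:
        in_g = group_of == g
        total = int(np.sum(in_g))
        if total == 0:
            raise ValueError(f"group {g!r} has no epochs")
        c = np.bincount(labels[in_g], minlength=k)
        counts[g] = c
        probs[g] = c / total
    return PmsProfile(groups=groups, counts=counts, probabilities=probs)


def subject_occupancies(
    labels: np.ndarray,
    subject_of: np.ndarray,
    group_of: np.ndarray,
    k: int,
) -> pd.DataFrame:
    """Per-subject occupancy fractions (rows: subjects; columns: substates).

    These are the sampling units for the permutation rank-sum tests; the
    group-level PMS is the epoch-pooled version from :func:`occupancy`.
    """
    labels = np.asarray(labels)
    subject_of = np.asarray(subject_of)
    group_of = np.asarray(group_of, dtype=object)
    rows = []
    for subj in dict.fromkeys(subject_of.tolist()):
        mask = subject_of == subj
        frac = np.bincount(labels[mask], minlength=k) / np.sum(mask)
        rows.append({"subject": subj, "group": group_of[mask][0],
                     **{f"substate_{i + 1}": frac[i] for i in range(k)}})
    return pd.DataFrame(rows)


def kuramoto_order(phases: PhaseSeries) -> SynchronyProfile:
    """Kuramoto order parameter r(t) = |mean_n exp(i theta_n(t))|."""
    if phases.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    z = np.exp(1j * phases.phases)
    r_t = np.abs(z.mean(axis=0))
    return SynchronyProfile(r_t=r_t, mean_r=float(r_t.mean()), sd_r=float(r_t.std()))


def group_difference_test(
    occ_a: np.ndarray,
    occ_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation rank-sum test per substate, with BH correction.

    ``occ_a`` and ``occ_b`` are (subjects x k) per-subject occupancy
    matrices.  The statistic is the group-A rank sum; subject group labels
    are shuffled ``n_perm`` times and
    ``p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1)``.
    """
    occ_a = np.atleast_2d(np.asarray(occ_a, dtype=float))
    occ_b = np.atleast_2d(np.asarray(occ_b, dtype=float))
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if occ_a.shape[0] < 2 or occ_b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if occ_a.shape[1] != occ_b.shape[1]:
        raise ValueError("occupancy matrices must share k")
    na = occ_a.shape[0]
    data = np.vstack([occ_a, occ_b])
    n = data.shape[0]
    ranks = sst.rankdata(data, axis=0)
    mu = na * (n + 1) / 2.0
    obs_dev = np.abs(ranks[:na].sum(axis=0) - mu)
    rng = np.random.default_rng(derive_seed(seed))
    exceed = np.zeros(data.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dev = np.abs(ranks[perm[:na]].sum(axis=0) - mu)
        exceed += dev >= obs_dev
    p_raw = (1 + exceed) / (n_perm + 1)
    p_fdr = multipletests(p_raw, method="fdr_bh")[1]
    return p_raw, p_fdr


def pairwise_occupancy_tests(
    subject_occ: pd.DataFrame,
    k: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise group contrasts, BH-corrected across the whole family.

    The family is every substate of every pairwise contrast at this k.
    """
    cols = [f"substate_{i + 1}" for i in range(k)]
    groups = list(dict.fromkeys(subject_occ["group"].tolist()))
    rows = []
    raw = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            occ_a = subject_occ.loc[subject_occ["group"] == ga, cols].to_numpy()
            occ_b = subject_occ.loc[subject_occ["group"] == gb, cols].to_numpy()
            p_raw, _ = group_difference_test(
                occ_a, occ_b, n_perm=n_perm, seed=derive_seed(seed, i, groups.index(gb))
            )
            for s in range(k):
                rows.append({"contrast": f"{ga} vs {gb}", "substate": s + 1,
                             "p_raw": float(p_raw[s])})
                raw.append(p_raw[s])
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(np.asarray(raw), method="fdr_bh")[1]
    return out


def recommend_k(
    stream: LeadingEigenvectorStream,
    k_values=range(3, 9),
    n_restarts: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    *,
    reference_group: str | None = None,
) -> tuple[int | None, dict]:
    """Smallest k whose substates separate every pair of groups after FDR.

    Runs the full k sweep (deterministic under the seed), testing per-subject
    occupancies for every pairwise contrast; returns the recommended k (or
    None if no k qualifies) plus the per-k result tables.
    """
    results = {}
    best = None
    for k in k_values:
        centroids, labels = cluster_eigenvectors(
            stream, k, n_restarts, seed, reference_group=reference_group
        )
        subj = subject_occupancies(labels, stream.subject_of, stream.group_of, k)
        stats = pairwise_occupancy_tests(subj, k, n_perm=n_perm, seed=derive_seed(seed, k))
        results[k] = {"centroids": centroids, "labels": labels, "stats": stats}
        sig = stats[stats["p_fdr"] < alpha]
        contrasts = set(stats["contrast"])
        if best is None and set(sig["contrast"]) == contrasts:
            best = k
    return best, results
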