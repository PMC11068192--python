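# Methods

## Overview

`metastates` implements a two-stage analysis of parcellated BOLD-like time
series:

1. a **model-free** characterization of a group's brain state as a
   Probabilistic Metastable Substate (PMS) space, obtained by leading
   eigenvector dynamics analysis (LEiDA) of time-resolved phase-coherence
   matrices; and
2. a **model-based** stage in which a network of coupled Stuart-Landau
   (supercritical Hopf) oscillators on a structural connectome is fitted to
   the empirical PMS, promoted to an effective connectivity, and perturbed
   one node at a time in silico to identify stimulation targets that force
   a transition toward a target state's PMS.

Because the kind of empirical cohort this pipeline targets (multi-group
resting-state fMRI plus a DTI connectome) is not freely redistributable,
the package ships a synthetic-cohort generator with known ground truth;
every downstream stage is exercised and validated against it.

## Model-free stage (LEiDA)

Each subject's region-by-time series is demeaned, linearly detrended, and
band-pass filtered to 0.04–0.07 Hz with a second-order Butterworth filter
applied forward and backward (zero phase).  The instantaneous phase
θ(n, t) of node n is the angle of the analytic (Hilbert) signal.  At every
repetition time the phase-coherence matrix

    dFC(n, p, t) = cos(θ(n, t) − θ(p, t))

is symmetric with unit diagonal; its leading eigenvector V₁(t) (unit norm)
summarizes the dominant phase-locking pattern.  Eigenvector signs are fixed
so that at most half the components are strictly positive; at an exact tie
the largest-magnitude component is made negative (the dominant community is
negative, the standard convention in this literature).  All subject-time
eigenvectors are pooled and clustered with K-means (Euclidean distance,
20 restarts by default, 300-iteration cap); cluster centroids are the
substate repertoire, and clusters are relabeled by descending occupancy in
a designated reference (control-like) group.  A group's PMS is the vector
of fractions of its pooled epochs assigned to each substate.  Per-subject
occupancy fractions — the sampling units for statistics — are provided
separately from the epoch-pooled group PMS.

Group contrasts use two-sided permutation tests of the rank-sum statistic
on per-subject occupancies (default 1000 permutations,
p = (1 + #{|stat*| ≥ |stat|}) / (n_perm + 1)), with Benjamini–Hochberg FDR
correction across the family of all substates × all pairwise contrasts at
a given k.  Permutations shuffle subject labels, not epochs: epochs within
a subject are strongly dependent, so subject is the exchangeable unit.
The full k = 3..8 sweep is exposed; `recommend_k` reports the smallest k
whose substates separate every pair of groups after FDR, rather than
hard-coding a particular k.

The Kuramoto order parameter r(t) = |mean_n exp(iθ(n, t))| summarizes
instantaneous whole-brain synchrony and is used to verify the generator's
graded-synchrony ground truth.

Design notes: the Hilbert transform's edge samples are retained (every
timepoint of every subject enters clustering); K-means uses Euclidean
distance (the distance metric is a free choice here — cosine-type metrics
appear in parts of this literature, and the choice is configurable in
principle but fixed to Euclidean for determinism of the contract).

## Model-based stage (coupled Hopf network)

Each node n obeys the normal form of a supercritical Hopf bifurcation in
Cartesian coordinates, coupled by differences through a symmetric matrix C
scaled by a global coupling G:

    dx_n/dt = [a_n − x_n² − y_n²] x_n − ω_n y_n + G Σ_p C_np (x_p − x_n) + β η_n(t)
    dy_n/dt = [a_n − x_n² − y_n²] y_n + ω_n x_n + G Σ_p C_np (y_p − y_n) + β η_n(t)

x_n is the BOLD-like observable.  For a_n < 0 the node relaxes to a fixed
point and emits noise-driven fluctuations; for a_n > 0 it settles on a limit
cycle of radius √a_n at frequency ω_n/2π.  Defaults: a_n = −0.02 everywhere
(subcritical working point), β = 0.01, ω_n = 2π f_n with f_n the per-node
spectral peak of the band-filtered data averaged over subjects and clamped
into the band.

Integration is Euler–Maruyama with dt = 0.1 s (required to divide the TR;
the dynamics are slow, ≤ 0.07 Hz, so this step is conservative — halving dt
changes summary synchrony by less than across-seed variability, which is
asserted in the tests).  Independent Gaussian increments of SD β·√dt enter
both coordinates.  Initial conditions are uniform in [−0.1, 0.1]² per node;
a transient of 100 TRs is discarded; x is recorded once per TR.

### Fitting the global coupling

The working point G is found by grid search (default 0 to 0.5 in steps of
0.01).  For each G the model is simulated n_runs times; each run passes
through exactly the empirical path (band-pass → Hilbert phase → leading
eigenvectors) and is assigned to the *empirical* centroids; labels pooled
over runs give the simulated PMS.  The objective is the symmetrized
Kullback–Leibler distance

    KL(P, Q) = ½ (Σ_i P_i ln(P_i/Q_i) + Σ_i Q_i ln(Q_i/P_i)),

with entries below 1e-6 raised to 1e-6 and renormalized before the
logarithms (the divergence is undefined at exact zeros; the smoothing
preserves the ordering of fits).  Ties resolve to the smaller G.  Each grid
point uses an independent seed derived from (master seed, grid index), so
the KL curve is independent of evaluation order.  The reference protocol
in this literature iterates the model 250 times per grid point; here
n_runs is configurable (250 reproduces that protocol; desk-scale
experiments use 5–20).

### Effective connectivity

Starting from the structural matrix (normalized so its maximum entry is
0.2), each off-diagonal pair is adjusted by the fixed-step rule

    C_ij ← C_ij + ε (FC_emp_ij − FC_mod_ij),   ε = 0.01,

where FC is the grand-average phase coherence ⟨cos(φ_j(t) − φ_i(t))⟩ over
all timepoints (and subjects, for the empirical side).  Updates apply to
*all* off-diagonal pairs, so absent structural links can be discovered;
after each update the matrix is clamped non-negative and re-symmetrized by
averaging with its transpose.  The loop stops when the mean absolute
off-diagonal discrepancy falls below 0.001 or at the iteration cap
(default 200); the iterate with the lowest discrepancy is returned, and
ten consecutive discrepancy increases abort with the history attached.
Simulated signals are band-pass filtered before the Hilbert transform,
mirroring the empirical path, so the two FC matrices are commensurable.

### In-silico perturbation

Stimulation is unilateral: one node's bifurcation parameter is moved while
all others stay at −0.02.  The synchronization protocol sweeps a from
−0.02 to 0.18 in steps of 0.01 (toward self-sustained oscillation); the
noise protocol sweeps from −0.02 to −0.22 in steps of −0.02 (toward a
deeper fixed point).  Each (node, intensity) cell runs 10 repetitions by
default with seeds derived from (master seed, node, intensity index,
repetition) — the map is reproducible cell-by-cell and independent of
evaluation order.  Per-repetition PMS vectors are averaged before a single
KL to the target (more stable than averaging per-repetition KLs; both
modes are exposed).  The unperturbed baseline KL is computed the same way.
The per-node minimum over intensities is the sensitivity map; the global
minimum is the optimal transition, with ties resolved to the weaker
stimulation and then the lower node index.  A transition counts as
"achieved" when the best KL beats the baseline and falls below a reporting
threshold (default 0.1); the flag never affects the argmin.  Repeated
stimulation at a fixed (node, intensity) (default 30 iterations) yields KL
samples for rank-based comparisons between candidate target areas.

## Synthetic cohorts and what they do (not) show

`make_structural_connectome` builds a connected random graph (random
spanning tree plus uniform extra edges to the target density) with
Exponential(1) edge weights — right-skewed, like streamline-count
matrices — symmetrized and rescaled so the maximum entry equals 0.2.

`make_group_cohort` simulates each subject from the Hopf model.  Node
frequencies are drawn once per cohort, uniformly in the analysis band
(0.04–0.07 Hz), and shared across subjects, standing for a common
parcellation and protocol.  Per-subject seeds derive from (master seed, 1,
global subject index), so appending subjects or regimes never changes
earlier subjects' data.

`make_benchmark_scene` builds three groups of equal size whose generating
couplings are strictly ordered: control-like G = 0.5, MCS-like G = 0.2,
UWS-like G = 0.02 (all at a = −0.02, β = 0.01, 295 timepoints at TR = 2 s,
4 subjects per group by default).  Group differences are induced through G
alone — the model-space analogue of the empirical finding that less
responsive groups fit at lower coupling.  These values were chosen so that
mean Kuramoto synchrony is reliably graded across groups at N = 20; with
narrower separations the group ordering is not stable against connectome
and noise realizations at desk scale.

The generator emulates band-limited oscillatory dynamics, graded
whole-brain synchrony, and a heavy-tailed connectome.  It does **not**
emulate hemodynamic convolution, scanner noise, motion, lesion
heterogeneity, or subject-level connectome variability, so passing tests
demonstrate correctness and recoverability of the *method*, not clinical
validity on real cohorts.

## Problem sizes of the recovery experiments

The packaged experiments run at desk scale, chosen so each validates a
specific property with comfortable statistical margin:

- **Global-coupling recovery**: N = 20 fully dense connectome, node
  frequencies drawn in 0.05–0.06 Hz, G* = 0.05, grid 0–0.2 in steps of
  0.01, k = 3 centroids clustered from runs pooled over G ∈ {0, 0.05,
  0.15} (the analogue of pooling all groups before clustering), empirical
  target PMS from 20 runs, 5 runs per grid point.  The dense connectome
  and narrow detuning place the synchronization-sensitive region of G
  inside the grid; with band-wide detuning on a sparse N = 20 graph the
  PMS is nearly flat over 0–0.2 and G* is unidentifiable — at full
  empirical scale (hundreds of nodes, much larger row sums) the sensitive
  region sits at much smaller G, which is why empirical fits land near
  0.04–0.07.
- **Effective-connectivity recovery**: N = 10 dense connectome, one link
  doubled, β = 0.005, empirical FC from three 1500-sample runs,
  optimization at 2000 samples per iteration, 50 iterations.
- **Protocol asymmetry**: the benchmark scene (N = 20), source model at
  the UWS-like ground-truth coupling, target PMS from the control-like
  group, five intensities per protocol, five repetitions per cell.

## Numerical choices and degenerate inputs

- Phases are wrapped to (−π, π]; a global phase shift leaves all coherence
  quantities unchanged (tested).
- `leading_eigenvector` rejects asymmetry beyond 1e-9 and non-finite
  entries; nearest-centroid ties go to the lowest index; empty groups,
  all-zero nodes (undefined phase), flat in-band spectra, bands violating
  the Nyquist limit, and dt not dividing TR all raise explicit errors.
- K-means with k greater than the number of distinct rows is rejected;
  restarts and seeding make the full k sweep deterministic.
- The per-node frequency estimator uses the periodogram of the filtered
  signal (resolution 1/(T·TR)) and is amplitude-invariant.

## Known limitations

- The Hopf observable is the raw oscillator coordinate; no
  Balloon–Windkessel hemodynamics, conduction delays, or heterogeneous
  node parameters beyond a_n.
- EC optimization assumes the noise-free ordering of FC discrepancies is
  informative at the chosen simulation length; at very short lengths the
  Monte-Carlo floor dominates and the gradient stalls.
- Absolute KL values depend on k and on centroid geometry; across
  different clusterings only relative/ordinal structure is comparable.
- The sign convention makes eigenvectors reproducible but can flip noisy
  vectors whose positive/negative split is near the tie boundary;
  clustering results at very small N should be read with that in mind.
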