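"""Coupled supercritical-Hopf (Stuart-Landau) whole-brain model.

Each parcellated brain area *n* is a Stuart-Landau oscillator in Cartesian
coordinates (x_n, y_n) with local bifurcation parameter a_n and intrinsic
angular frequency omega_n.  For a_n < 0 the node sits at a stable fixed point
and produces noise-driven fluctuations; for a_n > 0 it develops a stable
limit cycle of radius sqrt(a_n) oscillating at omega_n / (2*pi).  Nodes are
coupled through a symmetric structural matrix C scaled by a global coupling
G, with difference coupling G * sum_p C_np (x_p - x_n) (and likewise in y),
plus additive Gaussian noise of standard deviation beta on both coordinates.
The x coordinate is the BOLD-like observable.

Integration is Euler-Maruyama at a fixed step dt (default 0.1 s), with an
initial transient discarded and the state recorded once per repetition time
(TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import rng_for

__all__ = ["HopfModelSpec", "SimulationResult", "simulate", "default_spec"]

#: Local bifurcation parameter placing every node in the subcritical,
#: noise-driven regime while preserving resting-state-like structure.
DEFAULT_BIFURCATION = -0.02
#: Standard deviation of the additive Gaussian noise.
DEFAULT_NOISE_SD = 0.01
#: Integration step in seconds.
DEFAULT_DT_SECONDS = 0.1

_OMEGA_BAND_HZ = (0.001, 0.5)  # sanity range for BOLD-scale oscillations


@dataclass(frozen=True)
class HopfModelSpec:
    """Full parameterization of the coupled Hopf network simulator.

    Attributes
    ----------
    n_nodes : int
        Number of brain areas N.
    a : ndarray, shape (N,)
        Local bifurcation parameters (dimensionless).
    omega : ndarray, shape (N,)
        Intrinsic angular frequencies in rad/s (= 2*pi*f_n).
    coupling_matrix : ndarray, shape (N, N)
        Symmetric non-negative structural coupling C with zero diagonal.
    global_coupling : float
        Global coupling weight G scaling all connections.
    noise_sd : float
        Standard deviation beta of the additive Gaussian noise.
    dt_seconds : float
        Euler-Maruyama integration step.
    tr_seconds : float
        Sampling interval of the recorded BOLD-like observable.
    """

    n_nodes: int
    a: np.ndarray
    omega: np.ndarray
    coupling_matrix: np.ndarray
    global_coupling: float
    noise_sd: float
    dt_seconds: float = DEFAULT_DT_SECONDS
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        c = np.asarray(self.coupling_matrix, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "coupling_matrix", c)
        n = int(self.n_nodes)
        if a.shape != (n,) or omega.shape != (n,):
            raise ValueError(
                f"a and omega must have shape ({n},); got {a.shape} and {omega.shape}"
            )
        if c.shape != (n, n):
            raise ValueError(f"coupling_matrix must be {n}x{n}; got {c.shape}")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("coupling_matrix must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("coupling_matrix must have a zero diagonal")
        if np.any(c < 0):
            raise ValueError("coupling_matrix must be non-negative")
        if self.global_coupling < 0:
            raise ValueError("global_coupling must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dt_seconds <= 0 or self.tr_seconds <= 0:
            raise ValueError("dt_seconds and tr_seconds must be positive")
        if self.dt_seconds > self.tr_seconds / 5:
            raise ValueError("dt_seconds must be at most tr_seconds / 5")
        lo, hi = (2 * np.pi * f for f in _OMEGA_BAND_HZ)
        if np.any(omega < lo) or np.any(omega > hi):
            raise ValueError(
                f"omega entries must lie within 2*pi*[{_OMEGA_BAND_HZ[0]}, "
                f"{_OMEGA_BAND_HZ[1]}] rad/s"
            )

    def with_bifurcation(self, value: float, node: int | None = None) -> "HopfModelSpec":
        """Copy of the spec with node's (or every node's) bifurcation set to value."""
        a = self.a.copy()
        if node is None:
            a[:] = value
        else:
            a[node] = value
        return replace(self, a=a)

    def with_coupling_matrix(self, c: np.ndarray) -> "HopfModelSpec":
        return replace(self, coupling_matrix=np.asarray(c, dtype=float))

    def with_global_coupling(self, g: float) -> "HopfModelSpec":
        return replace(self, global_coupling=float(g))


@dataclass(frozen=True)
class SimulationResult:
    """BOLD-like output of one simulation run."""

    x: np.ndarray  # (N, T)
    seed: int
    transient_discarded_steps: int

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def t_points(self) -> int:
        return self.x.shape[1]


def default_spec(
    frequencies,
    connectome: np.ndarray,
    g: float,
    *,
    a: float = DEFAULT_BIFURCATION,
    noise_sd: float = DEFAULT_NOISE_SD,
    dt_seconds: float = DEFAULT_DT_SECONDS,
    tr_seconds: float = 2.0,
) -> HopfModelSpec:
    """Build a HopfModelSpec with the standard working-point parameters.

    Parameters
    ----------
    frequencies : FrequencyVector or array-like of float
        Per-node oscillation frequencies in Hz (``omega = 2*pi*f``).
    connectome : ndarray (N, N)
        Symmetric structural coupling matrix C.
    g : float
        Global coupling weight G.
    """
    f_hz = np.asarray(getattr(frequencies, "f_hz", frequencies), dtype=float)
    c = np.asarray(connectome, dtype=float)
    n = f_hz.size
    if c.shape != (n, n):
        raise ValueError(
            f"connectome shape {c.shape} does not match {n} frequencies"
        )
    return HopfModelSpec(
        n_nodes=n,
        a=np.full(n, float(a)),
        omega=2 * np.pi * f_hz,
        coupling_matrix=c,
        global_coupling=float(g),
        noise_sd=float(noise_sd),
        dt_seconds=float(dt_seconds),
        tr_seconds=float(tr_seconds),
    )


def _steps_per_tr(spec: HopfModelSpec) -> int:
    ratio = spec.tr_seconds / spec.dt_seconds
    steps = round(ratio)
    if abs(ratio - steps) > 1e-9 * ratio or steps < 1:
        raise ValueError(
            f"dt_seconds ({spec.dt_seconds}) must divide tr_seconds "
            f"({spec.tr_seconds}) to within tolerance"
        )
    return int(steps)


def simulate(
    spec: HopfModelSpec,
    t_points: int,
    seed: int,
    *,
    transient_trs: float = 100.0,
) -> SimulationResult:
    """Integrate the coupled Hopf network and record x once per TR.

    Euler-Maruyama with independent Gaussian increments of standard
    deviation ``noise_sd * sqrt(dt)`` on both coordinates of every node.
    Initial conditions are uniform in [-0.1, 0.1]^2 per node; a transient of
    ``transient_trs`` repetition times is integrated and discarded before
    the first recorded sample.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite (reports step and node).
    """
    if t_points < 2:
        raise ValueError("t_points must be at least 2")
    n = spec.n_nodes
    spt = _steps_per_tr(spec)
    n_transient = int(round(transient_trs * spt))
    last_step = n_transient + (t_points - 1) * spt

    rng = rng_for(seed)
    x = rng.uniform(-0.1, 0.1, size=n)
    y = rng.uniform(-0.1, 0.1, size=n)

    dt = spec.dt_seconds
    a = spec.a
    omega = spec.omega
    gc = spec.global_coupling * spec.coupling_matrix
    row_sum = gc.sum(axis=1)
    sq = spec.noise_sd * np.sqrt(dt)
    noisy = sq > 0

    out = np.empty((n, t_points))
    rec = 0
    chunk = 4096
    noise = None
    noise_pos = chunk  # force initial refill
    for step in range(last_step + 1):
        if step >= n_transient and (step - n_transient) % spt == 0:
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
                bad = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
                raise FloatingPointError(
                    f"non-finite state at integration step {step}, node {bad}"
                )
            out[:, rec] = x
            rec += 1
            if rec == t_points:
                break
        r2 = x * x + y * y
        shrink = a - r2
        dx = shrink * x - omega * y + (gc @ x - row_sum * x)
        dy = shrink * y + omega * x + (gc @ y - row_sum * y)
        if noisy:
            if noise_pos >= chunk:
                noise = rng.standard_normal((chunk, 2, n))
                noise_pos = 0
            nx, ny = noise[noise_pos]
            noise_pos += 1
            x = x + dt * dx + sq * nx
            y = y + dt * dy + sq * ny
        else:
            x = x + dt * dx
            y = y + dt * dy
    return SimulationResult(x=out, seed=int(seed), transient_discarded_steps=n_transient)
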