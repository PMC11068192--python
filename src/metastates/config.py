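"""Run configuration for the end-to-end pipeline.

The configuration is structured text (YAML) with explicit units in key
names.  Unknown keys are errors, not warnings; all downstream constraints
are checked at load time with the offending key path in the message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_TOP_KEYS = {
    "n_nodes", "n_subjects_per_group", "t_points", "tr_seconds", "seed",
    "band_hz", "k", "kmeans_restarts", "n_perm",
    "g_grid", "fit_runs", "fit_t_points",
    "source_group", "target_group", "reference_group",
    "ec", "perturbation",
}
_EC_KEYS = {"epsilon", "tol", "max_iter", "t_points"}
_PERT_KEYS = {"protocol", "n_reps", "n_intensities", "t_points"}


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"config key {key!r}: {msg}")


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for :func:`metastates.pipeline.run_full_pipeline`."""

    n_nodes: int = 20
    n_subjects_per_group: int = 4
    t_points: int = 295
    tr_seconds: float = 2.0
    seed: int = 0
    band_hz: tuple[float, float] = (0.04, 0.07)
    k: int = 3
    kmeans_restarts: int = 20
    n_perm: int = 1000
    g_grid: tuple[float, float, float] = (0.0, 0.2, 0.01)  # min, max, step
    fit_runs: int = 5
    fit_t_points: int = 295
    source_group: str = "uws_like"
    target_group: str = "control"
    reference_group: str = "control"
    ec: dict = field(default_factory=lambda: {
        "epsilon": 0.01, "tol": 0.001, "max_iter": 20, "t_points": 295,
    })
    perturbation: dict = field(default_factory=lambda: {
        "protocol": "synchronization", "n_reps": 10, "n_intensities": 21,
        "t_points": 295,
    })

    def __post_init__(self) -> None:
        _require(self.n_nodes >= 10, "n_nodes", "must be at least 10")
        _require(self.n_subjects_per_group >= 2, "n_subjects_per_group",
                 "must be at least 2")
        _require(self.t_points >= 20, "t_points", "must be at least 20")
        _require(self.tr_seconds > 0, "tr_seconds", "must be positive")
        band = tuple(float(b) for b in self.band_hz)
        object.__setattr__(self, "band_hz", band)
        _require(len(band) == 2 and 0 < band[0] < band[1], "band_hz",
                 "must be (low, high) with 0 < low < high")
        _require(band[1] < 1 / (2 * self.tr_seconds), "band_hz",
                 f"upper edge must stay below Nyquist {1 / (2 * self.tr_seconds)} Hz")
        _require(self.k >= 2, "k", "must be at least 2")
        _require(self.kmeans_restarts >= 1, "kmeans_restarts", "must be at least 1")
        _require(self.n_perm >= 1, "n_perm", "must be at least 1")
        grid = tuple(float(g) for g in self.g_grid)
        object.__setattr__(self, "g_grid", grid)
        _require(len(grid) == 3 and grid[0] <= grid[1] and grid[2] > 0, "g_grid",
                 "must be (min, max, step) with min <= max and step > 0")
        _require(self.fit_runs >= 1, "fit_runs", "must be at least 1")
        _require(self.fit_t_points >= 20, "fit_t_points", "must be at least 20")
        extra = set(self.ec) - _EC_KEYS
        _require(not extra, "ec", f"unknown key(s) {sorted(extra)}")
        ec = {"epsilon": 0.01, "tol": 0.001, "max_iter": 20, "t_points": 295}
        ec.update(self.ec)
        object.__setattr__(self, "ec", ec)
        _require(ec["epsilon"] > 0, "ec.epsilon", "must be positive")
        _require(ec["tol"] > 0, "ec.tol", "must be positive")
        _require(int(ec["max_iter"]) >= 1, "ec.max_iter", "must be at least 1")
        extra = set(self.perturbation) - _PERT_KEYS
        _require(not extra, "perturbation", f"unknown key(s) {sorted(extra)}")
        pert = {"protocol": "synchronization", "n_reps": 10,
                "n_intensities": 21, "t_points": 295}
        pert.update(self.perturbation)
        object.__setattr__(self, "perturbation", pert)
        _require(pert["protocol"] in ("synchronization", "noise"),
                 "perturbation.protocol",
                 "must be 'synchronization' or 'noise'")
        _require(int(pert["n_reps"]) >= 1, "perturbation.n_reps",
                 "must be at least 1")
        _require(int(pert["n_intensities"]) >= 2, "perturbation.n_intensities",
                 "must be at least 2")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["g_grid"] = list(self.g_grid)
        return d
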