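"""Run configuration.

One flat record of every tunable the pipeline exposes, serializable to and
from YAML byte-identically.  Defaults are documented in the README table
and mirrored here; see docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """All pipeline tunables.

    Attributes
    ----------
    upsample_factor : integer upsampling factor H (native -> fine grid).
    eta : high-confidence threshold on the upsampled probability map.
    alpha : weight of the regional (probability) force in the surface flow.
    beta : weight of the mean-curvature smoothing force.
    log_sigma_mm : scale of the Laplacian-of-Gaussian edge detector, in mm
        at the fine grid.
    sa_t0, sa_cooling, sa_iters_per_temp, sa_t_min, sa_restarts :
        simulated-annealing schedule for the sinusoid fit (costs are
        normalized by silhouette variance, so sa_t0 is dimensionless).
    n_points : number of interior points drawn per hippocampus.
    bin_width_mm : silhouette bin width along the long axis.
    trim_fraction : fraction of the long-axis range trimmed at each end
        before silhouette extraction.
    seed : master seed for every stochastic operation.
    """

    upsample_factor: int = 5
    eta: float = 0.5
    alpha: float = 1.0
    beta: float = 0.2
    log_sigma_mm: float = 0.5
    sa_t0: float = 1.0
    sa_cooling: float = 0.95
    sa_iters_per_temp: int = 50
    sa_t_min: float = 1e-4
    sa_restarts: int = 4
    n_points: int = 20000
    bin_width_mm: float = 0.2
    trim_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if int(self.upsample_factor) != self.upsample_factor or self.upsample_factor < 1:
            raise ParameterError("upsample_factor must be a positive integer")
        self.upsample_factor = int(self.upsample_factor)
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError("eta must lie in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be non-negative")
        if not self.log_sigma_mm > 0:
            raise ParameterError("log_sigma_mm must be positive")
        if not self.sa_t0 > 0 or not 0 < self.sa_cooling < 1:
            raise ParameterError("sa_t0 must be > 0 and sa_cooling in (0, 1)")
        if self.sa_iters_per_temp < 1 or self.sa_restarts < 1:
            raise ParameterError("sa_iters_per_temp and sa_restarts must be >= 1")
        if not self.sa_t_min > 0:
            raise ParameterError("sa_t_min must be positive")
        if self.n_points < 1:
            raise ParameterError("n_points must be a positive integer")
        if not self.bin_width_mm > 0:
            raise ParameterError("bin_width_mm must be positive")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ParameterError("trim_fraction must lie in [0, 0.5)")
        self.seed = int(self.seed)

    @property
    def sa_schedule(self) -> tuple:
        """(initial temperature, cooling factor, iterations per temperature,
        restarts)."""
        return (self.sa_t0, self.sa_cooling, self.sa_iters_per_temp,
                self.sa_restarts)

    # -- serialization ------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True,
                              default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path=None) -> "RunConfig":
        """Load a config file, or the documented defaults when path is None."""
        if path is None:
            return cls()
        return cls.from_yaml(Path(path).read_text())
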