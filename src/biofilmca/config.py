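"""Simulation configuration.

All model parameters are dimensionless except the lattice size ``L`` (sites;
one site represents 1 μm² of substratum, so an L=60 lattice mimics a
60 μm × 60 μm microscopy field of view).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

from .errors import InvalidParameterError

__all__ = ["SimulationConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one colonization run.

    Parameters
    ----------
    L
        Lateral lattice length in sites (square lattice, L ≥ 2).
    sigma
        Cell adhesiveness in [0, 1]. ``sigma=1`` mimics a constitutive
        matrix (EPS) producer: cells are never displaced by shoving and
        never detached by flow. ``sigma=0`` mimics a non-producer.
    rho0
        Founder density as a fraction of lattice sites in [0, 1].
    f
        Flow intensity in [0, 1]. Sets both the detachment pressure
        (p_d = f(1−σ) for cells with an empty upstream neighbor) and the
        maximum downstream relocation distance, floor(f·L).
    p_b
        Per-step birth-attempt probability in (0, 1]. The final pattern is
        insensitive to the birth rate itself; only the ratio of detachment
        to birth events matters, and that is governed by p_d.
    occupancy_threshold
        Stopping fraction in (0, 1]; runs halt once this fraction of sites
        is occupied (default 0.95).
    seed
        RNG seed for the run (optional; ensembles supply their own).
    max_steps
        Safety bound on the number of update steps.
    """

    L: int = 60
    sigma: float = 1.0
    rho0: float = 0.01
    f: float = 1.0
    p_b: float = 1.0
    occupancy_threshold: float = 0.95
    seed: int | None = None
    max_steps: int = 10_000_000

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int,)) or self.L < 2:
            raise InvalidParameterError(f"L must be an integer >= 2, got {self.L!r}")
        for name in ("sigma", "rho0", "f"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v!r}")
        if not (0.0 < self.p_b <= 1.0):
            raise InvalidParameterError(f"p_b must be in (0, 1], got {self.p_b!r}")
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise InvalidParameterError(
                f"occupancy_threshold must be in (0, 1], got {self.occupancy_threshold!r}"
            )
        if self.max_steps < 1:
            raise InvalidParameterError("max_steps must be positive")

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def p_s(self) -> float:
        """Shove-displacement probability (1−σ)/2, in [0, 0.5]."""
        return (1.0 - self.sigma) / 2.0

    @property
    def p_d(self) -> float:
        """Bare detachment probability f(1−σ); zeroed per-cell by drafting."""
        return self.f * (1.0 - self.sigma)

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    @property
    def n_founders(self) -> int:
        """Founder count: rho0·L² rounded half-up."""
        return int(math.floor(self.rho0 * self.n_sites + 0.5))

    @property
    def max_dx(self) -> int:
        """Maximum downstream relocation distance, floor(f·L).

        A small epsilon guards against binary-fraction noise in f·L
        (e.g. 0.1·60 evaluating just above 6).
        """
        return int(math.floor(self.f * self.L + 1e-9))

    @property
    def threshold_count(self) -> int:
        """Smallest occupied count satisfying the stopping fraction."""
        return int(math.ceil(self.occupancy_threshold * self.n_sites - 1e-9))

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
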