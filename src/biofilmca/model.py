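"""The stochastic cellular automaton of surface colonization.

Two strains (blue/red), identical except for their color label, compete for
space on a periodic square lattice under laminar flow. Each update step
performs one birth attempt followed by one detachment attempt, each on an
independently and uniformly chosen occupied cell:

* **Birth.** With probability ``p_b`` a random occupied cell divides. The
  newborn (same color as its parent) takes a uniformly chosen empty site of
  the parent's Moore neighborhood. If the neighborhood is full, the newborn
  tries to shove a uniformly chosen resident neighbor: with probability
  ``p_s = (1−σ)/2`` the resident is displaced and the newborn takes its
  site; otherwise the newborn loses. The losing cell moves to a uniformly
  chosen empty Moore neighbor of the resident's original site, or is
  removed with the outflow if that neighborhood is also full. Shove
  cascades are truncated: at most one shove per birth.

* **Detachment.** A random occupied cell is tested. Cells are protected by
  drafting: if the directly upstream site ((x−1) mod L, y) is occupied the
  cell cannot detach. Otherwise it detaches with probability
  ``p_d = f(1−σ)`` and is relocated downstream: Δx uniform on
  {0, …, floor(f·L)}, Δy uniform on {−Δx, …, Δx}, landing site evaluated
  with periodic wrap after the origin is vacated. If the landing site is
  occupied the cell is lost with the outflow.

A run is driven to confluence (95% occupancy by default) by
:func:`run_to_confluence`. This module is the readable reference engine;
ensembles use the numba kernel in :mod:`biofilmca._kernel`, which
implements the identical rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .config import SimulationConfig
from .errors import InvalidParameterError, NoPopulationError
from .lattice import BLUE, EMPTY, RED, Lattice

__all__ = [
    "shove_probability",
    "detachment_probability",
    "initialize_lattice",
    "attempt_birth",
    "sample_relocation",
    "attempt_detachment",
    "step",
    "run_to_confluence",
    "BirthOutcome",
    "DetachmentOutcome",
    "RelocationDraw",
    "RunRecord",
    "Termination",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# analytic probabilities
# ----------------------------------------------------------------------
def shove_probability(sigma: float) -> float:
    """Probability p_s = (1−σ)/2 that a resident loses a shoving contest.

    At σ=0 resident and newborn are equally likely to be shoved (p_s = 0.5);
    at σ=1 residents are never displaced.
    """
    if not (0.0 <= sigma <= 1.0):
        raise InvalidParameterError(f"sigma must be in [0, 1], got {sigma!r}")
    return (1.0 - sigma) / 2.0


def detachment_probability(sigma: float, f: float, upstream_empty: bool = True) -> float:
    """Probability p_d = f(1−σ) that an exposed cell detaches.

    Drafting: a cell whose directly upstream neighbor is occupied is
    protected and has detachment probability 0.
    """
    if not (0.0 <= sigma <= 1.0):
        raise InvalidParameterError(f"sigma must be in [0, 1], got {sigma!r}")
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError(f"f must be in [0, 1], got {f!r}")
    if not upstream_empty:
        return 0.0
    return f * (1.0 - sigma)


# ----------------------------------------------------------------------
# outcome records
# ----------------------------------------------------------------------
class Termination(Enum):
    THRESHOLD = "threshold"
    MAX_STEPS = "max_steps"
    EXTINCT = "extinct"


class RelocationOutcome(Enum):
    LANDED = "landed"
    REMOVED = "removed"


@dataclass
class RelocationDraw:
    """One flow-relocation draw for a detached cell."""

    dx: int
    dy: int
    landing: tuple[int, int]
    outcome: RelocationOutcome


@dataclass
class BirthOutcome:
    """Telemetry of one birth attempt (the lattice is updated in place)."""

    divided: bool = False
    shoved: bool = False
    resident_site: tuple[int, int] | None = None
    resident_displaced: bool = False
    newborn_site: tuple[int, int] | None = None
    loser_removed: bool = False
    occupancy_change: int = 0


@dataclass
class DetachmentOutcome:
    """Telemetry of one detachment attempt."""

    detached: bool = False
    origin: tuple[int, int] | None = None
    draw: RelocationDraw | None = None
    occupancy_change: int = 0


@dataclass
class RunRecord:
    """Provenance of one run to confluence."""

    steps: int = 0
    final_fraction: float = 0.0
    births: int = 0
    shove_removals: int = 0
    detachments: int = 0
    relocation_removals: int = 0
    terminated_by: Termination = Termination.THRESHOLD
    config: SimulationConfig | None = None
    engine: str = "python"

    @property
    def extinct(self) -> bool:
        return self.terminated_by is Termination.EXTINCT

    def to_dict(self) -> dict:
        d = {
            "steps": self.steps,
            "final_fraction": self.final_fraction,
            "births": self.births,
            "shove_removals": self.shove_removals,
            "detachments": self.detachments,
            "relocation_removals": self.relocation_removals,
            "terminated_by": self.terminated_by.value,
            "engine": self.engine,
        }
        if self.config is not None:
            d["config"] = self.config.to_dict()
        return d


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------
def initialize_lattice(config: SimulationConfig, rng: np.random.Generator) -> Lattice:
    """Seed founders uniformly at random, each blue or red with probability ½.

    Exactly ``round(rho0·L²)`` distinct sites are occupied (chosen without
    replacement), emulating a 1:1 blue:red inoculation mixture on average.
    """
    n = config.n_founders
    lat = Lattice.empty(config.L)
    if n == 0:
        return lat
    flat = rng.choice(config.n_sites, size=n, replace=False)
    colors = rng.integers(BLUE, RED + 1, size=n)
    ys, xs = np.unravel_index(flat, (config.L, config.L))
    lat.grid[ys, xs] = colors
    return lat


# ----------------------------------------------------------------------
# single events
# ----------------------------------------------------------------------
def _pick_occupied(lattice: Lattice, rng: np.random.Generator) -> tuple[int, int]:
    sites = lattice.occupied_sites()
    if len(sites) == 0:
        raise NoPopulationError("lattice has no occupied sites")
    x, y = sites[rng.integers(len(sites))]
    return int(x), int(y)


def attempt_birth(
    lattice: Lattice, config: SimulationConfig, rng: np.random.Generator
) -> BirthOutcome:
    """One birth attempt; updates the lattice in place and returns telemetry."""
    out = BirthOutcome()
    if lattice.occupied_count == 0:
        raise NoPopulationError("cannot attempt birth on an empty lattice")
    if rng.random() >= config.p_b:
        return out
    out.divided = True
    px, py = _pick_occupied(lattice, rng)
    color = lattice.get(px, py)

    empties = lattice.empty_moore_neighbors(px, py)
    if empties:
        qx, qy = empties[rng.integers(len(empties))]
        lattice.set(qx, qy, color)
        out.newborn_site = (qx, qy)
        out.occupancy_change = 1
        return out

    # Shove: neighborhood full, pick a resident target uniformly.
    out.shoved = True
    neighbors = lattice.moore_neighbors(px, py)
    rx, ry = neighbors[rng.integers(8)]
    out.resident_site = (rx, ry)
    resident_color = lattice.get(rx, ry)
    dest = lattice.empty_moore_neighbors(rx, ry)
    resident_loses = rng.random() < config.p_s
    out.resident_displaced = resident_loses
    if resident_loses:
        # Newborn takes the resident's site; resident moves or is removed.
        lattice.set(rx, ry, color)
        out.newborn_site = (rx, ry)
        if dest:
            dxy = dest[rng.integers(len(dest))]
            lattice.set(dxy[0], dxy[1], resident_color)
            out.occupancy_change = 1
        else:
            out.loser_removed = True
            out.occupancy_change = 0
    else:
        # Resident holds its ground; newborn lands nearby or is removed.
        if dest:
            dxy = dest[rng.integers(len(dest))]
            lattice.set(dxy[0], dxy[1], color)
            out.newborn_site = dxy
            out.occupancy_change = 1
        else:
            out.loser_removed = True
            out.occupancy_change = 0
    return out


def sample_relocation(
    origin: tuple[int, int],
    f: float,
    lattice: Lattice,
    rng: np.random.Generator,
    *,
    vacate: bool = True,
) -> RelocationDraw:
    """Draw a flow relocation for the cell at ``origin`` and apply it.

    Δx ~ U{0, …, floor(f·L)}, Δy ~ U{−Δx, …, Δx}; the landing site is
    evaluated with periodic wrap after the origin is vacated, so a Δx=Δy=0
    draw lands the cell back on its own site. An occupied landing site
    removes the cell from the system (loss with the outflow).
    """
    x, y = origin
    color = lattice.get(x, y)
    if color == EMPTY:
        raise InvalidParameterError(f"relocation origin {origin} is empty")
    max_dx = int(np.floor(f * lattice.width + 1e-9))
    dx = int(rng.integers(0, max_dx + 1))
    dy = int(rng.integers(-dx, dx + 1))
    if vacate:
        lattice.set(x, y, EMPTY)
    lx, ly = (x + dx) % lattice.width, (y + dy) % lattice.height
    if lattice.get(lx, ly) == EMPTY:
        lattice.set(lx, ly, color)
        return RelocationDraw(dx, dy, (lx, ly), RelocationOutcome.LANDED)
    return RelocationDraw(dx, dy, (lx, ly), RelocationOutcome.REMOVED)


def attempt_detachment(
    lattice: Lattice, config: SimulationConfig, rng: np.random.Generator
) -> DetachmentOutcome:
    """One detachment attempt; updates the lattice in place, returns telemetry."""
    out = DetachmentOutcome()
    if lattice.occupied_count == 0:
        raise NoPopulationError("cannot attempt detachment on an empty lattice")
    x, y = _pick_occupied(lattice, rng)
    # Drafting: an occupied upstream neighbor shields the cell entirely.
    if lattice.get(x - 1, y) != EMPTY:
        return out
    if config.p_d <= 0.0 or rng.random() >= config.p_d:
        return out
    out.detached = True
    out.origin = (x, y)
    draw = sample_relocation((x, y), config.f, lattice, rng)
    out.draw = draw
    out.occupancy_change = -1 if draw.outcome is RelocationOutcome.REMOVED else 0
    return out


def step(
    lattice: Lattice, config: SimulationConfig, rng: np.random.Generator
) -> tuple[BirthOutcome, DetachmentOutcome]:
    """One update step: a birth attempt, then a detachment attempt.

    The two sub-steps act on independently chosen occupied cells. Net
    occupancy change is in {−1, 0, +1}.
    """
    if lattice.occupied_count == 0:
        raise NoPopulationError("cannot step an empty lattice (population extinct)")
    birth = attempt_birth(lattice, config, rng)
    if lattice.occupied_count == 0:
        return birth, DetachmentOutcome()
    det = attempt_detachment(lattice, config, rng)
    return birth, det


# ----------------------------------------------------------------------
# run driver
# ----------------------------------------------------------------------
def run_to_confluence(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    engine: str = "numba",
) -> tuple[Lattice, RunRecord]:
    """Iterate steps until the occupancy threshold (or max_steps) is reached.

    Parameters
    ----------
    config
        Run parameters; ``config.rho0`` must be positive.
    rng
        Optional generator; defaults to ``default_rng(config.seed)``.
    engine
        ``"numba"`` (fast jitted kernel, default) or ``"python"`` (the
        reference implementation in this module). Both engines implement
        identical rules; their random streams differ.
    """
    if config.rho0 <= 0.0 or config.n_founders == 0:
        raise InvalidParameterError("run_to_confluence requires rho0 > 0 (with >= 1 founder)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lattice = initialize_lattice(config, rng)
    record = RunRecord(config=config, engine=engine)

    if lattice.occupied_count >= config.threshold_count:
        record.final_fraction = lattice.occupied_fraction
        record.terminated_by = Termination.THRESHOLD
        _log_run(record)
        return lattice, record

    if engine == "numba":
        from ._kernel import run_kernel

        kernel_seed = int(rng.integers(0, 2**31 - 1))
        steps, births, shove_rem, det, reloc_rem, status = run_kernel(
            lattice.grid,
            config.p_b,
            config.p_s,
            config.p_d,
            config.max_dx,
            config.threshold_count,
            config.max_steps,
            kernel_seed,
        )
        record.steps = int(steps)
        record.births = int(births)
        record.shove_removals = int(shove_rem)
        record.detachments = int(det)
        record.relocation_removals = int(reloc_rem)
        record.terminated_by = (
            Termination.THRESHOLD,
            Termination.MAX_STEPS,
            Termination.EXTINCT,
        )[int(status)]
    elif engine == "python":
        while record.steps < config.max_steps:
            record.steps += 1
            birth, det = step(lattice, config, rng)
            if birth.divided:
                record.births += 1
            if birth.loser_removed:
                record.shove_removals += 1
            if det.detached:
                record.detachments += 1
                if det.occupancy_change < 0:
                    record.relocation_removals += 1
            n = lattice.occupied_count
            if n == 0:
                record.terminated_by = Termination.EXTINCT
                break
            if n >= config.threshold_count:
                record.terminated_by = Termination.THRESHOLD
                break
        else:
            record.terminated_by = Termination.MAX_STEPS
    else:
        raise InvalidParameterError(f"unknown engine {engine!r}")

    record.final_fraction = lattice.occupied_fraction
    _log_run(record)
    return lattice, record


def _log_run(record: RunRecord) -> None:
    if record.extinct:
        logger.warning("run went extinct after %d steps", record.steps)
    else:
        logger.info(
            "run finished: steps=%d occupancy=%.3f births=%d shove_removals=%d "
            "detachments=%d relocation_removals=%d (%s)",
            record.steps,
            record.final_fraction,
            record.births,
            record.shove_removals,
            record.detachments,
            record.relocation_removals,
            record.terminated_by.value,
        )
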