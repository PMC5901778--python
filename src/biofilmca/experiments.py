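"""Ensemble runs and parameter sweeps.

These drivers regenerate the model's structural predictions: how the mean
clonal correlation length ξ depends on founder density ρ0 and adhesiveness
σ across flow intensities f, the Δξ = mean ξ(σ=1) − mean ξ(σ=0) phase
structure, the std(ξ) variability surfaces, and KDE comparisons of ξ
distributions across densities.

Seeding: every replicate draws its generator from a
``numpy.random.SeedSequence`` built from the base seed plus the bit
patterns of (f, ρ0, σ) and the replicate index, so grid points are
statistically independent yet byte-reproducible, and duplicated parameter
values reuse identical streams (a sweep over σ ∈ {1, 1} yields Δξ ≡ 0
exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import InsufficientDataError, InvalidParameterError
from .model import run_to_confluence
from .stats import (
    ColorPattern,
    CorrelationLength,
    DensityEstimate,
    adaptive_kde,
    autocorrelation,
    correlation_length,
    ensemble_summary,
)
from .errors import ZeroVarianceError

__all__ = [
    "SweepSpec",
    "SweepResult",
    "EnsembleResult",
    "run_ensemble",
    "sweep",
    "variability_surface",
    "compare_distributions",
]


# ----------------------------------------------------------------------
def _float_bits(v: float) -> int:
    return int(np.float64(v).view(np.uint64))


def _rep_seedseq(base_seed: int, config: SimulationConfig, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [
            int(base_seed),
            _float_bits(config.f),
            _float_bits(config.rho0),
            _float_bits(config.sigma),
            int(rep),
        ]
    )


@dataclass
class EnsembleResult:
    """ξ samples of one ensemble, with extinction/censoring bookkeeping.

    Behaves like a list of :class:`CorrelationLength` (iteration, len,
    indexing) so it can be fed directly to :func:`ensemble_summary`.
    """

    xis: list[CorrelationLength] = field(default_factory=list)
    n_extinct: int = 0

    @property
    def n_censored(self) -> int:
        return sum(1 for x in self.xis if x.censored)

    def values(self) -> np.ndarray:
        """Non-censored ξ values."""
        return np.asarray([x.xi for x in self.xis if not x.censored])

    def summary(self):
        return ensemble_summary(self.xis, n_extinct=self.n_extinct)

    def __iter__(self):
        return iter(self.xis)

    def __len__(self) -> int:
        return len(self.xis)

    def __getitem__(self, i):
        return self.xis[i]


def run_ensemble(
    config: SimulationConfig,
    n_reps: int,
    base_seed: int = 0,
    engine: str = "numba",
    r_max: int | None = None,
    periodic: bool = False,
) -> EnsembleResult:
    """Run ``n_reps`` independent colonizations and measure ξ of each.

    Extinct runs are flagged and excluded. Final patterns in which a
    single lineage has fixed are perfectly correlated at every separation
    and are recorded as censored at r_max.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    if r_max is None:
        r_max = config.L // 2
    result = EnsembleResult()
    for rep in range(n_reps):
        rng = np.random.default_rng(_rep_seedseq(base_seed, config, rep))
        lattice, record = run_to_confluence(config, rng=rng, engine=engine)
        if record.extinct:
            result.n_extinct += 1
            continue
        pattern = ColorPattern(lattice.grid, unit=1.0, periodic=periodic)
        try:
            profile = autocorrelation(pattern, r_max=r_max)
            xi = correlation_length(profile)
        except (ZeroVarianceError, InvalidParameterError):
            # Single-lineage (or pathologically sparse) final pattern:
            # perfectly correlated at every separation -> censored at r_max.
            xi = CorrelationLength(xi=float(r_max), censored=True)
        result.xis.append(xi)
    return result


# ----------------------------------------------------------------------
@dataclass
class SweepSpec:
    """Grid of (f, ρ0, σ) conditions for an ensemble sweep."""

    f_values: tuple[float, ...]
    rho0_values: tuple[float, ...]
    sigma_values: tuple[float, ...]
    n_reps: int = 200
    L: int = 60
    p_b: float = 1.0
    occupancy_threshold: float = 0.95
    base_seed: int = 0
    engine: str = "numba"
    max_steps: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        for name in ("f_values", "rho0_values", "sigma_values"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) == 0:
                raise InvalidParameterError(f"{name} must be non-empty")

    def config(self, f: float, rho0: float, sigma: float) -> SimulationConfig:
        return SimulationConfig(
            L=self.L,
            sigma=sigma,
            rho0=rho0,
            f=f,
            p_b=self.p_b,
            occupancy_threshold=self.occupancy_threshold,
            max_steps=self.max_steps,
        )


@dataclass
class SweepResult:
    """Per-grid-point ξ summaries and the Δξ adhesion-payoff table."""

    summaries: pd.DataFrame
    delta: pd.DataFrame  # columns: f, rho0, delta_xi (σ_hi minus σ_lo)
    sigma_hi: float
    sigma_lo: float


def _point_ensemble(spec: SweepSpec, f: float, rho0: float, sigma: float) -> EnsembleResult:
    return run_ensemble(
        spec.config(f, rho0, sigma),
        n_reps=spec.n_reps,
        base_seed=spec.base_seed,
        engine=spec.engine,
    )


def sweep(spec: SweepSpec, keep_samples: bool = False) -> SweepResult:
    """Fill the (f, ρ0, σ) grid with ξ ensemble summaries.

    Δξ compares the largest and smallest σ in the grid (the matrix-producer
    versus non-producer contrast when 1 and 0 are both present).
    Deterministic given
    ``spec.base_seed``; per-point failures are recorded as gaps.
    """
    rows = []
    means: dict[tuple[float, float, float], float] = {}
    samples: dict[tuple[float, float, float], EnsembleResult] = {}
    for f in spec.f_values:
        for rho0 in spec.rho0_values:
            for sigma in spec.sigma_values:
                ens = _point_ensemble(spec, f, rho0, sigma)
                if keep_samples:
                    samples[(f, rho0, sigma)] = ens
                try:
                    s = ens.summary()
                except InsufficientDataError:
                    rows.append(
                        dict(f=f, rho0=rho0, sigma=sigma, n=0,
                             n_censored=ens.n_censored, n_extinct=ens.n_extinct,
                             mean_xi=np.nan, std_xi=np.nan, median_xi=np.nan,
                             skew_xi=np.nan)
                    )
                    continue
                means[(f, rho0, sigma)] = s.mean
                rows.append(
                    dict(f=f, rho0=rho0, sigma=sigma, n=s.n,
                         n_censored=s.n_censored, n_extinct=s.n_extinct,
                         mean_xi=s.mean, std_xi=s.std, median_xi=s.median,
                         skew_xi=s.skewness)
                )
    summaries = pd.DataFrame(rows)

    sigma_hi = max(spec.sigma_values)
    sigma_lo = min(spec.sigma_values)
    drows = []
    for f in spec.f_values:
        for rho0 in spec.rho0_values:
            hi = means.get((f, rho0, sigma_hi))
            lo = means.get((f, rho0, sigma_lo))
            if hi is not None and lo is not None:
                drows.append(dict(f=f, rho0=rho0, delta_xi=hi - lo))
    result = SweepResult(
        summaries=summaries,
        delta=pd.DataFrame(drows, columns=["f", "rho0", "delta_xi"]),
        sigma_hi=sigma_hi,
        sigma_lo=sigma_lo,
    )
    if keep_samples:
        result.samples = samples  # type: ignore[attr-defined]
    return result


def bootstrap_ci(
    values: np.ndarray,
    statistic,
    n_boot: int = 500,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``statistic`` over ``values``."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values)
    stats = np.array(
        [statistic(values[rng.integers(0, len(values), len(values))]) for _ in range(n_boot)]
    )
    alpha = (1.0 - ci) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))


def variability_surface(
    spec: SweepSpec, n_boot: int = 200, ci: float = 0.95
) -> pd.DataFrame:
    """std(ξ) over the (f, ρ0, σ) grid with bootstrap confidence intervals.

    std(ξ) is the model's proxy for lineage-segregation variability.
    """
    rows = []
    for f in spec.f_values:
        for rho0 in spec.rho0_values:
            for sigma in spec.sigma_values:
                ens = _point_ensemble(spec, f, rho0, sigma)
                vals = ens.values()
                if len(vals) < 2:
                    rows.append(dict(f=f, rho0=rho0, sigma=sigma, n=len(vals),
                                     std_xi=np.nan, ci_lo=np.nan, ci_hi=np.nan))
                    continue
                lo, hi = bootstrap_ci(
                    vals, lambda v: v.std(ddof=1), n_boot=n_boot, ci=ci,
                    seed=spec.base_seed,
                )
                rows.append(dict(f=f, rho0=rho0, sigma=sigma, n=len(vals),
                                 std_xi=float(vals.std(ddof=1)), ci_lo=lo, ci_hi=hi))
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def overlap_coefficient(a: DensityEstimate, b: DensityEstimate) -> float:
    """∫ min(f, g) for two densities evaluated on the same grid."""
    if not np.array_equal(a.grid, b.grid):
        raise InvalidParameterError("overlap requires densities on a common grid")
    return float(np.trapezoid(np.minimum(a.density, b.density), a.grid))


def compare_distributions(
    xi_samples_by_group: dict, grid: np.ndarray | None = None, grid_points: int = 512
) -> tuple[dict, pd.DataFrame]:
    """Adaptive KDE per group plus pairwise overlap coefficients.

    ``xi_samples_by_group`` maps a label (e.g. a founder density) to its ξ
    samples (≥ 5 each). Returns (label → DensityEstimate, overlap table).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in xi_samples_by_group.items()}
    for k, v in groups.items():
        if len(v) < 5:
            raise InsufficientDataError(f"group {k!r} has fewer than 5 samples")
    if grid is None:
        top = max(float(v.max()) for v in groups.values())
        span = max(float(v.std(ddof=1)) for v in groups.values())
        grid = np.linspace(0.0, top + 5.0 * max(span, 1.0), grid_points)
    kdes = {k: adaptive_kde(v, grid=grid) for k, v in groups.items()}
    labels = list(kdes)
    rows = []
    for i, ka in enumerate(labels):
        for kb in labels[i + 1 :]:
            rows.append(
                dict(group_a=ka, group_b=kb,
                     overlap=overlap_coefficient(kdes[ka], kdes[kb]))
            )
    return kdes, pd.DataFrame(rows, columns=["group_a", "group_b", "overlap"])
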