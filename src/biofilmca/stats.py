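"""Spatial statistics for two-color occupation patterns.

The central quantity is the radially averaged spatial autocorrelation of
the lineage color,

    C(r) = ( <c_i c_j>_r − <c_i>_r <c_j>_r ) / ( <c_i²>_r − <c_i>_r² ),

where the averages run over all ordered pairs of *occupied* sites whose
Euclidean separation falls in the unit-width annulus [r−½, r+½), and the
color variable c takes value 1 (blue) or 2 (red). Empty sites are excluded
from all averages. The denominator is the variance of the pair-endpoint
color distribution in the same annulus, so each C(r) is a genuine Pearson
coefficient: C(0) = 1 by construction and |C(r)| ≤ 1 always. Under
periodic sampling every site enters every annulus equally, and the per-bin
normalization coincides with the global-variance form.

The clonal correlation length ξ is the first zero of C(r) (linear
interpolation between the bracketing annuli); it measures the typical
clonal cluster size. Profiles that never cross zero within r_max are
censored at r_max.

Two implementations are provided: an FFT-based one (cross-correlograms of
the color and occupancy indicators, binned radially; exact, because all
pair sums are integers and are rounded back to integers) and a brute-force
O(N²) pair enumeration that serves as its oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft
from scipy import stats as _sstats

from .errors import InsufficientDataError, InvalidParameterError, ZeroVarianceError

__all__ = [
    "ColorPattern",
    "CorrelationProfile",
    "CorrelationLength",
    "EnsembleSummary",
    "DensityEstimate",
    "autocorrelation",
    "autocorrelation_reference",
    "correlation_length",
    "ensemble_summary",
    "adaptive_kde",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class ColorPattern:
    """A two-color occupation pattern: grid of {0 empty, 1 blue, 2 red}.

    ``unit`` is the physical size of one grid cell (1 μm for simulation
    lattices, 0.065 μm per pixel for microscopy-derived patterns).
    ``periodic`` selects minimal-image pair distances (simulation lattices)
    versus bounded field-of-view pairs (the default, matching finite
    experimental tiles).
    """

    grid: np.ndarray
    unit: float = 1.0
    periodic: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise InvalidParameterError("pattern grid must be 2D")
        if not np.isin(self.grid, (0, 1, 2)).all():
            raise InvalidParameterError("pattern values must be 0, 1 or 2")
        if self.unit <= 0:
            raise InvalidParameterError("unit must be positive")


@dataclass
class CorrelationProfile:
    """Radially binned autocorrelation values with ordered-pair counts."""

    r: np.ndarray          # annulus centers, in elementary units
    C: np.ndarray          # correlation per annulus (nan if undefined)
    pair_counts: np.ndarray
    r_max: float
    unit: float = 1.0


@dataclass(frozen=True)
class CorrelationLength:
    """First zero ξ of C(r); censored when no crossing exists within r_max."""

    xi: float
    censored: bool = False


@dataclass
class EnsembleSummary:
    """Moments of a ξ ensemble; censored/extinct runs are excluded."""

    n: int
    mean: float
    std: float
    median: float
    skewness: float
    n_censored: int = 0
    n_extinct: int = 0
    degenerate_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "std": self.std,
            "median": self.median,
            "skewness": self.skewness,
            "n_censored": self.n_censored,
            "n_extinct": self.n_extinct,
            "degenerate_variance": self.degenerate_variance,
        }


@dataclass
class DensityEstimate:
    """Adaptive KDE of a ξ distribution."""

    grid: np.ndarray
    density: np.ndarray
    pilot_bandwidth: float
    local_bandwidths: np.ndarray = field(repr=False, default=None)

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


# ----------------------------------------------------------------------
# autocorrelation
# ----------------------------------------------------------------------
def _validate_two_colors(grid: np.ndarray) -> None:
    has_blue = bool((grid == 1).any())
    has_red = bool((grid == 2).any())
    if not (has_blue and has_red):
        raise ZeroVarianceError(
            "autocorrelation requires both colors; pattern has "
            f"blue={has_blue}, red={has_red}"
        )


def _default_rmax(grid: np.ndarray) -> int:
    # Half the smaller extent: longer annuli are dominated by few pairs.
    return min(grid.shape) // 2


def _profile_from_sums(n_pairs, s_c, s_cc, s_c2, r_max, unit) -> CorrelationProfile:
    """Assemble C(r) per annulus from integer ordered-pair sums."""
    ks = np.arange(len(n_pairs))
    keep = (n_pairs > 0) & (ks <= r_max)
    ks = ks[keep]
    n = n_pairs[keep]
    m = s_c[keep] / n
    ecc = s_cc[keep] / n
    ec2 = s_c2[keep] / n
    var = ec2 - m * m
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(var > 0, (ecc - m * m) / np.where(var > 0, var, 1.0), np.nan)
    if len(ks) == 0 or ks[0] != 0 or not np.isfinite(C[0]):
        raise ZeroVarianceError("pattern variance is zero; correlation undefined")
    return CorrelationProfile(
        r=ks.astype(float), C=C, pair_counts=n.astype(np.int64), r_max=float(r_max), unit=unit
    )


def autocorrelation(pattern: ColorPattern, r_max: int | None = None) -> CorrelationProfile:
    """Radially averaged color autocorrelation, FFT accelerated.

    Computes, for every displacement vector, the ordered-pair sums
    Σ m_i m_j, Σ c_i m_j, Σ c_i c_j and Σ c_i² m_j via cross-correlograms
    (m is the occupancy indicator), then pools displacements into unit
    annuli by Euclidean length. All sums are integers, so FFT round-off is
    removed exactly by rounding.
    """
    grid = pattern.grid
    _validate_two_colors(grid)
    if r_max is None:
        r_max = _default_rmax(grid)
    if r_max < 1:
        raise InvalidParameterError("r_max must be >= 1")

    H, W = grid.shape
    m = (grid != 0).astype(np.float64)
    c = grid.astype(np.float64)
    c2 = c * c

    if pattern.periodic:
        shape = (H, W)
        dy = np.minimum(np.arange(H), H - np.arange(H))
        dx = np.minimum(np.arange(W), W - np.arange(W))
    else:
        shape = (2 * H - 1, 2 * W - 1)
        iy = np.arange(shape[0])
        ix = np.arange(shape[1])
        dy = np.where(iy < H, iy, iy - shape[0])
        dx = np.where(ix < W, ix, ix - shape[1])

    Fm = _fft.rfftn(m, shape)
    Fc = _fft.rfftn(c, shape)
    Fc2 = _fft.rfftn(c2, shape)

    def corr(Fa, Fb):
        # corr(a, b)[d] = sum_i a_i * b_{i+d}  (circular over `shape`)
        return np.rint(_fft.irfftn(np.conj(Fa) * Fb, shape))

    n_d = corr(Fm, Fm)
    sc_d = corr(Fc, Fm)
    scc_d = corr(Fc, Fc)
    sc2_d = corr(Fc2, Fm)

    dist = np.hypot(np.abs(dy)[:, None], np.abs(dx)[None, :])
    bins = np.rint(dist).astype(np.int64).ravel()
    nbins = bins.max() + 1

    n_pairs = np.bincount(bins, weights=n_d.ravel(), minlength=nbins)
    s_c = np.bincount(bins, weights=sc_d.ravel(), minlength=nbins)
    s_cc = np.bincount(bins, weights=scc_d.ravel(), minlength=nbins)
    s_c2 = np.bincount(bins, weights=sc2_d.ravel(), minlength=nbins)
    return _profile_from_sums(n_pairs, s_c, s_cc, s_c2, r_max, pattern.unit)


def autocorrelation_reference(
    pattern: ColorPattern, r_max: int | None = None
) -> CorrelationProfile:
    """Brute-force O(N²) pair enumeration; the oracle for :func:`autocorrelation`.

    Intended for small patterns (≲ 40×40); identical contract.
    """
    grid = pattern.grid
    _validate_two_colors(grid)
    if r_max is None:
        r_max = _default_rmax(grid)
    if r_max < 1:
        raise InvalidParameterError("r_max must be >= 1")

    H, W = grid.shape
    ys, xs = np.nonzero(grid)
    colors = grid[ys, xs].astype(np.float64)

    ddy = np.abs(ys[:, None] - ys[None, :]).astype(np.float64)
    ddx = np.abs(xs[:, None] - xs[None, :]).astype(np.float64)
    if pattern.periodic:
        ddy = np.minimum(ddy, H - ddy)
        ddx = np.minimum(ddx, W - ddx)
    dist = np.hypot(ddy, ddx)
    bins = np.rint(dist).astype(np.int64)

    nbins = bins.max() + 1
    flat = bins.ravel()
    ci = np.broadcast_to(colors[:, None], bins.shape).ravel()
    cc = (colors[:, None] * colors[None, :]).ravel()

    n_pairs = np.bincount(flat, minlength=nbins).astype(np.float64)
    s_c = np.bincount(flat, weights=ci, minlength=nbins)
    s_cc = np.bincount(flat, weights=cc, minlength=nbins)
    s_c2 = np.bincount(flat, weights=ci * ci, minlength=nbins)
    return _profile_from_sums(n_pairs, s_c, s_cc, s_c2, r_max, pattern.unit)


# ----------------------------------------------------------------------
# correlation length
# ----------------------------------------------------------------------
def correlation_length(profile: CorrelationProfile) -> CorrelationLength:
    """First zero of C(r), linearly interpolated; censored at r_max if none.

    Walks the annuli in order of increasing r and returns the interpolated
    radius at the first sign change from positive to ≤ 0. Undefined (nan)
    annuli are skipped.
    """
    r = profile.r
    C = profile.C
    if len(r) < 2:
        raise InvalidParameterError("profile needs at least 2 bins")
    prev_r, prev_c = float(r[0]), float(C[0])
    for k in range(1, len(r)):
        ck = float(C[k])
        if not np.isfinite(ck):
            continue
        if ck <= 0.0:
            xi = prev_r + prev_c * (float(r[k]) - prev_r) / (prev_c - ck)
            return CorrelationLength(xi=float(xi), censored=False)
        prev_r, prev_c = float(r[k]), ck
    return CorrelationLength(xi=float(profile.r_max), censored=True)


# ----------------------------------------------------------------------
# ensemble summaries
# ----------------------------------------------------------------------
def ensemble_summary(
    xis: list[CorrelationLength | float], n_extinct: int = 0
) -> EnsembleSummary:
    """Mean, sample std, median and adjusted Fisher–Pearson skewness of ξ.

    Censored samples (and extinct runs, passed via ``n_extinct``) are
    counted separately and excluded from the moments.
    """
    if len(xis) == 0 and n_extinct == 0:
        raise InsufficientDataError("no samples")
    vals = []
    n_censored = 0
    for x in xis:
        if isinstance(x, CorrelationLength):
            if x.censored:
                n_censored += 1
            else:
                vals.append(x.xi)
        else:
            vals.append(float(x))
    if not vals:
        raise InsufficientDataError("no non-censored samples")
    v = np.asarray(vals, dtype=float)
    n = len(v)
    std = float(v.std(ddof=1)) if n > 1 else 0.0
    degenerate = std == 0.0
    if n >= 3 and not degenerate:
        skew = float(_sstats.skew(v, bias=False))
    else:
        skew = 0.0
    return EnsembleSummary(
        n=n,
        mean=float(v.mean()),
        std=std,
        median=float(np.median(v)),
        skewness=skew,
        n_censored=n_censored,
        n_extinct=n_extinct,
        degenerate_variance=degenerate,
    )


# ----------------------------------------------------------------------
# adaptive KDE
# ----------------------------------------------------------------------
_SQRT2PI = float(np.sqrt(2.0 * np.pi))


def _gauss_sum(points: np.ndarray, centers: np.ndarray, h) -> np.ndarray:
    """Mean over kernels centered at ``centers`` (bandwidths h, scalar or
    per-center), evaluated at ``points``; chunked to bound memory."""
    h = np.broadcast_to(np.asarray(h, dtype=float), centers.shape)
    out = np.zeros(points.shape, dtype=float)
    chunk = max(1, int(2**22 // max(len(centers), 1)))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk, None]
        z = (p - centers[None, :]) / h[None, :]
        out[lo : lo + chunk] = np.sum(np.exp(-0.5 * z * z) / (h[None, :] * _SQRT2PI), axis=1)
    return out / len(centers)


def adaptive_kde(
    samples,
    grid: np.ndarray | None = None,
    lower_bound: float | None = 0.0,
    grid_points: int = 512,
) -> DensityEstimate:
    """Abramson variable-bandwidth Gaussian KDE.

    A pilot Gaussian KDE with Silverman bandwidth h₀ is evaluated at the
    sample points; each sample then receives the local bandwidth
    h_i = h₀ · (f_pilot(x_i)/g)^(−1/2) with g the geometric mean of the
    pilot densities. Sparse regions (fat tails) get wider kernels, dense
    regions narrower ones. For positive-valued data (ξ > 0) boundary bias
    at 0 is corrected by reflection; pass ``lower_bound=None`` for
    unbounded data.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise InsufficientDataError("adaptive_kde requires >= 5 scalar samples")
    if lower_bound is not None and np.any(x <= lower_bound):
        raise InsufficientDataError(
            f"samples must exceed the lower bound {lower_bound}"
        )
    n = len(x)
    sd = float(x.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise InsufficientDataError("samples have zero spread")
    h0 = 0.9 * spread * n ** (-0.2)

    def fixed_kde(points: np.ndarray) -> np.ndarray:
        dens = _gauss_sum(points, x, h0)
        if lower_bound is not None:
            dens = dens + _gauss_sum(points, 2.0 * lower_bound - x, h0)
        return dens

    pilot = fixed_kde(x)
    g = float(np.exp(np.mean(np.log(pilot))))
    local_h = h0 * np.sqrt(g / pilot)

    if grid is None:
        hi = float(local_h.max())
        top = float(x.max()) + 5.0 * max(h0, hi)
        lo = lower_bound if lower_bound is not None else float(x.min()) - 5.0 * max(h0, hi)
        grid = np.linspace(lo, top, grid_points)
    grid = np.asarray(grid, dtype=float)

    dens = _gauss_sum(grid, x, local_h)
    if lower_bound is not None:
        dens = dens + _gauss_sum(grid, 2.0 * lower_bound - x, local_h)
        dens = np.where(grid < lower_bound, 0.0, dens)
    return DensityEstimate(
        grid=grid, density=dens, pilot_bandwidth=h0, local_bandwidths=local_h
    )
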