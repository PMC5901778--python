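"""Unit tests of the cellular-automaton rules (reference Python engine)."""

import numpy as np
import pytest
from scipy import stats as sstats

import biofilmca as bca
from biofilmca import (
    BLUE,
    EMPTY,
    RED,
    InvalidParameterError,
    Lattice,
    NoPopulationError,
    SimulationConfig,
    attempt_birth,
    attempt_detachment,
    detachment_probability,
    initialize_lattice,
    run_to_confluence,
    sample_relocation,
    shove_probability,
    step,
)
from biofilmca.model import RelocationOutcome, Termination

from conftest import full_lattice


# ----------------------------------------------------------------------
# analytic probabilities
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "sigma,expected",
    [(0.0, 0.5), (1.0, 0.0), (0.5, 0.25), (0.2, 0.4)],
)
def test_shove_probability_values(sigma, expected):
    assert shove_probability(sigma) == pytest.approx(expected)


@pytest.mark.parametrize(
    "sigma,f,upstream_empty,expected",
    [
        (1.0, 1.0, True, 0.0),   # highly-adhesive cells cannot be detached
        (0.0, 0.5, True, 0.5),
        (0.0, 1.0, False, 0.0),  # drafting: occupied upstream site shields
        (0.0, 0.0, True, 0.0),   # no flow, no detachment
        (0.5, 0.8, True, 0.4),
    ],
)
def test_detachment_probability_values(sigma, f, upstream_empty, expected):
    assert detachment_probability(sigma, f, upstream_empty) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
def test_probability_domain_errors(bad):
    with pytest.raises(InvalidParameterError):
        shove_probability(bad)
    with pytest.raises(InvalidParameterError):
        detachment_probability(bad, 0.5)
    with pytest.raises(InvalidParameterError):
        detachment_probability(0.5, bad)


def test_probability_bounds_over_domain():
    for sigma in np.linspace(0, 1, 21):
        assert 0.0 <= shove_probability(sigma) <= 0.5
        for f in np.linspace(0, 1, 21):
            assert 0.0 <= detachment_probability(sigma, f) <= 1.0


def test_config_validation():
    with pytest.raises(InvalidParameterError):
        SimulationConfig(L=1)
    with pytest.raises(InvalidParameterError):
        SimulationConfig(sigma=1.5)
    with pytest.raises(InvalidParameterError):
        SimulationConfig(p_b=0.0)
    with pytest.raises(InvalidParameterError):
        SimulationConfig(occupancy_threshold=0.0)


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "rho0,expected",
    [(0.0, 0), (0.01, 36), (1.0, 3600)],  # round(rho0 * 3600), half-up
)
def test_initialize_founder_counts(rho0, expected, rng):
    lat = initialize_lattice(SimulationConfig(L=60, rho0=rho0), rng)
    assert lat.occupied_count == expected


def test_initialize_distinct_sites_and_colors(rng):
    cfg = SimulationConfig(L=30, rho0=0.5)
    lat = initialize_lattice(cfg, rng)
    assert lat.occupied_count == cfg.n_founders
    blue, red = lat.color_counts()
    assert blue + red == cfg.n_founders
    assert blue > 0 and red > 0


def test_initialize_color_balance():
    """Founders are blue with probability 1/2: mean blue fraction over many
    initializations sits within 3 binomial SEs of 0.5."""
    cfg = SimulationConfig(L=10, rho0=0.36)  # 36 founders
    total_blue = 0
    n_inits = 2000
    rng = np.random.default_rng(99)
    for _ in range(n_inits):
        lat = initialize_lattice(cfg, rng)
        total_blue += lat.color_counts()[0]
    n_cells = n_inits * cfg.n_founders
    frac = total_blue / n_cells
    se = 0.5 / np.sqrt(n_cells)
    assert abs(frac - 0.5) < 3 * se


# ----------------------------------------------------------------------
# birth and shoving
# ----------------------------------------------------------------------
def test_birth_with_empty_neighbor_adds_parent_color(rng):
    lat = Lattice.empty(5)
    lat.set(2, 2, RED)
    cfg = SimulationConfig(L=5, sigma=0.5, rho0=0.1, p_b=1.0)
    out = attempt_birth(lat, cfg, rng)
    assert out.divided and not out.shoved
    assert out.occupancy_change == 1
    assert lat.occupied_count == 2
    assert lat.get(*out.newborn_site) == RED


def test_birth_on_empty_lattice_raises(rng):
    with pytest.raises(NoPopulationError):
        attempt_birth(Lattice.empty(5), SimulationConfig(L=5), rng)


def test_shove_sigma1_full_lattice_is_noop(rng):
    """At sigma=1 the resident never loses; on a fully occupied lattice the
    newborn has nowhere to land and is removed: lattice unchanged."""
    lat = full_lattice(4, BLUE)
    cfg = SimulationConfig(L=4, sigma=1.0, rho0=1.0)
    before = lat.grid.copy()
    for _ in range(50):
        out = attempt_birth(lat, cfg, rng)
        assert out.shoved and out.loser_removed and not out.resident_displaced
        assert out.occupancy_change == 0
    assert np.array_equal(lat.grid, before)


def test_shove_sigma0_resident_loses_half_the_time():
    """On a full lattice at sigma=0 the resident is displaced in ~50% of
    shoving contests (Monte Carlo against p_s = 0.5)."""
    cfg = SimulationConfig(L=4, sigma=0.0, rho0=1.0)
    rng = np.random.default_rng(0)
    n, displaced = 20_000, 0
    for _ in range(n):
        lat = full_lattice(4, BLUE)
        out = attempt_birth(lat, cfg, rng)
        assert out.shoved
        displaced += out.resident_displaced
    lo, hi = sstats.binom.interval(0.9999, n, 0.5)
    assert lo <= displaced <= hi


def test_shove_loser_lands_in_resident_neighborhood(rng):
    """When the resident neighborhood has an empty site, the loser ends up
    there and occupancy grows by one."""
    # Parent at center fully surrounded; one empty site two cells away.
    lat = full_lattice(5, BLUE)
    lat.set(0, 0, EMPTY)
    cfg = SimulationConfig(L=5, sigma=0.0, rho0=1.0)
    grew = 0
    shoves = 0
    for _ in range(200):
        work = lat.copy()
        out = attempt_birth(work, cfg, rng)
        shoves += out.shoved
        grew += out.occupancy_change
        assert out.occupancy_change in (0, 1)
    assert shoves > 0  # interior parents are fully surrounded
    assert grew > 0  # (0,0) is reachable from residents adjacent to it


# ----------------------------------------------------------------------
# relocation
# ----------------------------------------------------------------------
def test_relocation_f0_self_lands(rng):
    lat = Lattice.empty(10)
    lat.set(3, 4, BLUE)
    draw = sample_relocation((3, 4), 0.0, lat, rng)
    assert (draw.dx, draw.dy) == (0, 0)
    assert draw.outcome is RelocationOutcome.LANDED
    assert lat.get(3, 4) == BLUE and lat.occupied_count == 1


def test_relocation_dx_uniform_and_dy_bounded():
    """dx is uniform on {0..floor(f*L)} and |dy| <= dx (goodness of fit)."""
    rng = np.random.default_rng(3)
    L, f = 60, 1.0
    counts = np.zeros(L + 1, dtype=int)
    n = 100_000
    for _ in range(n):
        lat = Lattice.empty(L)
        lat.set(0, 0, BLUE)
        draw = sample_relocation((0, 0), f, lat, rng)
        assert abs(draw.dy) <= draw.dx <= L
        counts[draw.dx] += 1
    chi2 = sstats.chisquare(counts)
    assert chi2.pvalue > 1e-4


def test_relocation_occupied_landing_removes(rng):
    """A cell forced to land on an occupied site is lost with the outflow."""
    lat = Lattice(np.full((3, 3), RED, dtype=np.int8))
    lat.grid[1, 1] = BLUE
    removed = 0
    for _ in range(200):
        work = Lattice(lat.grid.copy())
        draw = sample_relocation((1, 1), 1.0, work, rng)
        if draw.outcome is RelocationOutcome.REMOVED:
            removed += 1
            assert work.occupied_count == 8
        else:  # only its own vacated site is empty
            assert (draw.dx % 3, draw.dy % 3) in {(0, 0)}
    assert removed > 0


# ----------------------------------------------------------------------
# detachment
# ----------------------------------------------------------------------
def test_detachment_sigma1_never(rng):
    lat = Lattice.empty(6)
    lat.set(2, 2, BLUE)
    cfg = SimulationConfig(L=6, sigma=1.0, f=1.0)
    for _ in range(200):
        out = attempt_detachment(lat, cfg, rng)
        assert not out.detached
    assert lat.get(2, 2) == BLUE


def test_detachment_f0_never(rng):
    lat = Lattice.empty(6)
    lat.set(2, 2, BLUE)
    cfg = SimulationConfig(L=6, sigma=0.0, f=0.0)
    for _ in range(200):
        assert not attempt_detachment(lat, cfg, rng).detached


def test_detachment_drafting_shields(rng):
    """A cell with an occupied upstream neighbor never detaches, even at
    sigma=0, f=1."""
    base = Lattice.empty(6)
    base.set(2, 2, BLUE)
    base.set(1, 2, RED)  # upstream of (2,2)
    cfg = SimulationConfig(L=6, sigma=0.0, f=1.0)
    for _ in range(300):
        out = attempt_detachment(base.copy(), cfg, rng)
        if out.detached:
            assert out.origin != (2, 2)


def test_detachment_exposed_cell_always_detaches_at_pd1(rng):
    """An isolated cell at sigma=0, f=1 has p_d=1: it detaches every attempt
    and lands inside the downstream cone (or is lost)."""
    cfg = SimulationConfig(L=8, sigma=0.0, f=1.0)
    for _ in range(100):
        lat = Lattice.empty(8)
        lat.set(4, 4, BLUE)
        out = attempt_detachment(lat, cfg, rng)
        assert out.detached
        assert out.occupancy_change in (-1, 0)
        assert lat.occupied_count in (0, 1)


def test_detachment_upstream_wraps_periodically(rng):
    """Column 0's upstream neighbor is column L-1."""
    base = Lattice.empty(5)
    base.set(0, 2, BLUE)
    base.set(4, 2, RED)  # occupies (L-1, 2): shields (0, 2)
    cfg = SimulationConfig(L=5, sigma=0.0, f=1.0)
    for _ in range(300):
        out = attempt_detachment(base.copy(), cfg, rng)
        if out.detached:
            assert out.origin == (4, 2)


# ----------------------------------------------------------------------
# step and run
# ----------------------------------------------------------------------
def test_step_occupancy_change_bounded(rng, small_config):
    lat = initialize_lattice(small_config, rng)
    for _ in range(2000):
        n0 = lat.occupied_count
        if n0 == 0:
            break
        birth, det = step(lat, small_config, rng)
        assert lat.occupied_count - n0 in (-1, 0, 1)
        assert lat.occupied_count <= lat.n_sites


def test_step_sigma1_detachment_never_changes_lattice(rng):
    cfg = SimulationConfig(L=15, sigma=1.0, rho0=0.1, f=1.0)
    lat = initialize_lattice(cfg, rng)
    for _ in range(3000):
        birth, det = step(lat, cfg, rng)
        assert not det.detached
        if lat.occupied_count >= cfg.threshold_count:
            break


def test_step_forced_growth_single_cell(rng):
    """p_b=1 with one isolated cell and f=0: occupancy must reach 2."""
    cfg = SimulationConfig(L=5, sigma=0.5, rho0=0.04, f=0.0, p_b=1.0)
    lat = Lattice.empty(5)
    lat.set(2, 2, BLUE)
    step(lat, cfg, rng)
    assert lat.occupied_count == 2


def test_run_reaches_threshold(small_config):
    lat, rec = run_to_confluence(small_config, engine="python")
    assert rec.terminated_by is Termination.THRESHOLD
    assert lat.occupied_fraction >= small_config.occupancy_threshold
    assert rec.final_fraction == pytest.approx(lat.occupied_fraction)


def test_run_rho0_zero_rejected():
    with pytest.raises(InvalidParameterError):
        run_to_confluence(SimulationConfig(L=10, rho0=0.0))


def test_run_already_saturated_returns_immediately():
    cfg = SimulationConfig(L=10, rho0=1.0, occupancy_threshold=0.95, seed=0)
    lat, rec = run_to_confluence(cfg, engine="python")
    assert rec.steps == 0
    assert lat.occupied_count == 100


def test_run_bookkeeping_invariant(small_config):
    """final occupancy = founders + births − shove removals − relocation
    removals, on both engines."""
    for engine in ("python", "numba"):
        lat, rec = run_to_confluence(small_config, engine=engine)
        expected = (
            small_config.n_founders
            + rec.births
            - rec.shove_removals
            - rec.relocation_removals
        )
        assert lat.occupied_count == expected


def test_sigma1_founders_keep_their_sites_python_engine():
    """At sigma=1 neither shoving nor detachment can move a founder."""
    cfg = SimulationConfig(L=15, sigma=1.0, rho0=0.05, f=1.0, seed=11)
    rng = np.random.default_rng(cfg.seed)
    init = initialize_lattice(cfg, np.random.default_rng(cfg.seed))
    founders = init.site_colors()
    lat, rec = run_to_confluence(cfg, engine="python")
    final = lat.site_colors()
    for site, color in founders.items():
        assert final[site] == color


def test_f0_no_transport():
    """With f=0 the run record shows zero detachments for any sigma."""
    for sigma in (0.0, 0.5, 1.0):
        cfg = SimulationConfig(L=15, sigma=sigma, rho0=0.05, f=0.0, seed=5)
        for engine in ("python", "numba"):
            _, rec = run_to_confluence(cfg, engine=engine)
            assert rec.detachments == 0
            assert rec.relocation_removals == 0


def test_color_symmetry_label_swap():
    """Swapping BLUE<->RED in the initial lattice and replaying the same
    random stream yields the label-swapped final lattice."""
    cfg = SimulationConfig(L=12, sigma=0.3, rho0=0.1, f=0.7)
    from biofilmca.model import step as _step

    def run(grid, seed, n_steps=1500):
        lat = Lattice(grid.copy())
        rng = np.random.default_rng(seed)
        for _ in range(n_steps):
            if lat.occupied_count in (0, lat.n_sites):
                break
            _step(lat, cfg, rng)
        return lat.grid

    init = initialize_lattice(cfg, np.random.default_rng(21)).grid
    swapped = np.where(init == BLUE, RED, np.where(init == RED, BLUE, EMPTY)).astype(np.int8)
    a = run(init, seed=77)
    b = run(swapped, seed=77)
    b_unswapped = np.where(b == BLUE, RED, np.where(b == RED, BLUE, EMPTY))
    assert np.array_equal(a, b_unswapped)


def test_lattice_rejects_bad_values():
    with pytest.raises(InvalidParameterError):
        Lattice(np.array([[0, 3], [1, 2]]))
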