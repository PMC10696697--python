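"""Deterministic toy worlds and species states with known ground truth.

Every scenario fully determines its landscape, parameters, and the
analytically expected outcome, so each stage of the pipeline can be
tested without external data:

``one-cell``
    A single habitable cell: one species forever, no speciation,
    temporal turnover 1.
``two-island``
    Two habitable blocks sealed off from each other by a land wall.
    Divergence between the islands grows by one per timestep, so the
    first speciation happens at timestep ``rho + 1``.
``four-island-fig4a``
    One species on four mutually isolated islands; one island's
    divergences to all others already exceed the speciation threshold.
    A single divergence-and-speciation step yields 2 species and 4
    populations in total.
``ring-barrier``
    A habitable cell fully enclosed by land inside open sea: the
    enclosed cell is unreachable from outside.
``multi-island``
    A 20 x 20 archipelago of eight reef banks in four quadrants sealed
    by a land cross that floods briefly at sea-level high stands, plus
    a latitudinal temperature gradient with slow drift.  This is the
    study landscape for scaled-down parameter sweeps; no exact outcome
    is attached.

Parameters default to the midpoints of the explored biological ranges
with the dispersal-kernel shape pinned at 2.5; scenarios override only
what their expected outcome requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .engine import SimulationParams, SpeciesState
from .landscape import Landscape, make_longitudinal_bioregions
from .phylo import PhylogenyEventLog

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "SCENARIOS", "make_multi_island_world"]

SCENARIOS = ("one-cell", "two-island", "four-island-fig4a", "ring-barrier", "multi-island")


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str
    rho: int = 10
    n_timesteps: int = 432
    seed: int = 0


@dataclass
class Fixture:
    scenario: str
    landscape: Landscape
    params: SimulationParams
    expected: dict[str, Any]
    states: list[SpeciesState] | None = None
    log: PhylogenyEventLog | None = None


def _static_landscape(
    elev: np.ndarray,
    temp: float = 24.2,
    n_frames: int = 2,
    cell_size_km: float = 100.0,
    n_bioregions: int = 1,
) -> Landscape:
    """Time-constant landscape from an elevation grid (m, positive up)."""
    R, C = elev.shape
    depth = np.repeat(-elev[None, :, :], n_frames, axis=0).astype(float)
    temperature = np.full((n_frames, R, C), float(temp))
    habitable = (depth > 0) & (depth <= 2000.0) & (temperature >= 17.0)
    return Landscape(
        temperature=temperature,
        depth=depth,
        habitable=habitable,
        bioregion=make_longitudinal_bioregions(R, C, n_bioregions),
        region_names=[f"realm_{i + 1}" for i in range(n_bioregions)],
        cell_size_km=cell_size_km,
    )


def _calm_params(rho: int, seed: int) -> SimulationParams:
    """Midpoint parameters tamed for exact expectations.

    Dispersal reaches neighbouring cells but not across barriers;
    mutation is at the bottom of its range so traits stay near the
    (matching) environmental temperature.
    """
    return SimulationParams(
        dispersal_scale=150.0,
        speciation_threshold=rho,
        mutation_sd=0.01,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _one_cell(spec: FixtureSpec) -> Fixture:
    elev = np.full((3, 3), 100.0)
    elev[1, 1] = -50.0
    world = _static_landscape(elev)
    return Fixture(
        scenario=spec.scenario,
        landscape=world,
        params=_calm_params(spec.rho, spec.seed),
        expected={"n_extant": 1, "n_speciations": 0, "turnover": 1.0},
    )


def _two_island(spec: FixtureSpec) -> Fixture:
    # habitable columns 0-1 and 3-4, a full land wall at column 2
    elev = np.full((4, 5), -50.0)
    elev[:, 2] = 100.0
    world = _static_landscape(elev)
    return Fixture(
        scenario=spec.scenario,
        landscape=world,
        params=_calm_params(spec.rho, spec.seed),
        expected={
            "first_speciation_time": spec.rho + 1,
            "n_extant": 2,
            "n_clusters": 2,
        },
    )


def _four_island(spec: FixtureSpec) -> Fixture:
    # four 3x3 habitable blocks separated by a land cross
    elev = np.full((7, 7), -50.0)
    elev[3, :] = 100.0
    elev[:, 3] = 100.0
    world = _static_landscape(elev)
    params = _calm_params(spec.rho, spec.seed)

    cells = world.habitable_cells(0)
    rows, cols = np.divmod(cells, 7)
    quadrant = (rows > 3).astype(int) * 2 + (cols > 3).astype(int)
    n = cells.size
    rho = spec.rho
    div = np.full((4, 4), 1.0)
    np.fill_diagonal(div, 0.0)
    div[0, 1:] = div[1:, 0] = rho + 1.0  # one island isolated beyond the threshold
    sp = SpeciesState(
        species_id=0,
        cells=cells.copy(),
        abundance=np.ones(n),
        thermal_optimum=np.full(n, params.thermal_optimum),
        competitive_niche=np.full(n, 0.5),
        cluster_of=quadrant,
        divergence=div,
        origin_time=0,
    )
    return Fixture(
        scenario=spec.scenario,
        landscape=world,
        params=params,
        states=[sp],
        log=PhylogenyEventLog(),
        expected={"n_species_after": 2, "n_populations_after": 4},
    )


def _ring_barrier(spec: FixtureSpec) -> Fixture:
    # habitable cell at the centre, land ring around it, open sea outside
    elev = np.full((5, 5), -50.0)
    elev[1:4, 1:4] = 100.0
    elev[2, 2] = -50.0
    world = _static_landscape(elev)
    return Fixture(
        scenario=spec.scenario,
        landscape=world,
        params=_calm_params(spec.rho, spec.seed),
        expected={"enclosed_cell": 12, "unreachable_from_outside": True},
    )


#: reef banks of the study world: (row, col, width in cells); four banks of
#: unequal size per quadrant at varied gaps, so that for any dispersal
#: scale some bank pair sits in the intermediate gene-flow regime
_BANKS = (
    # north-west quadrant
    (2, 1, 1.1), (2, 5, 0.8), (5, 2, 0.9), (6, 6, 1.2),
    # north-east quadrant
    (2, 13, 0.9), (3, 18, 1.1), (6, 12, 0.8), (6, 17, 0.9),
    # south-west quadrant
    (13, 1, 1.0), (14, 6, 0.9), (17, 2, 1.2), (17, 6, 0.8),
    # south-east quadrant
    (13, 13, 0.8), (14, 18, 1.0), (16, 16, 1.1), (17, 12, 0.9),
)


def make_multi_island_world(
    n_timesteps: int = 432,
    n_bioregions: int = 5,
    cell_size_km: float = 500.0,
) -> Landscape:
    """An archipelago of sixteen reef banks on a 20 x 20 grid.

    Four quadrants of four banks each (unequal sizes, varied spacings)
    are separated by a land cross.  The horizontal arm (rows 8-11) is
    permanent land, so the northern and southern hemispheres never
    exchange migrants and their divergence accrues without interruption.
    The vertical arm (columns 8-11) stands 119 m above mean sea level:
    it is land except at the very peak of the 40-step, 120 m sea-level
    cycle, when it floods into a shallow corridor that reconnects the
    east and west quadrants of each hemisphere for a single timestep per
    cycle.  Bank margins breathe with the 2000 m depth cut-off as sea
    level moves, and with the 17 degC cut-off as the latitudinal
    temperature field drifts.  Deep sea between banks within a quadrant
    is always passable but never habitable, so within-quadrant isolation
    is set by distance and dispersal ability; east-west isolation is
    punctuated by the rare floods; north-south isolation is absolute.
    """
    R = C = 20
    lats = np.linspace(40.0, -40.0, R)
    lons = np.linspace(0.0, 342.0, C)
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")

    elev = np.full((R, C), -2600.0)
    for (br, bc, sigma) in _BANKS:
        d2 = (rr - br) ** 2 + (cc - bc) ** 2
        elev = np.maximum(elev, -2600.0 + 2470.0 * np.exp(-d2 / (2.0 * sigma**2)))
    elev[:, 8:12] = 119.0
    elev[8:12, :] = 200.0

    steps = np.arange(n_timesteps)
    sea_level = 120.0 * np.sin(2.0 * np.pi * steps / 40.0)
    drift = 2.0 * np.sin(2.0 * np.pi * steps / 60.0)

    temperature = (28.0 - 0.27 * np.abs(lats))[None, :, None] + drift[:, None, None]
    temperature = np.broadcast_to(temperature, (n_timesteps, R, C)).copy()
    depth = sea_level[:, None, None] - elev[None, :, :]
    habitable = (depth > 0) & (depth <= 2000.0) & (temperature >= 17.0)

    return Landscape(
        temperature=temperature,
        depth=depth,
        habitable=habitable,
        bioregion=make_longitudinal_bioregions(R, C, n_bioregions),
        region_names=[f"realm_{i + 1}" for i in range(n_bioregions)],
        cell_size_km=cell_size_km,
        lats=lats,
        lons=lons,
    )


def _multi_island(spec: FixtureSpec) -> Fixture:
    world = make_multi_island_world(n_timesteps=spec.n_timesteps)
    return Fixture(
        scenario=spec.scenario,
        landscape=world,
        params=SimulationParams(speciation_threshold=spec.rho, seed=spec.seed),
        expected={},
    )


_BUILDERS = {
    "one-cell": _one_cell,
    "two-island": _two_island,
    "four-island-fig4a": _four_island,
    "ring-barrier": _ring_barrier,
    "multi-island": _multi_island,
}


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the named scenario; unknown names list the available ones."""
    try:
        builder = _BUILDERS[spec.scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {spec.scenario!r}; available: {', '.join(SCENARIOS)}"
        ) from None
    return builder(spec)
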