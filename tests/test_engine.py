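"""The per-timestep eco-evolutionary loop: dispersal, divergence,
speciation, trait evolution, ecology, and whole-run invariants."""

import numpy as np
import pytest

from diverscale.engine import (
    SimulationParams,
    SpeciesState,
    dispersal_success,
    run_simulation,
    seed_ancestor,
    step_divergence_and_speciation,
    step_ecology,
    step_trait_evolution,
)
from diverscale.fixtures import FixtureSpec, make_fixture
from diverscale.landscape import UnseedableWorldError, WorldSpec, generate_world
from diverscale.phylo import PhylogenyEventLog


def _species(cells, cluster_of, divergence, niche=0.5, t_opt=24.2, abundance=1.0):
    cells = np.asarray(cells)
    n = cells.size
    return SpeciesState(
        species_id=0,
        cells=cells,
        abundance=np.full(n, float(abundance)),
        thermal_optimum=np.full(n, float(t_opt)),
        competitive_niche=np.full(n, float(niche)),
        cluster_of=np.asarray(cluster_of),
        divergence=np.asarray(divergence, dtype=float),
    )


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def test_seed_ancestor_occupies_all_habitable_cells():
    fx = make_fixture(FixtureSpec("two-island"))
    sp = seed_ancestor(fx.landscape, fx.params)
    hab = fx.landscape.habitable_cells(0)
    np.testing.assert_array_equal(sp.cells, hab)
    np.testing.assert_allclose(sp.abundance, 1.0)
    np.testing.assert_allclose(sp.thermal_optimum, fx.params.thermal_optimum)
    np.testing.assert_allclose(sp.divergence, 0.0)


def test_seed_ancestor_unseedable():
    fx = make_fixture(FixtureSpec("one-cell"))
    fx.landscape.habitable[:] = False
    with pytest.raises(UnseedableWorldError):
        seed_ancestor(fx.landscape, fx.params)


# ---------------------------------------------------------------------------
# dispersal kernel
# ---------------------------------------------------------------------------

def test_dispersal_zero_distance_always_succeeds():
    rng = np.random.default_rng(0)
    assert dispersal_success(rng, np.zeros(10_000), scale=500.0, shape=2.5).all()


def test_dispersal_success_rate_at_scale_distance():
    # P(X > d) at d = scale is exp(-1) for any Weibull shape
    rng = np.random.default_rng(1)
    n = 100_000
    hits = dispersal_success(rng, np.full(n, 800.0), scale=800.0, shape=2.5)
    p = np.exp(-1.0)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits.mean() - p) < 3 * se


def test_unreachable_distance_never_succeeds():
    rng = np.random.default_rng(2)
    assert not dispersal_success(rng, np.full(100, np.inf), 5000.0, 2.5).any()


def test_colonisation_uses_initial_abundance_and_source_traits():
    fx = make_fixture(FixtureSpec("two-island", rho=50))
    params = SimulationParams(
        dispersal_scale=150.0, speciation_threshold=50,
        mutation_sd=0.0, initial_abundance=0.4, seed=5,
    )
    world = fx.landscape
    sp = seed_ancestor(world, params)
    # vacate one island cell, then let dispersal recolonise it
    target = sp.cells[0]
    sp.keep_cells(sp.cells != target)
    from diverscale.engine import step_dispersal

    rng = np.random.default_rng(3)
    for _ in range(20):
        step_dispersal([sp], world, 0, params, rng)
        if target in sp.cells:
            break
    assert target in sp.cells
    i = int(np.searchsorted(sp.cells, target))
    assert sp.abundance[i] == pytest.approx(0.4)
    assert sp.thermal_optimum[i] == pytest.approx(params.thermal_optimum)


# ---------------------------------------------------------------------------
# divergence and speciation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "start,gene_flow,expected",
    [(5.0, False, 6.0), (5.0, True, 4.0), (0.0, True, 0.0)],
)
def test_divergence_increment_decrement_floor(start, gene_flow, expected):
    div = np.array([[0.0, start], [start, 0.0]])
    sp = _species([0, 1], [0, 1], div)
    log = PhylogenyEventLog()
    record = {0: {(0, 1)}} if gene_flow else {}
    step_divergence_and_speciation([sp], record, rho=100, log=log, t=1)
    assert sp.divergence[0, 1] == pytest.approx(expected)


def test_four_isolated_clusters_one_beyond_threshold():
    # one species in four clusters, one cluster's divergences above rho:
    # a single step yields 2 species and still 4 populations in total
    fx = make_fixture(FixtureSpec("four-island-fig4a", rho=10))
    states, log = fx.states, fx.log
    step_divergence_and_speciation(states, {}, rho=10, log=log, t=1)
    extant = [s for s in states if s.is_extant]
    assert len(extant) == fx.expected["n_species_after"]
    assert sum(s.n_clusters for s in extant) == fx.expected["n_populations_after"]
    assert len(log.speciations) == 1
    assert log.speciations[0].min_cross_divergence > 10


def test_chain_connectivity_prevents_speciation():
    # A-B over threshold but connected through C: no split
    rho = 10
    div = np.array(
        [
            [0.0, rho + 2.0, 1.0],
            [rho + 2.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ]
    )
    sp = _species([0, 1, 2], [0, 1, 2], div)
    log = PhylogenyEventLog()
    # gene flow on the short edges keeps them below rho after the update
    step_divergence_and_speciation([sp], {0: {(0, 2), (1, 2)}}, rho, log, t=1)
    assert sp.n_clusters == 3
    assert not log.speciations


def test_parent_keeps_largest_component():
    rho = 5
    div = np.array([[0.0, rho + 2.0], [rho + 2.0, 0.0]])
    sp = _species([0, 1, 2], [0, 1, 1], div)  # cluster 1 holds more cells
    log = PhylogenyEventLog()
    step_divergence_and_speciation([sp], {0: {(0, 1)}}, rho, log, t=3)
    # decrement leaves rho+1 > rho: split; parent keeps the 2-cell cluster
    assert sp.n_cells == 2
    assert log.speciations[0].parent_id == 0
    assert log.speciations[0].child_id == 1


# ---------------------------------------------------------------------------
# trait evolution
# ---------------------------------------------------------------------------

def test_zero_mutation_leaves_homogeneous_traits_unchanged():
    sp = _species([0, 1, 2], [0, 0, 0], np.zeros((1, 1)), t_opt=20.0, niche=0.3)
    params = SimulationParams(mutation_sd=0.0)
    step_trait_evolution([sp], params, np.random.default_rng(0))
    np.testing.assert_allclose(sp.thermal_optimum, 20.0)
    np.testing.assert_allclose(sp.competitive_niche, 0.3)


def test_homogenisation_assigns_cluster_means_and_clamps():
    sp = _species([0, 1, 2, 3], [0, 0, 1, 1], np.zeros((2, 2)))
    sp.thermal_optimum = np.array([20.0, 24.0, 10.0, 30.0])
    sp.competitive_niche = np.array([0.2, 0.4, 1.3, 1.5])
    step_trait_evolution([sp], SimulationParams(mutation_sd=0.0), np.random.default_rng(0))
    np.testing.assert_allclose(sp.thermal_optimum, [22.0, 22.0, 20.0, 20.0])
    np.testing.assert_allclose(sp.competitive_niche[:2], 0.3)
    np.testing.assert_allclose(sp.competitive_niche[2:], 1.0)  # clamped


def test_trait_variance_accumulates_like_random_walk():
    # a lone single-cell species performs a Gaussian random walk: after t
    # steps the across-replicate variance is ~ t * sigma^2
    sigma, t, reps = 0.1, 16, 400
    finals = []
    for r in range(reps):
        sp = _species([0], [0], np.zeros((1, 1)), t_opt=0.0)
        rng = np.random.default_rng(1000 + r)
        for _ in range(t):
            step_trait_evolution([sp], SimulationParams(mutation_sd=sigma), rng)
        finals.append(sp.thermal_optimum[0])
    var = np.var(finals)
    expected = t * sigma**2
    # chi^2 MC error: s.d. of the sample variance ~ expected * sqrt(2/reps)
    assert abs(var - expected) < 4 * expected * np.sqrt(2.0 / reps)


# ---------------------------------------------------------------------------
# ecology
# ---------------------------------------------------------------------------

def _eco_world(temp=24.0):
    fx = make_fixture(FixtureSpec("one-cell"))
    fx.landscape.temperature[:] = temp
    return fx.landscape


def test_perfectly_adapted_lone_species_keeps_full_abundance():
    world = _eco_world(24.0)
    sp = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.5)
    step_ecology([sp], world, 0, SimulationParams(niche_width=0.2), PhylogenyEventLog(), 1)
    assert sp.abundance[0] == pytest.approx(1.0)


def test_thermal_multiplier_one_sd_off():
    world = _eco_world(24.0)
    sp = _species([4], [0], np.zeros((1, 1)), t_opt=26.0, niche=0.5)
    step_ecology([sp], world, 0, SimulationParams(niche_width=0.2), PhylogenyEventLog(), 1)
    assert sp.abundance[0] == pytest.approx(np.exp(-0.5))


def test_boundary_penalty_fraction():
    # niche 0.05, w 0.2: interval [-0.15, 0.25] has 0.15 outside [0, 1]
    world = _eco_world(24.0)
    sp = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.05)
    step_ecology([sp], world, 0, SimulationParams(niche_width=0.2), PhylogenyEventLog(), 1)
    assert sp.abundance[0] == pytest.approx(1.0 - 0.15 / 0.4)


def test_cell_below_threshold_is_vacated():
    world = _eco_world(24.0)
    delta = np.sqrt(-8.0 * np.log(0.099))  # thermal multiplier 0.099 < 0.1
    sp = _species([4], [0], np.zeros((1, 1)), t_opt=24.0 + delta, niche=0.5)
    log = PhylogenyEventLog()
    step_ecology([sp], world, 0, SimulationParams(niche_width=0.2), log, 7)
    assert sp.n_cells == 0
    assert not sp.is_extant
    assert log.extinctions[0].time == 7


def test_identical_niches_compete_to_mutual_exclusion():
    # full overlap at abundance 1 is a full competitive load for both
    world = _eco_world(24.0)
    a = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.5)
    b = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.5)
    b.species_id = 1
    step_ecology([a, b], world, 0, SimulationParams(niche_width=0.2), PhylogenyEventLog(), 1)
    assert a.n_cells == 0 and b.n_cells == 0


def test_partial_overlap_competition():
    # |n_a - n_b| = w: overlap w, load = a_j * w / (2w) = 0.5
    world = _eco_world(24.0)
    a = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.4)
    b = _species([4], [0], np.zeros((1, 1)), t_opt=24.0, niche=0.6)
    b.species_id = 1
    step_ecology([a, b], world, 0, SimulationParams(niche_width=0.2), PhylogenyEventLog(), 1)
    assert a.abundance[0] == pytest.approx(0.5)
    assert b.abundance[0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# whole-run behaviour
# ---------------------------------------------------------------------------

def test_run_simulation_deterministic():
    fx = make_fixture(FixtureSpec("two-island", rho=6))
    r1 = run_simulation(fx.landscape, fx.params, n_steps=15)
    r2 = run_simulation(fx.landscape, fx.params, n_steps=15)
    assert r1.log.to_dataframe().equals(r2.log.to_dataframe())
    assert r1.summaries.equals(r2.summaries)


def test_threshold_beyond_horizon_means_no_speciation():
    fx = make_fixture(FixtureSpec("two-island", rho=30))
    res = run_simulation(fx.landscape, fx.params, n_steps=20)
    assert not res.log.speciations
    assert len(res.extant) == 1


def test_two_island_first_speciation_at_rho_plus_one():
    rho = 7
    fx = make_fixture(FixtureSpec("two-island", rho=rho))
    res = run_simulation(fx.landscape, fx.params, n_steps=rho + 4)
    assert res.log.speciations[0].time == rho + 1
    assert len(res.extant) == 2


def test_high_dispersal_drives_divergence_to_zero():
    # all-sea world with an enormous kernel: constant gene flow, no splits
    world = generate_world(
        WorldSpec(n_rows=4, n_cols=4, n_timesteps=2, land_fraction=0.0,
                  relief_m=100.0, sea_level_amplitude_m=0.0,
                  temp_drift_amplitude=0.0, seed=1)
    )
    params = SimulationParams(dispersal_scale=1e6, speciation_threshold=3,
                              mutation_sd=0.0, seed=2)
    res = run_simulation(world, params, n_steps=25)
    assert not res.log.speciations
    for sp in res.extant:
        assert np.all(sp.divergence == 0.0)


def _random_small_runs(n_runs=8, n_steps=35):
    out = []
    master = np.random.default_rng(2024)
    seed = 0
    while len(out) < n_runs:
        seed += 1
        try:
            world = generate_world(
                WorldSpec(n_rows=8, n_cols=8, n_timesteps=n_steps + 1,
                          land_fraction=0.35, seed=seed)
            )
        except UnseedableWorldError:
            continue
        params = SimulationParams(
            dispersal_scale=float(master.uniform(100, 600)),
            speciation_threshold=int(master.integers(4, 15)),
            mutation_sd=float(master.uniform(0.01, 0.15)),
            niche_width=float(master.uniform(0.05, 0.5)),
            thermal_optimum=float(master.uniform(20, 28)),
            seed=seed,
        )
        out.append((world, params))
    return out


def test_run_invariants_on_random_small_worlds():
    """Divergence bounds, abundance bounds and event-log conservation."""
    for world, params in _random_small_runs():
        rho = params.speciation_threshold

        def check(t, states, log):
            for sp in states:
                if not sp.is_extant or sp.n_clusters < 2:
                    continue
                # below-threshold graph is connected after speciation
                from scipy.sparse import csr_matrix
                from scipy.sparse.csgraph import connected_components

                n_comp, _ = connected_components(
                    csr_matrix(sp.divergence <= rho), directed=False
                )
                assert n_comp == 1
                assert np.all(sp.divergence >= 0)

        res = run_simulation(world, params, observer=check)
        for e in res.log.speciations:
            assert e.min_cross_divergence > rho
        # conservation: created = extant + extinct at every timestep
        s = res.summaries
        assert (s["n_created"] == s["n_extant"] + s["n_extinct"]).all()
        for sp in res.extant:
            assert np.all(sp.abundance >= 0.1)
            assert np.all(sp.abundance <= 1.0)
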