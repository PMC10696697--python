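"""Per-timestep eco-evolutionary loop over a dynamic seascape.

One simulation follows a clade of reef fish from a single ancestor that
occupies every habitable cell of the first timestep.  Each timestep runs,
in order:

1. housekeeping — occupants of cells that became uninhabitable are
   removed, and every species' geographic clusters (populations) are
   recomputed for the current coastline;
2. divergence update and allopatric speciation, using the dispersal
   (gene-flow) record of the previous timestep;
3. dispersal — one Weibull kernel draw per (source cell, target cell)
   pair decides success; success into an occupied cell is gene flow,
   into an empty habitable cell a colonisation;
4. trait evolution — Gaussian mutation of the thermal optimum and the
   competitive niche, then homogenisation to the cluster mean;
5. ecology — thermal filtering, niche-overlap competition and a
   niche-boundary penalty set abundances; cells that fall below the
   survival threshold are vacated and empty species go extinct.

Divergence between two populations of the same species is an abstract
counter in units of timesteps: +1 per step without gene flow between
them, −1 (floored at zero) per step with it.  When a group of
populations sits at divergence greater than the speciation threshold
``rho`` from every other population of the species — i.e. the graph of
"still connected" pairs (divergence <= rho) falls apart — each isolated
group becomes a new species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components

from .landscape import Landscape, UnseedableWorldError
from .phylo import PhylogenyEventLog

__all__ = [
    "SimulationParams",
    "SpeciesState",
    "SimulationResult",
    "seed_ancestor",
    "assign_clusters",
    "step_dispersal",
    "step_divergence_and_speciation",
    "step_trait_evolution",
    "step_ecology",
    "run_simulation",
    "dispersal_success",
    "dispersal_reach_99",
]

#: minimum abundance below which a cell is vacated (local extinction)
ABUNDANCE_FLOOR = 0.1
#: standard deviation (degC) of the thermal performance Gaussian
THERMAL_SD = 2.0
#: competitive niche of the root species (midpoint of the [0, 1] axis)
INITIAL_NICHE = 0.5


@dataclass(frozen=True)
class SimulationParams:
    """The varied biological parameters of one simulation.

    Defaults are the midpoints of the explored ranges; the Weibull shape
    of the dispersal kernel is fixed at 2.5.
    """

    initial_abundance: float = 0.555  # abundance of a freshly colonised cell
    thermal_optimum: float = 24.2  # degC, root species' optimum at t=0
    dispersal_scale: float = 2550.0  # km, Weibull kernel scale
    dispersal_shape: float = 2.5  # Weibull kernel shape (fixed)
    speciation_threshold: int = 306  # rho, timesteps of divergence to speciate
    mutation_sd: float = 0.08  # per-step s.d. of trait mutation
    niche_width: float = 0.26  # w, half-width of the competitive niche
    seed: int = 0


@dataclass
class SpeciesState:
    """Occupancy, traits, and population divergence structure of one species.

    All per-cell arrays are aligned with ``cells`` (sorted flat cell
    indices).  ``cluster_of`` assigns each occupied cell to a geographic
    cluster (population); ``divergence`` is the symmetric cluster-by-
    cluster divergence matrix in units of timesteps (fractional values
    can appear when clusters merge and their histories are averaged).
    """

    species_id: int
    cells: np.ndarray
    abundance: np.ndarray
    thermal_optimum: np.ndarray
    competitive_niche: np.ndarray
    cluster_of: np.ndarray
    divergence: np.ndarray
    parent_id: int | None = None
    origin_time: int = 0
    extinction_time: int | None = None

    @property
    def is_extant(self) -> bool:
        return self.extinction_time is None

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)

    @property
    def n_clusters(self) -> int:
        return int(self.divergence.shape[0])

    def keep_cells(self, keep: np.ndarray) -> None:
        """Drop cells where ``keep`` is False (cluster structure untouched)."""
        self.cells = self.cells[keep]
        self.abundance = self.abundance[keep]
        self.thermal_optimum = self.thermal_optimum[keep]
        self.competitive_niche = self.competitive_niche[keep]
        self.cluster_of = self.cluster_of[keep]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=self.n_clusters)


@dataclass
class SimulationResult:
    states: list[SpeciesState]
    log: PhylogenyEventLog
    summaries: pd.DataFrame
    params: SimulationParams
    landscape: Landscape

    @property
    def extant(self) -> list[SpeciesState]:
        return [s for s in self.states if s.is_extant]


# ---------------------------------------------------------------------------
# seeding and clustering
# ---------------------------------------------------------------------------

def seed_ancestor(landscape: Landscape, params: SimulationParams) -> SpeciesState:
    """Create the root species occupying every habitable cell at t=0."""
    cells = landscape.habitable_cells(0)
    if cells.size == 0:
        raise UnseedableWorldError("no habitable cell at the first timestep")
    n = cells.size
    return SpeciesState(
        species_id=0,
        cells=cells.copy(),
        abundance=np.ones(n),
        thermal_optimum=np.full(n, params.thermal_optimum),
        competitive_niche=np.full(n, INITIAL_NICHE),
        cluster_of=np.zeros(n, dtype=int),
        divergence=np.zeros((1, 1)),
        parent_id=None,
        origin_time=0,
    )


def dispersal_reach_99(params: SimulationParams) -> float:
    """99th percentile of the Weibull dispersal kernel (km).

    Used to fuse geographic components that routine dispersal bridges,
    so a population is a dispersal-connected set of occupied cells, not
    merely a block of adjacent ones.
    """
    return params.dispersal_scale * np.log(100.0) ** (1.0 / params.dispersal_shape)


_EIGHT = np.ones((3, 3), dtype=int)


def assign_clusters(
    sp: SpeciesState,
    landscape: Landscape,
    frame: int,
    fuse_distance: float,
) -> list[set[int]]:
    """Recompute a species' geographic clusters and remap its divergences.

    Clusters are connected components of occupied cells under
    8-adjacency, with components additionally fused when the minimum
    cost distance between them is below ``fuse_distance`` (the species'
    dispersal reach).  Divergences between the new clusters are
    occupancy-weighted means of the old cluster-pair divergences; two
    fragments of a single former cluster start at divergence 0.

    Returns the old-to-new cluster mapping: element ``j`` is the set of
    new cluster indices that inherited cells from old cluster ``j``
    (empty if the old cluster lost all its cells).
    """
    R, C = landscape.n_rows, landscape.n_cols
    mask = np.zeros(R * C, dtype=bool)
    mask[sp.cells] = True
    lab, n_lab = ndimage.label(mask.reshape(R, C), structure=_EIGHT)
    comp = lab.ravel()[sp.cells] - 1

    if n_lab > 1 and np.isfinite(fuse_distance):
        cells_h, D = landscape.distances(frame)
        pos = np.searchsorted(cells_h, sp.cells)
        groups = [pos[comp == i] for i in range(n_lab)]
        parent = list(range(n_lab))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n_lab):
            for j in range(i + 1, n_lab):
                if find(i) == find(j):
                    continue
                dmin = D[np.ix_(groups[i], groups[j])].min()
                if dmin < fuse_distance:
                    parent[find(i)] = find(j)
        roots = np.array([find(i) for i in range(n_lab)])
        _, comp = np.unique(roots[comp], return_inverse=True)

    # renumber deterministically by first occurrence along sorted cells
    _, first = np.unique(comp, return_index=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_of = rank[np.searchsorted(np.unique(comp), comp)]
    k_new = int(new_of.max()) + 1

    # occupancy-weighted divergence remap
    k_old = sp.n_clusters
    W = np.zeros((k_new, k_old))
    np.add.at(W, (new_of, sp.cluster_of), 1.0)
    num = W @ sp.divergence @ W.T
    tot = W.sum(axis=1)
    den = np.outer(tot, tot) - W @ W.T  # pair count excluding same-old-cluster pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        div = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(div, 0.0)
    sp.cluster_of = new_of
    sp.divergence = 0.5 * (div + div.T)
    return [set(np.flatnonzero(W[:, j] > 0).tolist()) for j in range(k_old)]


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------

def dispersal_success(
    rng: np.random.Generator,
    distances: np.ndarray,
    scale: float,
    shape: float,
) -> np.ndarray:
    """One Weibull draw per entry; success where the draw exceeds the distance."""
    draws = rng.weibull(shape, size=np.shape(distances)) * scale
    return draws > np.asarray(distances)


def step_dispersal(
    states: list[SpeciesState],
    landscape: Landscape,
    frame: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> dict[int, set[tuple[int, int]]]:
    """Dispersal of every species; returns the per-species gene-flow record.

    The record maps species id to the set of unordered cluster pairs
    ``(i, j)`` (i < j) linked by at least one successful dispersal event
    this timestep, in either direction.  Colonisations (successes into
    cells unoccupied by the species at the start of the step) add the
    cell with ``initial_abundance`` and the source cell's traits, joining
    the source cell's cluster.
    """
    cells_h, D = landscape.distances(frame)
    pos = np.full(landscape.n_cells, -1, dtype=int)
    pos[cells_h] = np.arange(cells_h.size)
    record: dict[int, set[tuple[int, int]]] = {}

    for sp in states:
        if not sp.is_extant or sp.n_cells == 0:
            continue
        occ_pos = pos[sp.cells]
        dist = D[occ_pos]  # (n_occ, n_hab); inf where unreachable
        succ = dispersal_success(rng, dist, params.dispersal_scale, params.dispersal_shape)

        # gene flow between clusters, either direction
        succ_occ = succ[:, occ_pos]
        k = sp.n_clusters
        A = np.zeros((sp.n_cells, k))
        A[np.arange(sp.n_cells), sp.cluster_of] = 1.0
        M = (A.T @ succ_occ @ A) > 0
        linked = M | M.T
        pairs = {
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if linked[i, j]
        }
        record[sp.species_id] = pairs

        # colonisation of habitable cells unoccupied by this species
        empty = np.ones(cells_h.size, dtype=bool)
        empty[occ_pos] = False
        col_cols = np.flatnonzero(empty & succ.any(axis=0))
        if col_cols.size:
            src = np.argmax(succ[:, col_cols], axis=0)  # first successful source
            new_cells = cells_h[col_cols]
            sp.cells = np.concatenate([sp.cells, new_cells])
            sp.abundance = np.concatenate(
                [sp.abundance, np.full(new_cells.size, params.initial_abundance)]
            )
            sp.thermal_optimum = np.concatenate(
                [sp.thermal_optimum, sp.thermal_optimum[src]]
            )
            sp.competitive_niche = np.concatenate(
                [sp.competitive_niche, sp.competitive_niche[src]]
            )
            sp.cluster_of = np.concatenate([sp.cluster_of, sp.cluster_of[src]])
            order = np.argsort(sp.cells, kind="stable")
            sp.keep_cells(order)  # reorder to keep cells sorted
    return record


# ---------------------------------------------------------------------------
# divergence and speciation
# ---------------------------------------------------------------------------

def step_divergence_and_speciation(
    states: list[SpeciesState],
    record: dict[int, set[tuple[int, int]]],
    rho: float,
    log: PhylogenyEventLog,
    t: int,
) -> list[SpeciesState]:
    """Update pairwise divergences and split species that crossed ``rho``.

    Cluster pairs without gene flow this step gain +1 divergence, pairs
    with gene flow lose 1 (floored at 0).  Each species is then
    partitioned into connected components of the graph whose edges join
    cluster pairs at divergence <= rho; every component other than the
    parent's becomes a new species.  The parent identity stays with the
    component holding the most occupied cells (ties: the component
    containing the lowest cluster index).  Returns newly created species.
    """
    new_species: list[SpeciesState] = []
    for sp in sorted((s for s in states if s.is_extant), key=lambda s: s.species_id):
        k = sp.n_clusters
        if k == 0:
            continue
        dec = np.zeros((k, k), dtype=bool)
        for i, j in record.get(sp.species_id, ()):  # pairs valid for current clusters
            if i < k and j < k:
                dec[i, j] = dec[j, i] = True
        div = np.where(dec, np.maximum(sp.divergence - 1.0, 0.0), sp.divergence + 1.0)
        np.fill_diagonal(div, 0.0)
        sp.divergence = div
        if k == 1:
            continue

        adj = sparse.csr_matrix(div <= rho)
        n_comp, comp = connected_components(adj, directed=False)
        if n_comp == 1:
            continue

        sizes = sp.cluster_sizes()
        comp_cells = np.bincount(comp, weights=sizes, minlength=n_comp)
        comp_min_cluster = np.full(n_comp, k)
        for c in range(k):
            comp_min_cluster[comp[c]] = min(comp_min_cluster[comp[c]], c)
        parent_comp = min(
            range(n_comp), key=lambda c: (-comp_cells[c], comp_min_cluster[c])
        )
        cross = comp[:, None] != comp[None, :]
        min_cross = float(div[cross].min())

        child_comps = sorted(
            (c for c in range(n_comp) if c != parent_comp),
            key=lambda c: comp_min_cluster[c],
        )
        for c in child_comps:
            clusters = np.flatnonzero(comp == c)
            cell_mask = np.isin(sp.cluster_of, clusters)
            rank = {int(old): i for i, old in enumerate(clusters)}
            child = SpeciesState(
                species_id=log.next_species_id(),
                cells=sp.cells[cell_mask].copy(),
                abundance=sp.abundance[cell_mask].copy(),
                thermal_optimum=sp.thermal_optimum[cell_mask].copy(),
                competitive_niche=sp.competitive_niche[cell_mask].copy(),
                cluster_of=np.array([rank[int(x)] for x in sp.cluster_of[cell_mask]]),
                divergence=div[np.ix_(clusters, clusters)].copy(),
                parent_id=sp.species_id,
                origin_time=t,
            )
            log.record_speciation(t, sp.species_id, child.species_id, min_cross)
            new_species.append(child)

        # parent retains its own component; cross-component divergences dropped
        clusters = np.flatnonzero(comp == parent_comp)
        cell_mask = np.isin(sp.cluster_of, clusters)
        rank = {int(old): i for i, old in enumerate(clusters)}
        sp.keep_cells(cell_mask)
        sp.cluster_of = np.array([rank[int(x)] for x in sp.cluster_of])
        sp.divergence = div[np.ix_(clusters, clusters)].copy()
    states.extend(new_species)
    return new_species


# ---------------------------------------------------------------------------
# trait evolution
# ---------------------------------------------------------------------------

def step_trait_evolution(
    states: list[SpeciesState],
    params: SimulationParams,
    rng: np.random.Generator,
) -> None:
    """Gaussian trait mutation followed by within-cluster homogenisation.

    Each occupied cell's thermal optimum and competitive niche receive
    independent Normal(0, mutation_sd) increments; both traits are then
    set to their cluster's unweighted mean, and the competitive niche is
    clamped to [0, 1].
    """
    sd = params.mutation_sd
    for sp in sorted((s for s in states if s.is_extant), key=lambda s: s.species_id):
        n = sp.n_cells
        if n == 0:
            continue
        sp.thermal_optimum = sp.thermal_optimum + rng.normal(0.0, sd, size=n)
        sp.competitive_niche = sp.competitive_niche + rng.normal(0.0, sd, size=n)
        counts = np.bincount(sp.cluster_of, minlength=sp.n_clusters).astype(float)
        counts[counts == 0] = 1.0
        t_mean = np.bincount(sp.cluster_of, weights=sp.thermal_optimum, minlength=sp.n_clusters) / counts
        c_mean = np.bincount(sp.cluster_of, weights=sp.competitive_niche, minlength=sp.n_clusters) / counts
        sp.thermal_optimum = t_mean[sp.cluster_of]
        sp.competitive_niche = np.clip(c_mean[sp.cluster_of], 0.0, 1.0)


# ---------------------------------------------------------------------------
# ecology
# ---------------------------------------------------------------------------

def step_ecology(
    states: list[SpeciesState],
    landscape: Landscape,
    frame: int,
    params: SimulationParams,
    log: PhylogenyEventLog,
    t: int,
    colonised_this_step: dict[int, np.ndarray] | None = None,
) -> None:
    """Thermal filtering, competition, boundary penalty, local extinction.

    Per occupied cell and species: abundance starts at 1 (or at
    ``initial_abundance`` for cells colonised this timestep — the
    incumbency effect), is multiplied by the thermal performance
    ``exp(-(T_opt - T_env)^2 / (2 * 2^2))``, reduced by competition with
    co-occurring species in proportion to their abundances and niche
    overlap, and reduced by the fraction of the niche interval
    ``[niche - w, niche + w]`` lying outside [0, 1].  Cells ending below
    0.1 are vacated; species left without cells go extinct.
    """
    w = params.niche_width
    temp = landscape.temperature[frame].ravel()
    extant = [s for s in sorted(states, key=lambda s: s.species_id) if s.is_extant and s.n_cells]

    for sp in extant:
        base = np.ones(sp.n_cells)
        if colonised_this_step and sp.species_id in colonised_this_step:
            new = np.isin(sp.cells, colonised_this_step[sp.species_id])
            base[new] = params.initial_abundance
        delta = sp.thermal_optimum - temp[sp.cells]
        sp.abundance = base * np.exp(-(delta**2) / (2.0 * THERMAL_SD**2))

    # competition within cells shared by several species (simultaneous update)
    if len(extant) > 1:
        sp_idx = np.concatenate([np.full(s.n_cells, i) for i, s in enumerate(extant)])
        cell = np.concatenate([s.cells for s in extant])
        ab = np.concatenate([s.abundance for s in extant])
        niche = np.concatenate([s.competitive_niche for s in extant])
        local = np.concatenate([np.arange(s.n_cells) for s in extant])
        order = np.argsort(cell, kind="stable")
        cell_s = cell[order]
        bounds = np.flatnonzero(np.diff(cell_s)) + 1
        groups = np.split(order, bounds)
        for g in groups:
            if g.size < 2:
                continue
            a_g = ab[g]
            n_g = niche[g]
            overlap = np.maximum(0.0, 2.0 * w - np.abs(n_g[:, None] - n_g[None, :]))
            np.fill_diagonal(overlap, 0.0)
            load = (overlap @ a_g) / (2.0 * w)
            factor = 1.0 - np.minimum(load, 1.0)
            for m, f in zip(g, factor):
                extant[sp_idx[m]].abundance[local[m]] *= f

    for sp in extant:
        outside = np.maximum(0.0, w - sp.competitive_niche) + np.maximum(
            0.0, sp.competitive_niche + w - 1.0
        )
        sp.abundance = sp.abundance * np.maximum(0.0, 1.0 - outside / (2.0 * w))
        keep = sp.abundance >= ABUNDANCE_FLOOR
        if not keep.all():
            sp.keep_cells(keep)
        if sp.n_cells == 0:
            sp.extinction_time = t
            log.record_extinction(t, sp.species_id)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _remove_uninhabitable(
    states: list[SpeciesState],
    landscape: Landscape,
    frame: int,
    log: PhylogenyEventLog,
    t: int,
) -> None:
    hab = landscape.habitable[frame].ravel()
    for sp in states:
        if not sp.is_extant or sp.n_cells == 0:
            continue
        keep = hab[sp.cells]
        if not keep.all():
            sp.keep_cells(keep)
        if sp.n_cells == 0:
            sp.extinction_time = t
            log.record_extinction(t, sp.species_id)


def run_simulation(
    landscape: Landscape,
    params: SimulationParams,
    n_steps: int | None = None,
    observer: Callable[[int, list[SpeciesState], PhylogenyEventLog], None] | None = None,
) -> SimulationResult:
    """Run a full simulation; deterministic given (landscape, params, seed).

    ``n_steps`` defaults to ``landscape.n_timesteps - 1``; if it exceeds
    the number of landscape frames the last frame is reused (a static
    late world).  ``observer``, if given, is called after every
    speciation step with ``(t, states, log)``.  Terminates early when
    all species are extinct.
    """
    if n_steps is None:
        n_steps = landscape.n_timesteps - 1
    rng = np.random.default_rng(params.seed)
    rho = params.speciation_threshold
    reach = dispersal_reach_99(params)

    log = PhylogenyEventLog()
    states = [seed_ancestor(landscape, params)]
    record: dict[int, set[tuple[int, int]]] = {}
    rows = []

    for t in range(1, n_steps + 1):
        frame = min(t, landscape.n_timesteps - 1)
        _remove_uninhabitable(states, landscape, frame, log, t)
        # recluster for the current coastline; carry the gene-flow record
        # of the previous step across the cluster renumbering
        remapped: dict[int, set[tuple[int, int]]] = {}
        for sp in states:
            if not (sp.is_extant and sp.n_cells):
                continue
            mapping = assign_clusters(sp, landscape, frame, reach)
            pairs = record.get(sp.species_id)
            if pairs:
                out: set[tuple[int, int]] = set()
                for i, j in pairs:
                    for a in mapping[i] if i < len(mapping) else ():
                        for b in mapping[j] if j < len(mapping) else ():
                            if a != b:
                                out.add((min(a, b), max(a, b)))
                remapped[sp.species_id] = out
        step_divergence_and_speciation(states, remapped, rho, log, t)
        if observer is not None:
            observer(t, states, log)

        pre_cells = {s.species_id: s.cells.copy() for s in states if s.is_extant}
        record = step_dispersal(states, landscape, frame, params, rng)
        colonised = {
            s.species_id: np.setdiff1d(s.cells, pre_cells[s.species_id])
            for s in states
            if s.is_extant and s.species_id in pre_cells
        }
        step_trait_evolution(states, params, rng)
        step_ecology(states, landscape, frame, params, log, t, colonised)

        extant = [s for s in states if s.is_extant]
        rows.append(
            {
                "t": t,
                "n_extant": len(extant),
                "n_created": log.n_created,
                "n_extinct": len(log.extinctions),
                "n_clusters": sum(s.n_clusters for s in extant),
                "n_occupied_cells": sum(s.n_cells for s in extant),
            }
        )
        if not extant:
            break

    # refresh cluster structure so final states reflect final occupancy
    final_frame = min(n_steps, landscape.n_timesteps - 1)
    for sp in states:
        if sp.is_extant and sp.n_cells:
            assign_clusters(sp, landscape, final_frame, reach)
    log.end_time = n_steps
    return SimulationResult(
        states=states,
        log=log,
        summaries=pd.DataFrame(rows),
        params=params,
        landscape=landscape,
    )
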