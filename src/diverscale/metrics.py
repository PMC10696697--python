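"""Multi-level diversity metrics: richness, PD, MPD, clade properties,
continuity across organisational levels, and bioregional beta-diversity.

Species-level metrics are read off the dated species tree; population-
level metrics are read off each species' cluster dendrogram and averaged
across species.  Continuity compares the two levels per simulation after
min-max normalising each constituent metric across the whole ensemble:

    continuity = log(normalised species diversity / normalised population diversity)

positive values mean relatively more species-level diversity.  Beta-
diversity is the mean pairwise Euclidean distance of a metric across
bioregions.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .engine import SimulationResult, SpeciesState
from .phylo import population_phylogeny, species_phylogeny

__all__ = [
    "diversity_metrics",
    "evolutionary_distinctiveness",
    "clade_properties",
    "continuity",
    "beta_diversity",
    "trait_summary",
    "compute_metrics_row",
]

FACETS = ("richness", "pd", "mpd")


# ---------------------------------------------------------------------------
# tree-based diversity
# ---------------------------------------------------------------------------

def diversity_metrics(tree: dendropy.Tree) -> dict[str, float]:
    """Richness, Faith's PD and MPD of a dated tree.

    PD is the sum of all branch lengths; MPD the mean patristic distance
    over unordered tip pairs (NaN for a single tip).
    """
    tips = tree.leaf_nodes()
    richness = len(tips)
    pd_val = float(tree.length())
    if richness < 2:
        return {"richness": richness, "pd": pd_val, "mpd": float("nan")}
    pdm = tree.phylogenetic_distance_matrix()
    dists = [
        pdm.patristic_distance(a.taxon, b.taxon)
        for a, b in itertools.combinations(tips, 2)
    ]
    return {"richness": richness, "pd": pd_val, "mpd": float(np.mean(dists))}


def evolutionary_distinctiveness(tree: dendropy.Tree) -> dict[str, float]:
    """Fair-proportions evolutionary distinctiveness per tip.

    Each edge's length is divided equally among its descendant tips and
    summed along each root-to-tip path.  ED sums to the total tree
    length across tips.
    """
    ed: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        node = leaf
        while node is not None:
            if node.edge.length:
                n_desc = sum(1 for _ in node.leaf_iter())
                total += node.edge.length / n_desc
            node = node.parent_node
        ed[leaf.taxon.label] = total
    return ed


# ---------------------------------------------------------------------------
# clade properties
# ---------------------------------------------------------------------------

def temporal_turnover(n_extant: int, n_extinct: int) -> float:
    """Extant / (extant + extinct); NaN when nothing was ever created."""
    total = n_extant + n_extinct
    return n_extant / total if total else float("nan")


def weighted_endemism(states: Sequence[SpeciesState], classical: bool = False) -> float:
    """Mean per-cell weighted endemism.

    By default a cell's weighted endemism is the number of species
    occupying it divided by the summed range sizes (occupied-cell
    counts) of those species; the mean is taken over occupied cells.
    ``classical=True`` uses the range-rarity form instead: the per-cell
    sum of 1/range over occupying species.
    """
    counts: dict[int, int] = {}
    range_sum: dict[int, float] = {}
    inv_sum: dict[int, float] = {}
    for sp in states:
        if not sp.is_extant:
            continue
        r = sp.n_cells
        for c in sp.cells:
            counts[c] = counts.get(c, 0) + 1
            range_sum[c] = range_sum.get(c, 0.0) + r
            inv_sum[c] = inv_sum.get(c, 0.0) + 1.0 / r
    if not counts:
        return float("nan")
    if classical:
        return float(np.mean(list(inv_sum.values())))
    return float(np.mean([counts[c] / range_sum[c] for c in counts]))


def clade_properties(result: SimulationResult) -> dict[str, float]:
    """Turnover, range size, richness per cell, endemism, diversification rate."""
    log = result.log
    extant = result.extant
    n_extant = len(extant)
    n_extinct = len(log.extinctions)
    props: dict[str, float] = {
        "n_extant": n_extant,
        "n_total": log.n_created,
        "turnover": temporal_turnover(n_extant, n_extinct),
    }
    if n_extant == 0:
        props.update(
            species_range=float("nan"),
            mean_cell_richness=float("nan"),
            weighted_endemism=float("nan"),
            diversification_rate=float("nan"),
        )
        return props
    props["species_range"] = float(np.mean([s.n_cells for s in extant]))
    occupied = np.concatenate([s.cells for s in extant])
    cells, richness_per_cell = np.unique(occupied, return_counts=True)
    props["mean_cell_richness"] = float(richness_per_cell.mean())
    props["weighted_endemism"] = weighted_endemism(result.states)
    tree = species_phylogeny(log, extant_only=True)
    ed = evolutionary_distinctiveness(tree)
    rates = [1.0 / v for v in ed.values() if v > 0]
    props["diversification_rate"] = float(np.mean(rates)) if rates else float("nan")
    return props


# ---------------------------------------------------------------------------
# continuity and beta diversity
# ---------------------------------------------------------------------------

def _minmax_normalise(values: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        raise ValueError(f"metric '{name}' has no finite values to normalise")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError(f"metric '{name}' is constant across the ensemble")
    out = (v - lo) / (hi - lo)
    # zeros would make the log-ratio infinite: lift them to half the
    # smallest positive normalised value, preserving order
    pos = out[np.isfinite(out) & (out > 0)]
    if pos.size:
        out[np.isfinite(out) & (out == 0)] = pos.min() / 2.0
    return out


def continuity(
    species_values: np.ndarray,
    population_values: np.ndarray,
    name: str = "metric",
) -> np.ndarray:
    """Cross-level continuity score per simulation.

    Both constituent metrics are min-max rescaled to [0, 1] across the
    ensemble, then the score is ``log(species / population)``.  Positive
    scores mean relatively more species-level diversity.  NaN inputs
    propagate; a constant metric raises ``ValueError`` naming it.
    """
    s = _minmax_normalise(np.asarray(species_values, float), f"species {name}")
    p = _minmax_normalise(np.asarray(population_values, float), f"population {name}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(s / p)


def beta_diversity(values: Sequence[float]) -> float:
    """Mean pairwise Euclidean distance among bioregion values.

    NaN entries (undefined in a region) are dropped; fewer than two
    defined regions yields NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    return float(np.mean([abs(a - b) for a, b in itertools.combinations(v, 2)]))


# ---------------------------------------------------------------------------
# trait summaries
# ---------------------------------------------------------------------------

def trait_evenness(values: np.ndarray) -> float:
    """Regularity of nearest-neighbour spacing along the trait axis.

    1 for evenly spaced (or degenerate) values, approaching 0 as the
    values clump.  Computed as a normalised Camargo index on the sorted
    consecutive spacings.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3 or v[-1] == v[0]:
        return 1.0
    gaps = np.diff(v)
    p = gaps / gaps.sum()
    m = p.size
    dev = np.abs(p - 1.0 / m).sum()
    return float(1.0 - dev / (2.0 * (1.0 - 1.0 / m)))


def trait_diversity(values: np.ndarray) -> float:
    """Dispersion of trait values: mean absolute deviation about the mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return float("nan")
    return float(np.mean(np.abs(v - v.mean())))


def trait_summary(values: Sequence[float]) -> dict[str, float]:
    """Mean, min, max, range, evenness and diversity of a trait sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {k: float("nan") for k in ("mean", "min", "max", "range", "evenness", "diversity")}
    return {
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "evenness": trait_evenness(v),
        "diversity": trait_diversity(v),
    }


# ---------------------------------------------------------------------------
# one row per simulation
# ---------------------------------------------------------------------------

def _population_level(species_divs: list[np.ndarray], method: str = "complete") -> dict[str, float]:
    """Mean dendrogram PD/MPD across species plus total cluster count.

    Single-cluster species contribute 0 to the PD mean and are excluded
    from the MPD mean.
    """
    if not species_divs:
        return {"richness": 0, "pd": float("nan"), "mpd": float("nan")}
    pds, mpds = [], []
    n_clusters = 0
    for D in species_divs:
        dend = population_phylogeny(D, method=method)
        n_clusters += dend.n
        pds.append(dend.pd())
        if dend.n >= 2:
            mpds.append(dend.mpd())
    return {
        "richness": n_clusters,
        "pd": float(np.mean(pds)),
        "mpd": float(np.mean(mpds)) if mpds else float("nan"),
    }


def _species_level(result: SimulationResult) -> dict[str, float]:
    if not result.extant:
        return {"richness": 0, "pd": float("nan"), "mpd": float("nan")}
    tree = species_phylogeny(result.log, extant_only=True)
    return diversity_metrics(tree)


def _regional_values(result: SimulationResult) -> dict[str, dict[str, float]]:
    """Per-bioregion species- and population-level diversity values."""
    world = result.landscape
    names = world.region_names
    region_of = world.bioregion.ravel()
    extant = result.extant
    out: dict[str, dict[str, float]] = {}

    full_tree = species_phylogeny(result.log, extant_only=True) if extant else None
    for r, name in enumerate(names):
        sp_here = [s for s in extant if np.any(region_of[s.cells] == r)]
        row: dict[str, float] = {}
        if sp_here:
            if len(sp_here) < len(extant):
                sub = full_tree.extract_tree_with_taxa_labels(
                    [f"s{s.species_id}" for s in sp_here]
                )
            else:
                sub = full_tree
            sp_div = diversity_metrics(sub)
            divs = []
            for s in sp_here:
                clusters = np.unique(s.cluster_of[region_of[s.cells] == r])
                divs.append(s.divergence[np.ix_(clusters, clusters)])
            pop_div = _population_level(divs)
        else:
            sp_div = {"richness": 0, "pd": float("nan"), "mpd": float("nan")}
            pop_div = {"richness": 0, "pd": float("nan"), "mpd": float("nan")}
        for facet in FACETS:
            row[f"species_{facet}"] = sp_div[facet]
            row[f"pop_{facet}"] = pop_div[facet]
        out[name] = row
    return out


def compute_metrics_row(result: SimulationResult, sim_id: int | None = None) -> dict[str, float]:
    """Collapse one simulation into a flat metrics record.

    Contains the parameter echo, species- and population-level global
    (gamma) diversity per facet, clade properties, trait summaries,
    per-bioregion diversity values, and per-facet/level beta-diversity.
    Continuity columns are added later at the ensemble level, where the
    cross-simulation normalisation is available.
    """
    row: dict[str, float] = {"sim_id": sim_id if sim_id is not None else 0}
    p = result.params
    row.update(
        initial_abundance=p.initial_abundance,
        thermal_optimum=p.thermal_optimum,
        dispersal_scale=p.dispersal_scale,
        speciation_threshold=p.speciation_threshold,
        mutation_sd=p.mutation_sd,
        niche_width=p.niche_width,
        seed=p.seed,
    )
    row.update(clade_properties(result))

    sp = _species_level(result)
    pop = _population_level([s.divergence for s in result.extant])
    for facet in FACETS:
        row[f"species_{facet}"] = sp[facet]
        row[f"pop_{facet}"] = pop[facet]
    row["total_clusters"] = pop["richness"]

    # trait values are homogenised within clusters: summarise one value
    # per cluster across all extant species
    therm, comp = [], []
    for s in result.extant:
        for k in range(s.n_clusters):
            mask = s.cluster_of == k
            if mask.any():
                therm.append(s.thermal_optimum[mask][0])
                comp.append(s.competitive_niche[mask][0])
    for trait, vals in (("thermal", therm), ("competitive", comp)):
        for stat, val in trait_summary(vals).items():
            row[f"{trait}_{stat}"] = val

    regional = _regional_values(result)
    for name, vals in regional.items():
        for key, v in vals.items():
            row[f"{key}__{name}"] = v
    for level in ("species", "pop"):
        for facet in FACETS:
            vals = [regional[name][f"{level}_{facet}"] for name in regional]
            row[f"beta_{level}_{facet}"] = beta_diversity(vals)
    return row


def add_continuity_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append continuity columns (one per facet) to a metrics table.

    Normalisation is ensemble-wide per metric and per level, so this can
    only be computed once all simulations of an ensemble are collected.
    Besides the gamma-level ``continuity_<facet>`` scores, a
    ``beta_continuity_<facet>`` column gives the mean pairwise distance
    of *regional* continuity values across bioregions (regional metrics
    are normalised pooling all regions of the ensemble); it complements
    the per-level ``beta_*`` columns computed per simulation.
    """
    out = df.copy()
    for facet in FACETS:
        out[f"continuity_{facet}"] = continuity(
            df[f"species_{facet}"].to_numpy(float),
            df[f"pop_{facet}"].to_numpy(float),
            name=facet,
        )
        regions = sorted(
            c.split("__", 1)[1] for c in df.columns if c.startswith(f"species_{facet}__")
        )
        if len(regions) < 2:
            continue
        sp = df[[f"species_{facet}__{r}" for r in regions]].to_numpy(float)
        pp = df[[f"pop_{facet}__{r}" for r in regions]].to_numpy(float)
        try:
            cont = continuity(sp.ravel(), pp.ravel(), name=facet).reshape(sp.shape)
        except ValueError:
            out[f"beta_continuity_{facet}"] = np.nan
            continue
        out[f"beta_continuity_{facet}"] = [beta_diversity(row) for row in cont]
    return out
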