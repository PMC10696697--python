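"""Dated species phylogenies and population dendrograms.

The engine emits a :class:`PhylogenyEventLog` — an ordered record of
speciation and extinction events.  This module turns that log into a
dated species tree (branch lengths in timesteps) and turns a species'
cluster-to-cluster divergence matrix into an ultrametric population
dendrogram, both serialisable to Newick.

Ultrametric convention: a merge at height ``h`` places the two leaves at
depth ``h / 2`` below the node, so the cophenetic (tip-to-tip) distance
equals the merge height — a two-population dendrogram at divergence
``d`` has total branch length ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SpeciationEvent",
    "ExtinctionEvent",
    "PhylogenyEventLog",
    "species_phylogeny",
    "PopulationDendrogram",
    "population_phylogeny",
]


@dataclass(frozen=True)
class SpeciationEvent:
    time: int
    parent_id: int
    child_id: int
    #: smallest divergence between the separating population groups at
    #: the moment of the split (always above the speciation threshold)
    min_cross_divergence: float = np.nan


@dataclass(frozen=True)
class ExtinctionEvent:
    time: int
    species_id: int


@dataclass
class PhylogenyEventLog:
    """Ordered speciation/extinction events of one simulation."""

    speciations: list[SpeciationEvent] = field(default_factory=list)
    extinctions: list[ExtinctionEvent] = field(default_factory=list)
    root_id: int = 0
    end_time: int = 0
    _next_id: int = 1

    def next_species_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def record_speciation(
        self, time: int, parent_id: int, child_id: int, min_cross_divergence: float = np.nan
    ) -> None:
        self.speciations.append(
            SpeciationEvent(time, parent_id, child_id, min_cross_divergence)
        )

    def record_extinction(self, time: int, species_id: int) -> None:
        self.extinctions.append(ExtinctionEvent(time, species_id))

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_created(self) -> int:
        return 1 + len(self.speciations)

    @property
    def extinct_ids(self) -> set[int]:
        return {e.species_id for e in self.extinctions}

    @property
    def created_ids(self) -> list[int]:
        return [self.root_id] + [e.child_id for e in self.speciations]

    @property
    def extant_ids(self) -> list[int]:
        dead = self.extinct_ids
        return [s for s in self.created_ids if s not in dead]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"event": "speciation", "time": e.time, "species_id": e.child_id, "parent_id": e.parent_id}
            for e in self.speciations
        ] + [
            {"event": "extinction", "time": e.time, "species_id": e.species_id, "parent_id": None}
            for e in self.extinctions
        ]
        df = pd.DataFrame(rows, columns=["event", "time", "species_id", "parent_id"])
        return df.sort_values(["time", "event"], kind="stable").reset_index(drop=True)

    def validate(self) -> None:
        """Check internal consistency of the event record."""
        seen = {self.root_id}
        for e in self.speciations:
            if e.parent_id not in seen:
                raise ValueError(f"parent {e.parent_id} speciates before existing")
            if e.child_id in seen:
                raise ValueError(f"duplicate species id {e.child_id}")
            seen.add(e.child_id)
        if len(self.extinct_ids) != len(self.extinctions):
            raise ValueError("species recorded extinct more than once")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def species_phylogeny(
    log: PhylogenyEventLog,
    extant_only: bool = False,
    date_by: str = "event",
) -> dendropy.Tree:
    """Build the dated species tree from the event log.

    Each speciation event creates a split; tips extend to the species'
    extinction time or, for extant species, to the simulation end time.
    The root carries a stem edge from time 0 to the first split, so a
    no-speciation run yields a single tip whose branch length equals the
    simulation duration.  Taxon labels are ``s<species_id>``.

    ``date_by`` selects the split-dating convention: ``"event"`` (the
    default) places the split at the speciation event's timestep;
    ``"divergence"`` back-dates it by the divergence the separating
    populations had accrued, so the diversity held between populations
    before the split is carried into the species tree (total summed
    branch length across the two levels is then conserved through a
    speciation event).
    """
    if date_by not in ("event", "divergence"):
        raise ValueError("date_by must be 'event' or 'divergence'")
    log.validate()
    if log.n_created < 1:  # pragma: no cover - log always has a root
        raise ValueError("empty event log")
    extinct_at = {e.species_id: e.time for e in log.extinctions}
    if extant_only and not log.extant_ids:
        raise ValueError("no extant species to build a tree from")

    by_parent: dict[int, list[SpeciationEvent]] = {}
    for e in sorted(log.speciations, key=lambda e: (e.time, e.child_id)):
        by_parent.setdefault(e.parent_id, []).append(e)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    end = log.end_time

    # iterative construction; node ``time`` attribute dates each node
    tree.seed_node.time = 0.0
    stack: list[tuple[dendropy.Node, int, float, int]] = []

    def open_segment(parent_node, s, start, idx):
        stack.append((parent_node, s, start, idx))

    # the seed node is the start of the root species' stem
    root_node = tree.seed_node
    open_segment(root_node, log.root_id, 0.0, 0)

    while stack:
        parent_node, s, start, idx = stack.pop()
        evs = by_parent.get(s, [])
        if idx < len(evs):
            e = evs[idx]
            split_time = float(e.time)
            if date_by == "divergence" and np.isfinite(e.min_cross_divergence):
                split_time = max(start, float(e.time) - float(e.min_cross_divergence))
            node = dendropy.Node()
            node.time = split_time
            parent_node.add_child(node)
            node.edge.length = split_time - start
            open_segment(node, s, split_time, idx + 1)
            open_segment(node, e.child_id, split_time, 0)
        else:
            tip_time = float(extinct_at.get(s, end))
            leaf = dendropy.Node()
            leaf.time = tip_time
            leaf.taxon = tns.new_taxon(label=f"s{s}")
            parent_node.add_child(leaf)
            leaf.edge.length = tip_time - start

    # the seed node has exactly one child (the stem); lift it to the root
    stem = tree.seed_node.child_nodes()[0]
    stem.parent_node = None
    tree.seed_node = stem

    if extant_only:
        keep = {f"s{s}" for s in log.extant_ids}
        taxa = [t for t in tns if t.label in keep]
        tree.retain_taxa(taxa, suppress_unifurcations=True)
    return tree


# ---------------------------------------------------------------------------
# population dendrogram
# ---------------------------------------------------------------------------

class PopulationDendrogram:
    """Ultrametric dendrogram over the geographic clusters of one species.

    Built by agglomerative clustering of the symmetric, non-negative
    cluster-to-cluster divergence matrix (complete linkage by default).
    A single-cluster species yields a degenerate one-leaf dendrogram
    with total branch length 0 and undefined mean pairwise distance.
    """

    def __init__(self, divergence: np.ndarray, method: str = "complete"):
        D = np.asarray(divergence, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("divergence matrix must be square")
        if np.any(D < 0):
            raise ValueError("divergence matrix must be non-negative")
        if not np.allclose(D, D.T):
            raise ValueError("divergence matrix must be symmetric")
        self.n = D.shape[0]
        self.method = method
        if self.n > 1:
            self.linkage = linkage(squareform(D, checks=False), method=method)
        else:
            self.linkage = np.zeros((0, 4))

    def pd(self) -> float:
        """Total branch length (Faith's PD of the dendrogram)."""
        if self.n < 2:
            return 0.0
        heights = np.zeros(self.n + self.linkage.shape[0])
        heights[self.n:] = self.linkage[:, 2]
        total = 0.0
        for k, (a, b, h, _) in enumerate(self.linkage):
            total += (h - heights[int(a)]) / 2.0 + (h - heights[int(b)]) / 2.0
        return float(total)

    def mpd(self) -> float:
        """Mean cophenetic (tip-to-tip) distance; NaN for a single leaf."""
        if self.n < 2:
            return float("nan")
        return float(cophenet(self.linkage).mean())

    def cophenetic_matrix(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros((self.n, self.n))
        return squareform(cophenet(self.linkage))

    def to_newick(self, labels: list[str] | None = None) -> str:
        if labels is None:
            labels = [f"c{i}" for i in range(self.n)]
        if self.n == 1:
            return f"{labels[0]}:0.0;"
        heights = np.zeros(self.n + self.linkage.shape[0])
        heights[self.n:] = self.linkage[:, 2]

        def render(i: int) -> str:
            if i < self.n:
                return labels[i]
            a, b, h, _ = self.linkage[i - self.n]
            la = f"{render(int(a))}:{(h - heights[int(a)]) / 2.0:.10g}"
            lb = f"{render(int(b))}:{(h - heights[int(b)]) / 2.0:.10g}"
            return f"({la},{lb})"

        return render(self.n + self.linkage.shape[0] - 1) + ";"

    def to_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")


def population_phylogeny(divergence: np.ndarray, method: str = "complete") -> PopulationDendrogram:
    """Agglomerative dendrogram over a species' geographic clusters."""
    return PopulationDendrogram(divergence, method=method)
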