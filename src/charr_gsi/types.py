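"""Core in-memory containers for genetic stock identification.

The universal substrate is :class:`GenotypeTable` — diploid multilocus
genotypes with collection (river) and reporting-unit labels.  All GSI
likelihoods reduce to the per-group allele-count tensor
:class:`AlleleCounts`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing allele slot
MISSING = -1

REFERENCE = "reference"
MIXTURE = "mixture"


class ParseError(ValueError):
    """Malformed on-disk input (line-level problem)."""


class FormatError(ValueError):
    """Input violates a structural convention of the format."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with sample metadata.

    Parameters
    ----------
    individual_id, collection, reporting_unit, sample_type
        Per-individual metadata arrays.  ``reporting_unit`` may equal
        ``collection``; mixture individuals carry an empty reporting unit.
    locus_ids
        Ordered locus names.
    genotypes
        Integer array of shape ``(n, L, 2)``; allele codes are opaque
        non-negative integers, :data:`MISSING` marks an empty slot.  Pairs
        are stored unordered (canonicalised ascending), and a genotype is
        either fully present or fully missing.
    """

    individual_id: np.ndarray
    collection: np.ndarray
    reporting_unit: np.ndarray
    sample_type: np.ndarray
    locus_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.collection = np.asarray(self.collection, dtype=object)
        self.reporting_unit = np.asarray(self.reporting_unit, dtype=object)
        self.sample_type = np.asarray(self.sample_type, dtype=object)
        self.locus_ids = list(self.locus_ids)
        g = np.asarray(self.genotypes, dtype=np.int64)
        if g.ndim != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, L, 2)")
        if g.shape[0] != len(self.individual_id):
            raise ValueError("genotype rows do not match individual ids")
        if g.shape[1] != len(self.locus_ids):
            raise ValueError("genotype columns do not match locus ids")
        n_missing = (g == MISSING).sum(axis=2)
        if np.any(n_missing == 1):
            bad = np.argwhere(n_missing == 1)[0]
            raise ValueError(
                f"half-called genotype for individual "
                f"{self.individual_id[bad[0]]!r} at locus {self.locus_ids[bad[1]]!r}"
            )
        # canonical unordered storage
        self.genotypes = np.sort(g, axis=2)
        bad_types = set(self.sample_type) - {REFERENCE, MIXTURE}
        if bad_types:
            raise ValueError(f"unknown sample_type values: {sorted(bad_types)}")
        # every collection maps to exactly one reporting unit (reference rows)
        ref = self.sample_type == REFERENCE
        mapping: dict[str, str] = {}
        for c, u in zip(self.collection[ref], self.reporting_unit[ref]):
            if c in mapping and mapping[c] != u:
                raise ValueError(f"collection {c!r} maps to multiple reporting units")
            mapping[c] = u

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def collections(self) -> list[str]:
        """Collection labels in order of first appearance."""
        return list(dict.fromkeys(self.collection))

    def reporting_units(self) -> list[str]:
        """Reporting-unit labels in order of first appearance (reference rows)."""
        ref = self.sample_type == REFERENCE
        return list(dict.fromkeys(self.reporting_unit[ref]))

    def unit_of(self) -> dict[str, str]:
        """Collection -> reporting-unit mapping from reference rows."""
        ref = self.sample_type == REFERENCE
        return dict(zip(self.collection[ref], self.reporting_unit[ref]))

    # -- subsetting -----------------------------------------------------
    def subset(self, rows) -> "GenotypeTable":
        rows = np.asarray(rows)
        return GenotypeTable(
            self.individual_id[rows],
            self.collection[rows],
            self.reporting_unit[rows],
            self.sample_type[rows],
            self.locus_ids,
            self.genotypes[rows],
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        idx = [pos[l] for l in loci]
        return GenotypeTable(
            self.individual_id,
            self.collection,
            self.reporting_unit,
            self.sample_type,
            list(loci),
            self.genotypes[:, idx, :],
        )

    def with_units(self, mapping: dict[str, str]) -> "GenotypeTable":
        """Relabel reporting units of reference rows via ``mapping``."""
        units = self.reporting_unit.copy()
        ref = self.sample_type == REFERENCE
        units[ref] = [mapping.get(c, u) for c, u in
                      zip(self.collection[ref], self.reporting_unit[ref])]
        return GenotypeTable(self.individual_id, self.collection, units,
                             self.sample_type, self.locus_ids, self.genotypes)

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            list(self.individual_id) == list(other.individual_id)
            and list(self.collection) == list(other.collection)
            and list(self.reporting_unit) == list(other.reporting_unit)
            and list(self.sample_type) == list(other.sample_type)
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )

    @staticmethod
    def concat(tables: Iterable["GenotypeTable"]) -> "GenotypeTable":
        tables = list(tables)
        loci = tables[0].locus_ids
        for t in tables[1:]:
            if t.locus_ids != loci:
                raise ValueError("cannot concatenate tables with different loci")
        return GenotypeTable(
            np.concatenate([t.individual_id for t in tables]),
            np.concatenate([t.collection for t in tables]),
            np.concatenate([t.reporting_unit for t in tables]),
            np.concatenate([t.sample_type for t in tables]),
            loci,
            np.concatenate([t.genotypes for t in tables], axis=0),
        )


@dataclass
class AlleleCounts:
    """Per-group, per-locus allele counts: the GSI sufficient statistic.

    ``counts[l][g, a]`` is the number of copies of allele ``alleles[l][a]``
    observed at locus ``l`` in group ``g``; ``n[g, l]`` is the total number
    of allele copies (2 x non-missing individuals).
    """

    groups: list[str]
    loci: list[str]
    alleles: list[np.ndarray]          # per locus, sorted allele codes
    counts: list[np.ndarray]           # per locus, (G, A_l)
    n: np.ndarray                      # (G, L)

    def __post_init__(self) -> None:
        for l, (al, y) in enumerate(zip(self.alleles, self.counts)):
            if y.shape != (len(self.groups), len(al)):
                raise ValueError(f"count block shape mismatch at locus {l}")
            if not np.allclose(y.sum(axis=1), self.n[:, l]):
                raise ValueError(f"counts do not sum to totals at locus {self.loci[l]}")

    def freqs(self, l: int) -> np.ndarray:
        """Allele frequencies at locus ``l`` (rows with n=0 give NaN)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts[l] / self.n[:, [l]]

    def group_index(self, group: str) -> int:
        return self.groups.index(group)

    def subset_loci(self, idx: Sequence[int]) -> "AlleleCounts":
        return AlleleCounts(
            self.groups,
            [self.loci[i] for i in idx],
            [self.alleles[i] for i in idx],
            [self.counts[i] for i in idx],
            self.n[:, list(idx)],
        )

    def aggregate(self, mapping: dict[str, str]) -> "AlleleCounts":
        """Pool groups according to ``mapping`` (group -> supergroup)."""
        new_groups = list(dict.fromkeys(mapping[g] for g in self.groups))
        pos = {g: i for i, g in enumerate(new_groups)}
        rows = np.array([pos[mapping[g]] for g in self.groups])
        counts = []
        n = np.zeros((len(new_groups), len(self.loci)))
        for l in range(len(self.loci)):
            y = np.zeros((len(new_groups), len(self.alleles[l])))
            np.add.at(y, rows, self.counts[l])
            counts.append(y)
        np.add.at(n, rows, self.n)
        return AlleleCounts(new_groups, self.loci, self.alleles, counts, n)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over labelled groups."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


class TreeNode:
    """Node of an unrooted tree (represented with a degree-3 pseudo-root).

    ``length`` is the branch to the parent (None at the root), ``support``
    a bootstrap percentage for the edge above, ``note`` records e.g. a
    negative NJ length clamped to zero.
    """

    __slots__ = ("name", "length", "children", "support", "note")

    def __init__(self, name=None, length=None, children=None, support=None, note=None):
        self.name = name
        self.length = length
        self.children = children if children is not None else []
        self.support = support
        self.note = note

    @property
    def is_leaf(self) -> bool:
        return not self.children

    # -- traversal ------------------------------------------------------
    def walk(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves()}

    # -- structure queries ----------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf splits, one per internal edge (canonical side)."""
        all_leaves = frozenset(self.leaf_names())
        out = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            out.add(_canonical_split(side, all_leaves))
        return out

    def cherries(self) -> list[tuple[str, str]]:
        """Leaf pairs attached to a common vertex."""
        pairs = []
        for node in self.walk():
            leaf_kids = sorted(c.name for c in node.children if c.is_leaf)
            for i in range(len(leaf_kids)):
                for j in range(i + 1, len(leaf_kids)):
                    pairs.append((leaf_kids[i], leaf_kids[j]))
        return pairs

    def leaf_distance(self, a: str, b: str) -> float:
        parent: dict[TreeNode, TreeNode] = {}
        nodes = {}
        for node in self.walk():
            for c in node.children:
                parent[c] = node
            if node.is_leaf:
                nodes[node.name] = node

        def path_up(n):
            out = [n]
            while n in parent:
                n = parent[n]
                out.append(n)
            return out

        pa, pb = path_up(nodes[a]), path_up(nodes[b])
        seen = {id(n): i for i, n in enumerate(pa)}
        for j, n in enumerate(pb):
            if id(n) in seen:
                i = seen[id(n)]
                return float(
                    sum(x.length or 0.0 for x in pa[:i]) +
                    sum(x.length or 0.0 for x in pb[:j])
                )
        raise ValueError("leaves not in the same tree")

    # -- serialisation --------------------------------------------------
    def to_newick(self) -> str:
        return _newick(self) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.to_newick()})"


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    a, b = sorted([side, other], key=lambda s: (len(s), sorted(s)))
    return a


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        label = node.name or ""
    else:
        inner = ",".join(_newick(c) for c in node.children)
        sup = "" if node.support is None else f"{node.support:g}"
        label = f"({inner}){sup}"
    if node.length is not None:
        label += f":{node.length:g}"
    return label


@dataclass
class Ordination:
    """Principal-coordinates result: coordinates plus the eigen-spectrum."""

    labels: list[str]
    coordinates: np.ndarray          # (n, k) positive axes only
    eigenvalues: np.ndarray          # all, sorted descending (may be negative)
    proportion_explained: np.ndarray  # over the positive eigenvalue sum

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


@dataclass
class AssignmentResult:
    """Per-individual scaled likelihoods over collections and units."""

    individual_id: np.ndarray
    group_label: np.ndarray            # origin fishery / input collection label
    true_collection: np.ndarray | None
    true_unit: np.ndarray | None
    collections: list[str]
    units: list[str]
    collection_probs: np.ndarray       # (n, C), rows sum to 1
    unit_probs: np.ndarray             # (n, U), rows sum to 1
    map_collection: np.ndarray
    map_unit: np.ndarray

    def subset(self, rows) -> "AssignmentResult":
        """Restrict to a boolean mask / index of individuals (e.g. holdout)."""
        rows = np.asarray(rows)
        return AssignmentResult(
            self.individual_id[rows], self.group_label[rows],
            None if self.true_collection is None else self.true_collection[rows],
            None if self.true_unit is None else self.true_unit[rows],
            self.collections, self.units,
            self.collection_probs[rows], self.unit_probs[rows],
            self.map_collection[rows], self.map_unit[rows],
        )

    def collection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.collection_probs, index=self.individual_id,
                            columns=self.collections)

    def unit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.unit_probs, index=self.individual_id,
                            columns=self.units)


@dataclass
class GroupMetrics:
    """Accuracy/efficiency per reporting unit plus unweighted panel means."""

    table: pd.DataFrame                # index unit: accuracy, efficiency, ...
    mean_accuracy: float
    mean_efficiency: float


@dataclass
class MixtureEstimate:
    """Posterior mixing proportions per reporting unit from the Gibbs chain."""

    units: list[str]
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    included_units: list[str]
    collections: list[str]
    collection_mean: np.ndarray
    individual_id: np.ndarray
    group_label: np.ndarray
    indiv_posterior: np.ndarray        # (n, C) mean origin posterior
    unit_trace: np.ndarray             # (kept sweeps, U)
    settings: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "ci_low": self.ci_low, "ci_high": self.ci_high,
             "included": [u in self.included_units for u in self.units]},
            index=self.units,
        )

    def indiv_unit_posterior(self) -> np.ndarray:
        unit_of = dict(zip(self.collections, self.settings["unit_of_collection"]))
        out = np.zeros((len(self.individual_id), len(self.units)))
        for j, c in enumerate(self.collections):
            out[:, self.units.index(unit_of[c])] += self.indiv_posterior[:, j]
        return out


@dataclass
class PanelSpec:
    """F_ST-ranked, LD-pruned marker panel with its train/holdout split."""

    ranked: pd.DataFrame               # locus, fst (descending)
    selected: list[str]
    panel_size: int
    train_ids: list[str]
    holdout_ids: list[str]
    seed: int


@dataclass
class ReportingGroupMap:
    """Collection -> reporting group mapping with replayable merge history."""

    mapping: dict[str, str]
    history: pd.DataFrame              # round, merged_groups, new_group, ...

    def n_groups(self) -> int:
        return len(set(self.mapping.values()))

    def replay(self, collections: Sequence[str]) -> dict[str, str]:
        """Re-apply the merge history from an identity map."""
        mapping = {c: c for c in collections}
        for _, row in self.history.iterrows():
            members = row["merged_groups"].split("|")
            new = row["new_group"]
            for c, g in mapping.items():
                if g in members:
                    mapping[c] = new
        return mapping


@dataclass
class SimReport:
    """Output of the power simulations (100% and flat-Dirichlet mixtures)."""

    per_replicate: pd.DataFrame
    aggregate: pd.DataFrame
    details: dict = field(default_factory=dict)


@dataclass
class CoastGrid:
    """Land/sea raster; sea cells form the least-cost graph.

    The grid is georeferenced by the latitude/longitude of the centre of the
    top-left cell; rows run north to south.  ``cell_km`` is the edge length
    of a cell in kilometres.
    """

    sea: np.ndarray                    # (rows, cols) bool, True = sea
    cell_km: float
    lat0: float = 0.0
    lon0: float = 0.0

    def __post_init__(self) -> None:
        self.sea = np.asarray(self.sea, dtype=bool)
        if self.sea.ndim != 2:
            raise ValueError("grid mask must be 2-D")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        if not self.sea.any():
            raise ValueError("grid has no sea cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sea.shape

    # local equirectangular scaling at the grid's mean latitude
    def _km_per_deg(self) -> tuple[float, float]:
        mean_lat = self.lat0 - (self.shape[0] - 1) / 2 * self.cell_km / 110.574
        return 110.574, 111.320 * float(np.cos(np.deg2rad(mean_lat)))

    def latlon_to_rowcol(self, lat: float, lon: float) -> tuple[float, float]:
        km_lat, km_lon = self._km_per_deg()
        row = (self.lat0 - lat) * km_lat / self.cell_km
        col = (lon - self.lon0) * km_lon / self.cell_km
        return row, col

    def rowcol_to_latlon(self, row: float, col: float) -> tuple[float, float]:
        km_lat, km_lon = self._km_per_deg()
        return (self.lat0 - row * self.cell_km / km_lat,
                self.lon0 + col * self.cell_km / km_lon)


@dataclass
class LeastCostResult:
    """Shortest through-water path between two sites."""

    site_a: str
    site_b: str
    distance_km: float
    path: list[tuple[int, int]] | None = None


@dataclass
class RegressionResult:
    """Simple OLS summary (slope, intercept, R^2, F-test p)."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


@dataclass
class MovementSummary:
    """Spatial summary of assignments or recaptures per fishery/stock."""

    counts: pd.DataFrame               # one row per (fishery/stock, origin)
    per_group: pd.DataFrame
    pooled_fraction: float | None = None
    pooled_fraction_excluded: float | None = None
    regression: RegressionResult | None = None
    details: dict = field(default_factory=dict)
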