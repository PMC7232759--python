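"""Allele frequencies, Weir-Cockerham F_ST, LD, genetic distances, NJ, PCoA.

Conventions fixed here:

* theta uses the two-level allele-based Weir & Cockerham (1984) ANOVA
  (populations / gametes) — genotypes are treated as random unions of
  gametes, so within-individual components are not estimated.  Multi-locus
  and pairwise values are ratios of summed variance components, never means
  of per-locus ratios.
* the chord (Cavalli-Sforza & Edwards) distance is
  D = sqrt((2/L) * sum_l (1 - cos theta_l)) with
  cos theta_l = sum_a sqrt(p1 * p2); packages differ by constant factors,
  which do not affect NJ topology.
* LD is the squared Pearson correlation of allele dosages (composite
  genotypic LD; no phasing).
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import (MISSING, AlleleCounts, DistanceMatrix, GenotypeTable,
                    Ordination, TreeNode)

log = logging.getLogger(__name__)

__all__ = [
    "allele_counts", "wc_fst", "ld_rsq", "dosage_matrix", "chord_distance",
    "nei_distance", "neighbor_joining", "bootstrap_tree", "pcoa",
    "filter_snps",
]


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def allele_counts(table: GenotypeTable, grouping: str = "collection") -> AlleleCounts:
    """Tally allele copies per group and locus.

    Missing genotypes are excluded; a locus with no calls in any group is
    dropped with a warning.  The allele registry at each locus is the union
    over all groups, sorted by code.
    """
    if table.n_individuals == 0:
        raise ValueError("empty genotype table")
    if grouping == "collection":
        labels = table.collection
    elif grouping == "reporting_unit":
        labels = table.reporting_unit
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = list(dict.fromkeys(labels))
    gidx = np.array([groups.index(l) for l in labels])

    loci, alleles, counts = [], [], []
    n_cols = []
    for j, locus in enumerate(table.locus_ids):
        g = table.genotypes[:, j, :]
        present = g[:, 0] != MISSING
        if not present.any():
            warnings.warn(f"locus {locus!r} has no calls in any group; dropped")
            log.warning("dropping all-missing locus %s", locus)
            continue
        codes = np.unique(g[present])
        pos = {c: k for k, c in enumerate(codes)}
        y = np.zeros((len(groups), len(codes)))
        rows = np.repeat(gidx[present], 2)
        cols = np.array([pos[c] for c in g[present].ravel()])
        np.add.at(y, (rows, cols), 1.0)
        loci.append(locus)
        alleles.append(codes.astype(np.int64))
        counts.append(y)
        n_cols.append(y.sum(axis=1))
    if not loci:
        raise ValueError("all loci are entirely missing")
    n = np.column_stack(n_cols)
    return AlleleCounts(groups, loci, alleles, counts, n)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _theta_components(counts: AlleleCounts, rows: np.ndarray, l: int):
    """Summed (among, among+within) variance components at locus ``l``."""
    n = counts.n[rows, l]
    keep = n > 0
    n = n[keep]
    r = len(n)
    if r < 2:
        return 0.0, 0.0
    y = counts.counts[l][rows][keep]
    p = y / n[:, None]
    N = n.sum()
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    pbar = y.sum(axis=0) / N
    msp = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = ((n[:, None] * p * (1 - p)).sum(axis=0) / (N - r)) if N > r else \
        np.zeros_like(pbar)
    a = (msp - msg) / nc
    return float(a.sum()), float((a + msg).sum())


def wc_fst(counts: AlleleCounts, scope: str = "global"):
    """Weir & Cockerham (1984) theta.

    ``scope``:

    * ``"per_locus"`` — Series of theta_l (ratio of summed per-allele
      components at that locus); monomorphic loci give NaN.
    * ``"global"`` — single ratio-of-sums over all loci.
    * ``"pairwise"`` — DataFrame of two-collection theta, ratio-of-sums
      over loci for each pair.

    Values may be slightly negative; they are not clamped.
    """
    rows = np.arange(len(counts.groups))
    if scope == "per_locus":
        out = {}
        for l, locus in enumerate(counts.loci):
            num, den = _theta_components(counts, rows, l)
            out[locus] = num / den if den > 0 else np.nan
        return pd.Series(out, name="theta")
    if scope == "global":
        num = den = 0.0
        for l in range(len(counts.loci)):
            a, d = _theta_components(counts, rows, l)
            num += a
            den += d
        return num / den if den > 0 else np.nan
    if scope == "pairwise":
        G = len(counts.groups)
        mat = np.zeros((G, G))
        for i in range(G):
            for j in range(i + 1, G):
                pair = np.array([i, j])
                num = den = 0.0
                for l in range(len(counts.loci)):
                    a, d = _theta_components(counts, pair, l)
                    num += a
                    den += d
                mat[i, j] = mat[j, i] = num / den if den > 0 else np.nan
        return pd.DataFrame(mat, index=counts.groups, columns=counts.groups)
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def dosage_matrix(table: GenotypeTable) -> np.ndarray:
    """(n, L) dosage of the highest-coded allele at each biallelic locus.

    Missing genotypes give NaN; loci with more than two alleles raise.
    """
    n, L = table.n_individuals, table.n_loci
    out = np.full((n, L), np.nan)
    for j, locus in enumerate(table.locus_ids):
        g = table.genotypes[:, j, :]
        present = g[:, 0] != MISSING
        codes = np.unique(g[present])
        if len(codes) > 2:
            raise ValueError(f"locus {locus!r} is not biallelic ({len(codes)} alleles)")
        ref = codes.max() if len(codes) else 0
        out[present, j] = (g[present] == ref).sum(axis=1)
    return out


def ld_rsq(table: GenotypeTable, locus_i: str, locus_j: str) -> float:
    """Composite genotypic LD: squared dosage correlation in [0, 1]."""
    sub = table.subset_loci([locus_i, locus_j])
    dos = dosage_matrix(sub)
    complete = ~np.isnan(dos).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("fewer than 2 individuals complete at both loci")
    x, y = dos[complete, 0], dos[complete, 1]
    if x.std() == 0 or y.std() == 0:
        warnings.warn(f"monomorphic locus in ld_rsq({locus_i!r}, {locus_j!r}); r2=0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------

def _check_informative(counts: AlleleCounts) -> None:
    dead = [g for k, g in enumerate(counts.groups) if counts.n[k].sum() == 0]
    if dead:
        warnings.warn(f"groups with no data excluded from distances: {dead}")


def _freq_stacks(counts: AlleleCounts):
    """Per-locus (G, G) cross-product stacks for the distance formulas.

    Returns ``cos`` (chord cosines), ``jxy`` (Nei cross-homozygosity, with
    diagonal = within-group J), and ``valid`` pair masks (both groups have
    data at the locus).
    """
    G, L = counts.n.shape
    cos = np.empty((L, G, G))
    jxy = np.empty((L, G, G))
    valid = np.empty((L, G, G), dtype=bool)
    for l in range(L):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts.counts[l] / counts.n[:, [l]]
        ok = counts.n[:, l] > 0
        p = np.nan_to_num(p)
        s = np.sqrt(p)
        cos[l] = np.minimum(s @ s.T, 1.0)
        jxy[l] = p @ p.T
        valid[l] = np.outer(ok, ok)
    return cos, jxy, valid


def _chord_from_stacks(cos, valid, loci_idx, labels) -> DistanceMatrix:
    c, v = cos[loci_idx], valid[loci_idx]
    L_used = v.sum(axis=0)
    deficit = np.where(v, 1.0 - c, 0.0)
    deficit[deficit < 1e-12] = 0.0      # identical frequencies give exactly 0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(2.0 * deficit.sum(axis=0) / L_used)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def _nei_from_stacks(jxy, valid, loci_idx, labels) -> DistanceMatrix:
    j, v = jxy[loci_idx], valid[loci_idx]
    L_used = v.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jbar = np.where(v, j, 0.0).sum(axis=0) / L_used
        diag = np.diag(jbar)
        d = -np.log(jbar / np.sqrt(np.outer(diag, diag)))
    d[np.isneginf(d)] = np.inf
    if np.isinf(d).any():
        warnings.warn("pairs with no shared alleles: Nei distance infinite")
    d = np.where(np.isinf(d), np.inf, np.maximum(d, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def chord_distance(counts: AlleleCounts) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance, D = sqrt((2/L) sum(1-cos)).

    cos theta_l = sum_a sqrt(p1 p2); loci where either group lacks data are
    skipped pair-wise.
    """
    _check_informative(counts)
    cos, _, valid = _freq_stacks(counts)
    return _chord_from_stacks(cos, valid, np.arange(len(counts.loci)),
                              counts.groups)


def nei_distance(counts: AlleleCounts) -> DistanceMatrix:
    """Nei (1972) standard distance D = -ln(J12 / sqrt(J1 J2)).

    J terms are averaged over loci; pairs sharing no alleles anywhere get
    +inf.
    """
    _check_informative(counts)
    _, jxy, valid = _freq_stacks(counts)
    return _nei_from_stacks(jxy, valid, np.arange(len(counts.loci)),
                            counts.groups)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Ties in the Q criterion are broken by the lowest (i, j) index pair.
    Negative branch-length estimates are clamped to zero and noted on the
    node.  On an additive matrix, leaf path lengths reproduce D exactly.
    """
    m = len(D.labels)
    if m < 3:
        raise ValueError("neighbour joining needs at least 3 labels")
    nodes = [TreeNode(name=l) for l in D.labels]
    d = D.values.astype(float).copy()
    active = list(range(m))

    def _set_len(node: TreeNode, length: float) -> None:
        if length < 0:
            node.note = f"negative NJ length {length:.6g} clamped to 0"
            length = 0.0
        node.length = float(length)

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (k - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)                       # first minimum = lowest (i, j)
        ii, jj = divmod(flat, k)
        if ii > jj:
            ii, jj = jj, ii
        dij = sub[ii, jj]
        li = 0.5 * dij + (R[ii] - R[jj]) / (2 * (k - 2))
        lj = dij - li
        ni, nj = nodes[active[ii]], nodes[active[jj]]
        _set_len(ni, li)
        _set_len(nj, lj)
        parent = TreeNode(children=[ni, nj])
        new_d = 0.5 * (sub[ii, :] + sub[jj, :] - dij)
        gi, gj = active[ii], active[jj]
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for pos, g in enumerate(active):
            d[g, -1] = d[-1, g] = new_d[pos]
        d[-1, -1] = 0.0
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for node, length in zip(root.children, (la, lb, lc)):
        _set_len(node, length)
    return root


def bootstrap_tree(table: GenotypeTable, distance: str = "chord",
                   replicates: int = 1000, seed: int = 0,
                   grouping: str = "collection") -> TreeNode:
    """Point-estimate NJ tree with locus-bootstrap support percentages.

    Loci are resampled with replacement; supports are the percentage of
    replicates whose tree contains each internal bipartition of the
    point-estimate tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if distance not in ("chord", "nei"):
        raise ValueError(f"unknown distance {distance!r}")
    counts = allele_counts(table, grouping)
    L = len(counts.loci)
    if L < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    cos, jxy, valid = _freq_stacks(counts)

    def dist_for(idx):
        if distance == "chord":
            return _chord_from_stacks(cos, valid, idx, counts.groups)
        return _nei_from_stacks(jxy, valid, idx, counts.groups)

    tree = neighbor_joining(dist_for(np.arange(L)))
    want = {split: 0 for split in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        rep_tree = neighbor_joining(dist_for(idx))
        found = rep_tree.bipartitions()
        for split in want:
            if split in found:
                want[split] += 1
    all_leaves = frozenset(l.name for l in tree.leaves())
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        split = frozenset(node.leaf_names())
        key = min([split, all_leaves - split], key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * want[key] / replicates
    return tree


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(D: DistanceMatrix) -> Ordination:
    """Principal coordinates: Gower-centre -D^2/2, eigendecompose.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axes with
    non-positive eigenvalues are dropped but the full spectrum is reported.
    """
    if len(D.labels) < 2:
        raise ValueError("PCoA needs at least 2 labels")
    A = -0.5 * D.values ** 2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = np.where(pos, eigval / pos_sum, 0.0) if pos_sum > 0 else \
        np.zeros_like(eigval)
    return Ordination(D.labels, coords, eigval, prop)


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

def filter_snps(table: GenotypeTable, maf_min: float = 0.01,
                missing_max: float = 0.05) -> GenotypeTable:
    """Keep biallelic loci with pooled MAF >= maf_min and missing <= missing_max."""
    keep = []
    for j, locus in enumerate(table.locus_ids):
        g = table.genotypes[:, j, :]
        present = g[:, 0] != MISSING
        miss_frac = 1.0 - present.mean()
        codes, freq = np.unique(g[present], return_counts=True)
        if len(codes) > 2:
            raise ValueError(f"locus {locus!r} is not biallelic")
        maf = 0.0 if len(codes) < 2 else freq.min() / freq.sum()
        if maf >= maf_min and miss_frac <= missing_max:
            keep.append(locus)
    log.info("filter_snps: kept %d / %d loci", len(keep), table.n_loci)
    return table.subset_loci(keep)
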