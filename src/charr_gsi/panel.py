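"""Marker-panel construction and iterative reporting-group revision.

Panel selection ranks biallelic loci by global F_ST computed on a
stratified training subset, then greedily admits loci whose dosage r^2
with every already-selected locus stays at or below the LD ceiling.
Reporting-group collapse merges a low-accuracy group with a partner that
is both its sister (cherry) in the current NJ tree and within a least-cost
shore distance gate, re-running self-assignment between merges.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .gsi import accuracy_efficiency, self_assign_loo
from .popgen import allele_counts, chord_distance, dosage_matrix, neighbor_joining, wc_fst
from .spatial import least_cost_matrix
from .types import (CoastGrid, GenotypeTable, PanelSpec, REFERENCE,
                    ReportingGroupMap, TreeNode)

log = logging.getLogger(__name__)

__all__ = ["select_top_loci", "collapse_reporting_groups"]


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------

def stratified_split(table: GenotypeTable, train_frac: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-collection split; returns boolean (train, holdout) masks."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train = np.zeros(table.n_individuals, dtype=bool)
    for c in table.collections():
        rows = np.flatnonzero(table.collection == c)
        k = max(1, int(round(train_frac * len(rows))))
        train[rng.choice(rows, size=k, replace=False)] = True
    return train, ~train


def _masked_rsq(x: np.ndarray, S: np.ndarray) -> np.ndarray:
    """r^2 of dosage vector ``x`` against each column of ``S`` (pairwise
    complete observations); NaN-dosage aware and fully vectorised."""
    Mx = ~np.isnan(x)
    M = ~np.isnan(S) & Mx[:, None]               # (n, k) valid pairs
    x0 = np.where(Mx, x, 0.0)
    S0 = np.nan_to_num(S)
    n = M.sum(axis=0).astype(float)
    sx = x0 @ M
    sy = (S0 * M).sum(axis=0)
    sxx = (x0 ** 2) @ M
    syy = (S0 ** 2 * M).sum(axis=0)
    sxy = x0 @ (S0 * M)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx ** 2 / n
        vy = syy - sy ** 2 / n
        r2 = cov ** 2 / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return np.minimum(r2, 1.0)


def select_top_loci(table: GenotypeTable, fst_min: float = 0.05,
                    ld_max: float = 0.2, train_frac: float = 0.33,
                    panel_size: int = 500, seed: int = 0) -> PanelSpec:
    """F_ST-ranked, LD-pruned panel from a stratified training subset.

    Loci with training-set global theta >= ``fst_min`` are ranked
    descending; a greedy scan admits each unless its dosage r^2 with any
    already-selected locus exceeds ``ld_max`` (computed on training
    individuals), stopping at ``panel_size`` or exhaustion.
    """
    train_mask, holdout_mask = stratified_split(table, train_frac, seed)
    train = table.subset(train_mask)
    counts = allele_counts(train, "collection")
    theta = wc_fst(counts, "per_locus")
    ranked = (theta.dropna().sort_values(ascending=False)
              .rename_axis("locus").reset_index(name="fst"))
    eligible = ranked[ranked["fst"] >= fst_min]
    if eligible.empty:
        warnings.warn("no loci pass the F_ST threshold; empty panel")
    dos = dosage_matrix(train)
    col_of = {l: j for j, l in enumerate(table.locus_ids)}
    selected: list[str] = []
    sel_cols: list[int] = []
    for locus in eligible["locus"]:
        if len(selected) >= panel_size:
            break
        j = col_of[locus]
        if sel_cols:
            r2 = _masked_rsq(dos[:, j], dos[:, sel_cols])
            if (r2 > ld_max).any():
                continue
        selected.append(locus)
        sel_cols.append(j)
    if len(selected) < panel_size:
        warnings.warn(
            f"only {len(selected)} eligible loci for panel_size={panel_size}")
    return PanelSpec(
        ranked, selected, panel_size,
        list(table.individual_id[train_mask]),
        list(table.individual_id[holdout_mask]), seed,
    )


# ---------------------------------------------------------------------------
# Reporting-group collapse
# ---------------------------------------------------------------------------

def _group_sites_distance(dmat: pd.DataFrame, members_a, members_b) -> float:
    return float(min(dmat.loc[a, b] for a in members_a for b in members_b))


def collapse_reporting_groups(baseline: GenotypeTable, sites: pd.DataFrame,
                              grid: CoastGrid, tree: TreeNode | None = None,
                              acc_min: float = 0.5, dist_max_km: float = 15.0,
                              prob_threshold: float = 0.5,
                              max_rounds: int = 30) -> ReportingGroupMap:
    """Iteratively merge low-accuracy reporting groups.

    Each round runs leave-one-out self-assignment, computes per-group
    accuracy at ``prob_threshold``, and looks for groups below
    ``acc_min``.  Starting from the lowest-accuracy one, a group is merged
    with a partner that (a) forms a cherry with it in the NJ tree built
    from the current grouping's chord distances and (b) lies within
    ``dist_max_km`` least-cost kilometres (minimum over member river
    sites).  One merge per round; metrics are rebuilt before the next.
    Stops when every group clears ``acc_min``, no eligible merge exists,
    or ``max_rounds`` is hit.  The returned history replays to the final
    map.
    """
    ref = baseline.subset(baseline.sample_type == REFERENCE)
    collections = ref.collections()
    missing_sites = set(collections) - set(sites["site_id"])
    if missing_sites:
        raise ValueError(f"collections without river sites: {sorted(missing_sites)}")
    river_sites = sites[sites["site_id"].isin(collections)].reset_index(drop=True)
    dmat = least_cost_matrix(grid, river_sites)

    mapping = {c: c for c in collections}
    history: list[dict] = []
    for round_no in range(1, max_rounds + 1):
        grouped = ref.with_units(mapping)
        result = self_assign_loo(grouped)
        metrics = accuracy_efficiency(result, prob_threshold)
        acc = metrics.table["accuracy"]
        low = acc[acc < acc_min].sort_values()
        if low.empty:
            log.info("collapse converged after %d rounds", round_no - 1)
            break
        groups = list(dict.fromkeys(mapping.values()))
        if len(groups) < 3:
            break
        if round_no == 1 and tree is not None:
            nj = tree
        else:
            counts = allele_counts(grouped, "reporting_unit")
            nj = neighbor_joining(chord_distance(counts))
        cherries = nj.cherries()
        members = {g: [c for c, gg in mapping.items() if gg == g]
                   for g in groups}
        merged = False
        for g in low.index:
            partners = [b if a == g else a for a, b in cherries if g in (a, b)]
            candidates = []
            for p in partners:
                d = _group_sites_distance(dmat, members[g], members[p])
                if d <= dist_max_km:
                    candidates.append((d, p))
            if not candidates:
                continue
            d, partner = sorted(candidates)[0]
            new_name = "+".join(sorted(set(
                members_name for pair in (g, partner)
                for members_name in pair.split("+"))))
            for c in members[g] + members[partner]:
                mapping[c] = new_name
            history.append({
                "round": round_no, "merged_groups": f"{g}|{partner}",
                "new_group": new_name,
                "trigger_accuracy": float(low[g]),
                "shore_distance_km": d, "nj_sister": True,
            })
            log.info("round %d: merged %s + %s (A=%.2f, d=%.1f km)",
                     round_no, g, partner, low[g], d)
            merged = True
            break
        if not merged:
            log.info("no eligible merge remains; stopping")
            break
    cols = ["round", "merged_groups", "new_group", "trigger_accuracy",
            "shore_distance_km", "nj_sister"]
    return ReportingGroupMap(mapping, pd.DataFrame(history, columns=cols))
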