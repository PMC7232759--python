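"""Least-cost marine distances and spatial movement summaries.

Distances run over the sea cells of a :class:`CoastGrid`: 8-connected,
with orthogonal steps costing ``cell_km`` and diagonal steps
``cell_km * sqrt(2)`` (the usual raster least-cost convention;
4-connectivity is available by flag).  Sites are snapped to the nearest
sea cell, ties broken row-major.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.stats import linregress

from .types import (AssignmentResult, CoastGrid, LeastCostResult,
                    MixtureEstimate, MovementSummary, RegressionResult)

log = logging.getLogger(__name__)

__all__ = [
    "snap_to_sea", "least_cost_distance", "least_cost_matrix",
    "assignment_geography", "drainage_regression", "tagging_analysis",
]


class GridConnectivityError(ValueError):
    """The two sites sit in different sea components."""


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _sea_graph(grid: CoastGrid, diagonal: bool = True):
    """Sparse weighted adjacency over sea cells; returns (graph, cell_index).

    ``cell_index`` maps (row, col) -> node id; -1 for land.
    """
    sea = grid.sea
    rows, cols = sea.shape
    index = np.full(sea.shape, -1, dtype=np.int64)
    index[sea] = np.arange(sea.sum())
    steps = [(0, 1, 1.0), (1, 0, 1.0)]
    if diagonal:
        steps += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    src, dst, w = [], [], []
    for dr, dc, cost in steps:
        a = index[max(0, -dr): rows - max(0, dr),
                  max(0, -dc): cols - max(0, dc)]
        b = index[max(0, dr): rows - max(0, -dr),
                  max(0, dc): cols - max(0, -dc)]
        ok = (a >= 0) & (b >= 0)
        src.append(a[ok])
        dst.append(b[ok])
        w.append(np.full(ok.sum(), cost * grid.cell_km))
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    w = np.concatenate(w)
    n = sea.sum()
    graph = coo_matrix((np.concatenate([w, w]),
                        (np.concatenate([src, dst]),
                         np.concatenate([dst, src]))), shape=(n, n)).tocsr()
    return graph, index


def snap_to_sea(grid: CoastGrid, lat: float, lon: float) -> tuple[int, int]:
    """Nearest sea cell to a lat/lon point (great-circle via local scaling).

    Ties are broken in row-major order.
    """
    row, col = grid.latlon_to_rowcol(lat, lon)
    rr, cc = np.nonzero(grid.sea)
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    best = np.argmin(d2)  # argmin returns the first = row-major tie-break
    return int(rr[best]), int(cc[best])


# ---------------------------------------------------------------------------
# Least-cost distances
# ---------------------------------------------------------------------------

def least_cost_matrix(grid: CoastGrid, sites: pd.DataFrame,
                      diagonal: bool = True) -> pd.DataFrame:
    """Pairwise least-cost distances (km) between all sites in the table."""
    graph, index = _sea_graph(grid, diagonal)
    cells = [snap_to_sea(grid, r.latitude, r.longitude)
             for r in sites.itertuples()]
    nodes = np.array([index[c] for c in cells])
    uniq, inverse = np.unique(nodes, return_inverse=True)
    dmat = dijkstra(graph, directed=False, indices=uniq)
    out = dmat[np.ix_(inverse, nodes)]
    if np.isinf(out).any():
        _, labels = connected_components(graph, directed=False)
        comp = {s: int(labels[n]) for s, n in zip(sites["site_id"], nodes)}
        raise GridConnectivityError(
            f"sites lie in disconnected sea components: {comp}")
    return pd.DataFrame(out, index=list(sites["site_id"]),
                        columns=list(sites["site_id"]))


def least_cost_distance(grid: CoastGrid, a, b, diagonal: bool = True,
                        with_path: bool = False) -> LeastCostResult:
    """Least-cost distance between two sites.

    ``a`` and ``b`` are ``(lat, lon)`` tuples or site-table rows (anything
    with ``latitude``/``longitude`` attributes or keys).
    """
    def _coords(s):
        if isinstance(s, (tuple, list)):
            return float(s[0]), float(s[1]), f"{s[0]:.4f},{s[1]:.4f}"
        lat = s["latitude"] if not hasattr(s, "latitude") else s.latitude
        lon = s["longitude"] if not hasattr(s, "longitude") else s.longitude
        name = s["site_id"] if not hasattr(s, "site_id") else s.site_id
        return float(lat), float(lon), str(name)

    lat_a, lon_a, name_a = _coords(a)
    lat_b, lon_b, name_b = _coords(b)
    graph, index = _sea_graph(grid, diagonal)
    ca = snap_to_sea(grid, lat_a, lon_a)
    cb = snap_to_sea(grid, lat_b, lon_b)
    na, nb = index[ca], index[cb]
    dist, pred = dijkstra(graph, directed=False, indices=na,
                          return_predecessors=True)
    if np.isinf(dist[nb]):
        _, labels = connected_components(graph, directed=False)
        raise GridConnectivityError(
            f"{name_a} (component {labels[na]}) and {name_b} "
            f"(component {labels[nb]}) are not connected by sea")
    path = None
    if with_path:
        node_rc = {int(index[r, c]): (int(r), int(c))
                   for r, c in zip(*np.nonzero(grid.sea))}
        path = [node_rc[int(nb)]]
        cur = nb
        while cur != na:
            cur = pred[cur]
            path.append(node_rc[int(cur)])
        path.reverse()
    return LeastCostResult(name_a, name_b, float(dist[nb]), path)


# ---------------------------------------------------------------------------
# Assignment geography
# ---------------------------------------------------------------------------

def _assignment_records(assignments) -> pd.DataFrame:
    """Normalise assignment containers to (individual, fishery, unit, prob)."""
    if isinstance(assignments, AssignmentResult):
        items = [assignments]
    elif isinstance(assignments, MixtureEstimate):
        items = [assignments]
    else:
        items = list(assignments)
    rows = []
    for item in items:
        if isinstance(item, AssignmentResult):
            probs, units = item.unit_probs, item.units
            ids, fishery = item.individual_id, item.group_label
        else:
            probs, units = item.indiv_unit_posterior(), item.units
            ids, fishery = item.individual_id, item.group_label
        best = probs.argmax(axis=1)
        for i in range(len(ids)):
            rows.append({"individual": ids[i], "fishery": fishery[i],
                         "unit": units[best[i]],
                         "prob": float(probs[i, best[i]])})
    return pd.DataFrame(rows)


def assignment_geography(assignments, sites: pd.DataFrame, grid: CoastGrid,
                         unit_sites: dict[str, list[str]] | None = None,
                         prob_min: float = 0.8, threshold_km: float = 200.0,
                         exclude_fisheries: tuple = ()) -> MovementSummary:
    """Distance-to-origin summary of fishery assignments.

    Individuals assigned to a reporting unit with posterior probability
    above ``prob_min`` are kept; the summary reports, per fishery and
    pooled, the fraction of them whose origin unit lies within
    ``threshold_km`` least-cost kilometres of the fishery.  ``unit_sites``
    maps reporting units to their member river site ids (defaults to the
    unit name itself); the unit-fishery distance is the minimum over
    member sites.  A second pooled fraction excludes the fisheries listed
    in ``exclude_fisheries``.
    """
    rec = _assignment_records(assignments)
    rec = rec[rec["prob"] > prob_min].reset_index(drop=True)
    unit_sites = unit_sites or {u: [u] for u in rec["unit"].unique()}
    needed = set(rec["fishery"]) | {s for ss in unit_sites.values() for s in ss}
    missing = needed - set(sites["site_id"])
    if missing:
        raise ValueError(f"sites missing from the site table: {sorted(missing)}")
    sub = sites[sites["site_id"].isin(needed)].reset_index(drop=True)
    dmat = least_cost_matrix(grid, sub)

    def unit_dist(fishery, unit):
        return min(dmat.loc[fishery, s] for s in unit_sites[unit])

    counts = (rec.groupby(["fishery", "unit"]).size()
              .rename("n").reset_index())
    counts["distance_km"] = [unit_dist(f, u) for f, u in
                             zip(counts["fishery"], counts["unit"])]
    per_fishery = []
    for f, block in counts.groupby("fishery"):
        n = block["n"].sum()
        near = block.loc[block["distance_km"] <= threshold_km, "n"].sum()
        per_fishery.append({"fishery": f, "n": int(n),
                            "n_within": int(near),
                            "fraction_within": near / n})
    per_fishery = pd.DataFrame(per_fishery)
    total = counts["n"].sum()
    near = counts.loc[counts["distance_km"] <= threshold_km, "n"].sum()
    pooled = float(near / total) if total else np.nan
    keep = ~counts["fishery"].isin(exclude_fisheries)
    total_x = counts.loc[keep, "n"].sum()
    near_x = counts.loc[keep & (counts["distance_km"] <= threshold_km), "n"].sum()
    pooled_x = float(near_x / total_x) if total_x else np.nan
    return MovementSummary(counts, per_fishery, pooled, pooled_x,
                           details={"prob_min": prob_min,
                                    "threshold_km": threshold_km,
                                    "n_assigned": int(total)})


def drainage_regression(summary: MovementSummary,
                        sites: pd.DataFrame) -> RegressionResult:
    """OLS of within-fishery origin proportion on drainage area.

    Only fisheries with more than two contributing reporting units enter;
    the origin's drainage area is taken from its (first member) river site.
    """
    counts = summary.counts
    area = dict(zip(sites["site_id"], sites.get("drainage_area")))
    pts = []
    for f, block in counts.groupby("fishery"):
        contributing = block[block["n"] > 0]
        if len(contributing) <= 2:
            continue
        total = contributing["n"].sum()
        for _, row in contributing.iterrows():
            a = area.get(row["unit"])
            if a is None or pd.isna(a):
                warnings.warn(f"no drainage area for unit {row['unit']}; skipped")
                continue
            pts.append((float(a), row["n"] / total))
    if len(pts) < 3:
        raise ValueError(
            "fewer than 3 (area, proportion) points after the "
            ">2-contributors filter; regression refused")
    x, y = np.array(pts).T
    fit = linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue ** 2), float(fit.pvalue), len(pts))


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def tagging_analysis(tags: pd.DataFrame, sites: pd.DataFrame, grid: CoastGrid,
                     region_map: dict[str, str]) -> MovementSummary:
    """Tag-recapture movement analysis.

    Produces one record per (stock, recapture site) with the recapture
    count and the least-cost distance from the tagging site, a pooled OLS
    of count on distance, and per-stock percentages of recaptures made
    within the tagging region (plus their mean across stocks).
    """
    rec = tags[tags["recaptured"]].copy()
    known = set(sites["site_id"])
    skipped = (~rec["tag_site"].isin(known)) | (~rec["recapture_site"].isin(known))
    if skipped.any():
        warnings.warn(f"{int(skipped.sum())} recapture records with unknown "
                      "sites skipped")
        rec = rec[~skipped]
    used = sorted(set(rec["tag_site"]) | set(rec["recapture_site"]))
    sub = sites[sites["site_id"].isin(used)].reset_index(drop=True)
    dmat = least_cost_matrix(grid, sub)
    rec["distance_km"] = [dmat.loc[t, r] for t, r in
                          zip(rec["tag_site"], rec["recapture_site"])]
    counts = (rec.groupby(["stock", "tag_site", "recapture_site"])
              .agg(n=("tag_id", "size"), distance_km=("distance_km", "first"))
              .reset_index())
    per_stock = []
    for stock, block in rec.groupby("stock"):
        home = block["tag_site"].map(region_map)
        there = block["recapture_site"].map(region_map)
        within = float((home == there).mean()) * 100.0
        per_stock.append({
            "stock": stock, "n_recaptured": len(block),
            "pct_within_region": within,
            "mean_distance_km": float(block["distance_km"].mean()),
            "max_distance_km": float(block["distance_km"].max()),
        })
    per_stock = pd.DataFrame(per_stock)
    regression = None
    if len(counts) >= 3 and counts["distance_km"].nunique() > 1:
        fit = linregress(counts["distance_km"], counts["n"])
        regression = RegressionResult(float(fit.slope), float(fit.intercept),
                                      float(fit.rvalue ** 2),
                                      float(fit.pvalue), len(counts))
    return MovementSummary(
        counts, per_stock, regression=regression,
        details={
            "mean_pct_within_region": float(per_stock["pct_within_region"].mean()),
            "distances_km": rec["distance_km"].to_numpy(),
            "n_recaptures": int(len(rec)),
        },
    )
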