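"""Synthetic study generator: baselines, mixtures, tagging, coast rasters.

The genetic model is hierarchical Dirichlet drift: ancestral allele
frequencies per locus, regional frequencies drawn from
Dirichlet(p_anc * (1 - F_region) / F_region), and river (collection)
frequencies from Dirichlet(p_region * (1 - F_pop) / F_pop), so the two
drift parameters directly set the expected differentiation at each level
(for a Dirichlet with parameter a*p the standardised frequency variance is
1/(a + 1) = F).  Genotypes are random unions of gametes (HWE) and
missingness is applied uniformly per genotype.

Defaults emulate the study scale: 28 river collections in 5 regional
groups along a north-south coastline, microsatellite loci with 3-15
alleles (mean about 7.3), cross-region pairwise theta near 0.10, fishery
mixtures of known composition, and tag-recapture records under an
exponential distance-decay kernel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (MISSING, MIXTURE, REFERENCE, CoastGrid, GenotypeTable)

__all__ = ["ScenarioConfig", "generate_coast", "generate_baseline",
           "generate_mixture", "generate_tagging"]


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_regions: int = 5
    pops_per_region: tuple = (6, 6, 6, 5, 5)        # 28 collections
    f_region: float = 0.06
    f_pop: float = 0.05
    # per-locus drift heterogeneity: each locus scales both drift levels by
    # a log-uniform factor in [1/spread, spread]; 1.0 = homogeneous loci
    f_locus_spread: float = 2.2
    n_loci_msat: int = 100
    msat_allele_mean: float = 7.3                    # 3 + Poisson, clamped 3..15
    n_loci_snp: int = 0
    snp_maf_low: float = 0.05
    snp_maf_high: float = 0.5
    inds_per_collection: int = 30
    missing_rate: float = 0.02
    # coastline geometry
    cell_km: float = 2.0
    river_spacing_km: float = 40.0
    coast_margin_cells: int = 4
    lat0: float = 59.0
    lon0: float = -64.0
    n_fjords: int = 0
    # engineered near-panmictic clusters: tuples of collection indices that
    # share identical population frequencies and sit close together
    panmictic_clusters: tuple = ()
    cluster_spacing_km: float = 6.0
    # satellites: (index, source_index, f) — the population at ``index``
    # redraws its frequencies by drifting from ``source_index``'s with
    # parameter f (geometry unaffected); emulates leaky neighbours
    satellite_pops: tuple = ()
    # fisheries / tagging
    n_fisheries: int = 9
    dispersal_scale_km: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pops_per_region) != self.n_regions:
            raise ValueError("pops_per_region length must equal n_regions")
        for rate in (self.f_region, self.f_pop):
            if not 0.0 <= rate < 1.0:
                raise ValueError("drift parameters must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_collections(self) -> int:
        return int(sum(self.pops_per_region))


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One Dirichlet drift step: F = 0 copies the frequencies exactly."""
    if f == 0.0:
        return p.copy()
    p = np.maximum(p, 1e-9)
    q = rng.dirichlet(p * (1.0 - f) / f)
    return q


def _collection_names(config: ScenarioConfig) -> tuple[list[str], list[str]]:
    names, regions = [], []
    k = 0
    for r, n_pops in enumerate(config.pops_per_region):
        for _ in range(n_pops):
            k += 1
            names.append(f"P{k:02d}")
            regions.append(f"reg{r + 1}")
    return names, regions


# ---------------------------------------------------------------------------
# Coast raster and sites
# ---------------------------------------------------------------------------

def _river_positions_km(config: ScenarioConfig) -> np.ndarray:
    """Alongshore (north->south) km of each river mouth.

    Members of an engineered cluster sit ``cluster_spacing_km`` apart;
    other neighbours sit ``river_spacing_km`` apart.
    """
    n = config.n_collections
    in_cluster_with_prev = np.zeros(n, dtype=bool)
    for cluster in config.panmictic_clusters:
        members = sorted(cluster)
        for a, b in zip(members, members[1:]):
            if b == a + 1:
                in_cluster_with_prev[b] = True
    pos = np.zeros(n)
    for i in range(1, n):
        step = (config.cluster_spacing_km if in_cluster_with_prev[i]
                else config.river_spacing_km)
        pos[i] = pos[i - 1] + step
    return pos


def generate_coast(config: ScenarioConfig) -> CoastGrid:
    """A straight north-south coast: land strip on the west, open sea east.

    Optional fjord walls (land spurs jutting east) force least-cost
    detours.  The sea is a single connected component by construction.
    """
    positions = _river_positions_km(config)
    n_rows = int(np.ceil(positions[-1] / config.cell_km)) + 2 * config.coast_margin_cells + 1
    n_cols = 3 * config.coast_margin_cells + 10
    sea = np.ones((n_rows, n_cols), dtype=bool)
    land_cols = config.coast_margin_cells
    sea[:, :land_cols] = False
    if config.n_fjords:
        rng = np.random.default_rng(config.seed + 104729)
        wall_rows = rng.choice(
            np.arange(config.coast_margin_cells + 2,
                      n_rows - config.coast_margin_cells - 2),
            size=config.n_fjords, replace=False)
        for r in wall_rows:
            sea[r, land_cols:land_cols + n_cols // 2] = False
    return CoastGrid(sea, config.cell_km, config.lat0, config.lon0)


def _sites_frame(config: ScenarioConfig, grid: CoastGrid,
                 rng: np.random.Generator) -> pd.DataFrame:
    names, _ = _collection_names(config)
    positions = _river_positions_km(config)
    rows = config.coast_margin_cells + positions / config.cell_km
    col = config.coast_margin_cells        # first sea column (the shoreline)
    records = []
    for name, row in zip(names, rows):
        lat, lon = grid.rowcol_to_latlon(row, col)
        records.append({"site_id": name, "latitude": lat, "longitude": lon,
                        "drainage_area": float(rng.lognormal(5.0, 0.8)),
                        "role": "river"})
    # fisheries offshore, spread along the same coast
    span = positions[-1] if positions[-1] > 0 else 1.0
    for k in range(config.n_fisheries):
        alongshore = span * (k + 0.5) / config.n_fisheries
        row = config.coast_margin_cells + alongshore / config.cell_km
        lat, lon = grid.rowcol_to_latlon(row, col + 3)
        records.append({"site_id": f"F{k + 1:02d}", "latitude": lat,
                        "longitude": lon, "drainage_area": np.nan,
                        "role": "fishery"})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def generate_baseline(config: ScenarioConfig):
    """Simulate the reference baseline.

    Returns ``(table, sites, truth)`` where ``truth`` holds the true
    per-collection allele frequencies, the region map and the config —
    everything recovery tests need.
    """
    rng = np.random.default_rng(config.seed)
    names, regions = _collection_names(config)
    n_pops = config.n_collections

    loci, freqs_anc = [], []
    for j in range(config.n_loci_msat):
        k = 3 + rng.poisson(config.msat_allele_mean - 3.0)
        k = int(np.clip(k, 3, 15))
        loci.append(f"msat{j + 1:03d}")
        freqs_anc.append(rng.dirichlet(np.ones(k)))
    for j in range(config.n_loci_snp):
        maf = rng.uniform(config.snp_maf_low, config.snp_maf_high)
        loci.append(f"snp{j + 1:04d}")
        freqs_anc.append(np.array([1.0 - maf, maf]))

    # per-locus drift scaling emulates the heterogeneity of real loci
    # (informative vs near-neutral markers)
    L = len(loci)
    if config.f_locus_spread > 1.0:
        log_s = np.log(config.f_locus_spread)
        locus_factor = np.exp(rng.uniform(-log_s, log_s, size=L))
    else:
        locus_factor = np.ones(L)

    def scaled(f: float, l: int) -> float:
        return min(f * locus_factor[l], 0.9) if f > 0 else 0.0

    region_ids = sorted(set(regions))
    freqs_region = {r: [_drift(rng, p, scaled(config.f_region, l))
                        for l, p in enumerate(freqs_anc)]
                    for r in region_ids}
    freqs_pop: list[list[np.ndarray]] = []
    for name, region in zip(names, regions):
        freqs_pop.append([_drift(rng, p, scaled(config.f_pop, l))
                          for l, p in enumerate(freqs_region[region])])
    # engineered panmictic clusters: members share the first member's freqs
    for cluster in config.panmictic_clusters:
        members = sorted(cluster)
        for m in members[1:]:
            freqs_pop[m] = [p.copy() for p in freqs_pop[members[0]]]
    # satellites: weakly drifted copies of another population's frequencies
    sat_rng = np.random.default_rng(config.seed + 7919)
    for idx, src, f in config.satellite_pops:
        freqs_pop[idx] = [_drift(sat_rng, p, scaled(f, l))
                          for l, p in enumerate(freqs_pop[src])]

    n_i = config.inds_per_collection
    ids, colls, units, genos = [], [], [], []
    for k, (name, region) in enumerate(zip(names, regions)):
        g = np.empty((n_i, len(loci), 2), dtype=np.int64)
        for l, p in enumerate(freqs_pop[k]):
            draws = rng.choice(len(p), size=(n_i, 2), p=p)
            g[:, l, :] = draws + 1            # allele codes are 1-based
        miss = rng.random((n_i, len(loci))) < config.missing_rate
        g[miss] = MISSING
        genos.append(g)
        ids.extend(f"{name}_{i + 1:04d}" for i in range(n_i))
        colls.extend([name] * n_i)
        units.extend([name] * n_i)
    table = GenotypeTable(
        np.array(ids, dtype=object), np.array(colls, dtype=object),
        np.array(units, dtype=object),
        np.full(len(ids), REFERENCE, dtype=object), loci,
        np.concatenate(genos, axis=0),
    )
    grid = generate_coast(config)
    sites = _sites_frame(config, grid, np.random.default_rng(config.seed + 1))
    truth = {
        "config": config,
        "collections": names,
        "region_of": dict(zip(names, regions)),
        "loci": loci,
        "freqs": {name: freqs_pop[k] for k, name in enumerate(names)},
        "grid": grid,
    }
    return table, sites, truth


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

def generate_mixture(truth: dict, proportions: dict[str, float], size: int,
                     seed: int, fishery: str = "mix",
                     exact: bool = False) -> tuple[GenotypeTable, np.ndarray]:
    """Draw a fishery mixture of known composition from true frequencies.

    ``proportions`` maps collection names to mixing weights (must sum to
    1).  Origins are drawn multinomially; with ``exact=True`` the
    composition is fixed to the rounded expected counts instead
    (largest-remainder apportionment), which removes binomial composition
    noise from recovery experiments.  Returns the mixture table
    (sample_type ``mixture``, empty reporting unit, collection = fishery
    label) and the hidden truth labels as a separate array.
    """
    names = list(proportions)
    w = np.array([proportions[c] for c in names], dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture proportions must sum to 1")
    unknown = set(names) - set(truth["collections"])
    if unknown:
        raise ValueError(f"unknown collections in proportions: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    if exact:
        base = np.floor(w * size).astype(int)
        remainder = w * size - base
        short = size - base.sum()
        for k in np.argsort(-remainder)[:short]:
            base[k] += 1
        origin_idx = np.repeat(np.arange(len(names)), base)
    else:
        origin_idx = rng.choice(len(names), size=size, p=w)
    loci = truth["loci"]
    g = np.empty((size, len(loci), 2), dtype=np.int64)
    for k, name in enumerate(names):
        rows = np.flatnonzero(origin_idx == k)
        if len(rows) == 0:
            continue
        for l, p in enumerate(truth["freqs"][name]):
            g[rows, l, :] = rng.choice(len(p), size=(len(rows), 2), p=p) + 1
    miss_rate = truth["config"].missing_rate
    if miss_rate:
        miss = rng.random((size, len(loci))) < miss_rate
        g[miss] = MISSING
    ids = np.array([f"{fishery}_{i + 1:05d}" for i in range(size)], dtype=object)
    table = GenotypeTable(
        ids, np.full(size, fishery, dtype=object),
        np.full(size, "", dtype=object),
        np.full(size, MIXTURE, dtype=object), loci, g,
    )
    labels = np.array([names[k] for k in origin_idx], dtype=object)
    return table, labels


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def generate_tagging(sites: pd.DataFrame, grid: CoastGrid,
                     n_tags_per_stock: dict[str, int],
                     kernel_scale_km: float,
                     recapture_effort: dict[str, float],
                     recapture_rate: float = 0.25,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate tag-recapture records under a distance-decay kernel.

    A recaptured fish tagged at site s is recaptured at site t with
    probability proportional to ``effort_t * exp(-d(s, t) / scale)``
    (least-cost distance); recapture itself is Bernoulli per tag.
    """
    if kernel_scale_km < 0:
        raise ValueError("kernel_scale_km must be >= 0")
    from .spatial import least_cost_matrix
    stocks = list(n_tags_per_stock)
    effort_sites = [s for s, e in recapture_effort.items() if e > 0]
    used = sorted(set(stocks) | set(effort_sites))
    sub = sites[sites["site_id"].isin(used)].reset_index(drop=True)
    missing = set(used) - set(sub["site_id"])
    if missing:
        raise ValueError(f"sites missing from table: {sorted(missing)}")
    dmat = least_cost_matrix(grid, sub)
    rng = np.random.default_rng(seed)
    rows = []
    tag_no = 0
    for stock in stocks:
        d = np.array([dmat.loc[stock, t] for t in effort_sites])
        eff = np.array([recapture_effort[t] for t in effort_sites])
        if kernel_scale_km == 0:
            w = eff * (d == 0)
            if w.sum() == 0:   # no effort at the tagging site itself
                w = (d == d.min()) * eff
        else:
            w = eff * np.exp(-d / kernel_scale_km)
        w = w / w.sum()
        for _ in range(n_tags_per_stock[stock]):
            tag_no += 1
            recaptured = rng.random() < recapture_rate
            site = effort_sites[rng.choice(len(effort_sites), p=w)] \
                if recaptured else ""
            rows.append({"tag_id": f"T{tag_no:06d}", "stock": stock,
                         "tag_site": stock, "recapture_site": site,
                         "recaptured": recaptured})
    return pd.DataFrame(rows)
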