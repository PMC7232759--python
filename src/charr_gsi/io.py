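"""Readers and writers for the on-disk formats.

Genepop (2- or 3-digit diploid), the wide sample table (one row per
individual, two columns per locus), plain-text land/sea raster grids, and
the CSV site and tag tables.  All CSV dialects are comma-separated with a
header, UTF-8.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (MISSING, MIXTURE, REFERENCE, CoastGrid, FormatError,
                    GenotypeTable, ParseError)

log = logging.getLogger(__name__)

__all__ = [
    "read_genepop", "write_genepop", "read_sample_table", "write_sample_table",
    "read_grid", "write_grid", "read_sites", "write_sites", "read_tags",
    "write_tags",
]


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def read_genepop(path, ploidy_digits: int | None = None,
                 unit_map: dict[str, str] | None = None) -> GenotypeTable:
    """Read a Genepop file into a :class:`GenotypeTable`.

    One collection is created per POP block, named after the shared prefix
    (text before the first ``_``) of the block's last individual id, with a
    ``pop_k`` fallback.  Allele code 0 (``00``/``000``) is missing.

    Parameters
    ----------
    ploidy_digits
        2 or 3; inferred from the first genotype token when None.
    unit_map
        Optional collection -> reporting-unit mapping (Genepop itself has
        no reporting-unit concept); unmapped collections report as
        themselves.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: not a Genepop file (too short)")
    # title line, then locus names until the first Pop
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no POP separator found")

    ids, genos, pop_blocks = [], [], []
    block: list[int] = []
    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            if block or pop_blocks:
                pop_blocks.append(block)
                block = []
            else:
                pop_blocks.append(block)  # first Pop opens an empty block
                block = []
            continue
        if "," not in raw:
            raise ParseError(f"{path}:{lineno + 1}: individual line lacks a comma")
        ident, rest = raw.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: expected {len(loci)} genotypes, "
                f"got {len(tokens)}"
            )
        if ploidy_digits is None:
            if tokens and len(tokens[0]) in (4, 6):
                ploidy_digits = len(tokens[0]) // 2
            else:
                raise FormatError(f"{path}:{lineno + 1}: cannot infer digit width")
        row = np.empty((len(loci), 2), dtype=np.int64)
        for l, tok in enumerate(tokens):
            if len(tok) != 2 * ploidy_digits or not tok.isdigit():
                raise FormatError(
                    f"{path}:{lineno + 1}: token {tok!r} is not a "
                    f"{2 * ploidy_digits}-digit genotype"
                )
            a, b = int(tok[:ploidy_digits]), int(tok[ploidy_digits:])
            row[l] = (a if a else MISSING, b if b else MISSING)
            if (row[l] == MISSING).sum() == 1:
                raise ParseError(
                    f"{path}:{lineno + 1}: half-missing genotype {tok!r}"
                )
        ids.append(ident.strip())
        genos.append(row)
        block.append(len(ids) - 1)
    pop_blocks.append(block)
    pop_blocks = [b for b in pop_blocks if b]
    if not pop_blocks:
        raise FormatError(f"{path}: file contains no individuals")

    collections = np.empty(len(ids), dtype=object)
    for k, b in enumerate(pop_blocks):
        last_id = ids[b[-1]]
        prefix = last_id.split("_")[0] if "_" in last_id else last_id
        name = prefix or f"pop_{k + 1}"
        collections[b] = name

    unit_map = unit_map or {}
    units = np.array([unit_map.get(c, c) for c in collections], dtype=object)
    return GenotypeTable(
        np.array(ids, dtype=object), collections, units,
        np.full(len(ids), REFERENCE, dtype=object), loci,
        np.stack(genos),
    )


def write_genepop(table: GenotypeTable, path, ploidy_digits: int = 3,
                  title: str = "charr_gsi export") -> None:
    """Write a :class:`GenotypeTable` in Genepop format (missing -> zeros)."""
    if table.n_individuals == 0:
        raise ValueError("refusing to write an empty table")
    limit = 10 ** ploidy_digits
    too_big = [l for j, l in enumerate(table.locus_ids)
               if table.genotypes[:, j, :].max(initial=0) >= limit]
    if too_big:
        raise ValueError(
            f"allele codes exceed {ploidy_digits} digits at loci: {too_big}"
        )
    out = [title]
    out.extend(table.locus_ids)
    for coll in table.collections():
        out.append("Pop")
        for i in np.flatnonzero(table.collection == coll):
            toks = []
            for a, b in table.genotypes[i]:
                a = 0 if a == MISSING else a
                b = 0 if b == MISSING else b
                toks.append(f"{a:0{ploidy_digits}d}{b:0{ploidy_digits}d}")
            out.append(f"{table.individual_id[i]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Wide sample table
# ---------------------------------------------------------------------------

_DEFAULT_HEADER = {"sample_type": "sample_type", "repunit": "repunit",
                   "collection": "collection", "indiv": "indiv"}


def read_sample_table(path, header_map: dict[str, str] | None = None) -> GenotypeTable:
    """Read the wide one-row-per-individual table.

    The first four columns are sample_type, repunit, collection and indiv
    (renameable via ``header_map``); the rest come in pairs, two allele
    columns per locus.  Mixture rows have an empty repunit; blank alleles
    are missing.
    """
    hm = dict(_DEFAULT_HEADER)
    hm.update(header_map or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = [hm["sample_type"], hm["repunit"], hm["collection"], hm["indiv"]]
    for col in meta_cols:
        if col not in df.columns[:4].tolist():
            raise FormatError(f"{path}: expected metadata column {col!r} in header")
    allele_cols = [c for c in df.columns if c not in meta_cols]
    if len(allele_cols) % 2:
        raise FormatError(f"{path}: odd number of allele columns ({len(allele_cols)})")
    loci = [re.sub(r"(\.\d+|_[12]|_[ab])$", "", allele_cols[2 * j])
            for j in range(len(allele_cols) // 2)]
    if df[hm["indiv"]].duplicated().any():
        dups = df[hm["indiv"]][df[hm["indiv"]].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate individual ids: {dups[:5]}")

    n, L = len(df), len(loci)
    genos = np.full((n, L, 2), MISSING, dtype=np.int64)
    for j in range(L):
        for s, col in enumerate(allele_cols[2 * j: 2 * j + 2]):
            vals = df[col].str.strip()
            present = vals != ""
            genos[present.to_numpy(), j, s] = vals[present].astype(int).to_numpy()
    stype = df[hm["sample_type"]].str.strip().to_numpy(dtype=object)
    return GenotypeTable(
        df[hm["indiv"]].to_numpy(dtype=object),
        df[hm["collection"]].to_numpy(dtype=object),
        df[hm["repunit"]].str.strip().to_numpy(dtype=object),
        stype, loci, genos,
    )


def write_sample_table(table: GenotypeTable, path) -> None:
    cols: dict[str, list] = {
        "sample_type": list(table.sample_type),
        "repunit": list(table.reporting_unit),
        "collection": list(table.collection),
        "indiv": list(table.individual_id),
    }
    for j, locus in enumerate(table.locus_ids):
        for s in range(2):
            vals = table.genotypes[:, j, s]
            cols[f"{locus}_{s + 1}"] = ["" if v == MISSING else str(v) for v in vals]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster grid
# ---------------------------------------------------------------------------

def read_grid(path) -> CoastGrid:
    """Read a plain-text land/sea raster (header lines, then a 0/1 matrix)."""
    lines = [l for l in Path(path).read_text(encoding="utf-8").splitlines()
             if l.strip()]
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "nrows", "ncols", "cell_km", "lat0", "lon0"):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("nrows", "ncols", "cell_km"):
        if key not in header:
            raise FormatError(f"{path}: missing header line {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    rows = []
    for i, line in enumerate(lines[body_start:body_start + nrows]):
        vals = line.split()
        if len(vals) != ncols:
            raise FormatError(
                f"{path}: row {i} has {len(vals)} cells, expected {ncols}"
            )
        rows.append([int(v) for v in vals])
    if len(rows) != nrows:
        raise FormatError(f"{path}: expected {nrows} rows, found {len(rows)}")
    mask = np.array(rows, dtype=bool)
    if not mask.any():
        raise ValueError(f"{path}: grid is all land")
    return CoastGrid(mask, header["cell_km"],
                     header.get("lat0", 0.0), header.get("lon0", 0.0))


def write_grid(grid: CoastGrid, path) -> None:
    r, c = grid.shape
    out = [f"nrows {r}", f"ncols {c}", f"cell_km {grid.cell_km:g}",
           f"lat0 {grid.lat0:.6f}", f"lon0 {grid.lon0:.6f}"]
    for row in grid.sea.astype(int):
        out.append(" ".join(str(v) for v in row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Site and tag tables
# ---------------------------------------------------------------------------

def read_sites(path) -> pd.DataFrame:
    """Site table: site_id, latitude, longitude, optional drainage_area, role."""
    df = pd.read_csv(path)
    required = {"site_id", "latitude", "longitude", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing site columns {sorted(missing)}")
    if df["site_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate site ids")
    if not df["latitude"].between(-90, 90).all():
        raise ValueError(f"{path}: latitude out of [-90, 90]")
    if not df["longitude"].between(-180, 180).all():
        raise ValueError(f"{path}: longitude out of [-180, 180]")
    if "drainage_area" in df.columns:
        present = df["drainage_area"].notna()
        if not (df.loc[present, "drainage_area"] > 0).all():
            raise ValueError(f"{path}: drainage_area must be positive")
    bad_roles = set(df["role"]) - {"river", "fishery", "tagging"}
    if bad_roles:
        raise ValueError(f"{path}: unknown site roles {sorted(bad_roles)}")
    return df


def write_sites(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tags(path) -> pd.DataFrame:
    """Tag table: tag_id, stock, tag_site, recapture_site, recaptured."""
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"tag_id": str, "stock": str, "tag_site": str,
                            "recapture_site": str})
    required = {"tag_id", "stock", "tag_site", "recapture_site", "recaptured"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing tag columns {sorted(missing)}")
    if df["tag_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate tag ids")
    rec = df["recaptured"].astype(str).str.lower().isin(("true", "1", "yes"))
    df["recaptured"] = rec
    has_site = df["recapture_site"].astype(str).str.strip() != ""
    if (rec != has_site).any():
        raise ValueError(f"{path}: recapture_site must be present iff recaptured")
    return df


def write_tags(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
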