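"""Independent reference implementations used only to check the package.

Each oracle is coded from the published definition by a different route
than the library (indicator-variable ANOVA for theta, direct formula
evaluation for distances, Bellman-Ford relaxation and bounded path
enumeration for least-cost paths) so agreement is meaningful.
"""
import itertools

import numpy as np


def wc_theta_oracle(pop_alleles_per_locus):
    """Weir-Cockerham theta via per-allele indicator ANOVA.

    ``pop_alleles_per_locus`` is a list over loci; each entry is a list
    over populations of 1-D arrays of allele copies.  Returns the
    ratio-of-sums estimate over all loci and alleles.
    """
    a_sum = d_sum = 0.0
    for pops in pop_alleles_per_locus:
        pops = [np.asarray(p) for p in pops if len(p) > 0]
        r = len(pops)
        if r < 2:
            continue
        sizes = np.array([len(p) for p in pops], dtype=float)
        N = sizes.sum()
        nc = (N - (sizes ** 2).sum() / N) / (r - 1)
        for allele in sorted({int(a) for p in pops for a in p}):
            x = [(p == allele).astype(float) for p in pops]
            means = np.array([xi.mean() for xi in x])
            grand = sum(xi.sum() for xi in x) / N
            ssb = float((sizes * (means - grand) ** 2).sum())
            ssw = float(sum(((xi - m) ** 2).sum() for xi, m in zip(x, means)))
            msb = ssb / (r - 1)
            msw = ssw / (N - r) if N > r else 0.0
            a = (msb - msw) / nc
            a_sum += a
            d_sum += a + msw
    return a_sum / d_sum if d_sum else np.nan


def chord_distance_oracle(freqs1, freqs2):
    """Direct evaluation of D = sqrt((2/L) sum_l (1 - sum_a sqrt(p q)))."""
    total = 0.0
    for p, q in zip(freqs1, freqs2):
        total += 1.0 - sum(np.sqrt(pa * qa) for pa, qa in zip(p, q))
    return np.sqrt(2.0 * total / len(freqs1))


def nei_distance_oracle(freqs1, freqs2):
    """Direct evaluation of Nei's standard distance."""
    L = len(freqs1)
    j1 = sum(sum(pa * pa for pa in p) for p in freqs1) / L
    j2 = sum(sum(qa * qa for qa in q) for q in freqs2) / L
    j12 = sum(sum(pa * qa for pa, qa in zip(p, q))
              for p, q in zip(freqs1, freqs2)) / L
    return -np.log(j12 / np.sqrt(j1 * j2))


def bellman_ford_grid(sea, cell_km, src, diagonal=True):
    """Shortest sea distances from ``src`` by repeated edge relaxation."""
    rows, cols = sea.shape
    dist = np.full(sea.shape, np.inf)
    dist[src] = 0.0
    steps = [(0, 1, 1.0), (0, -1, 1.0), (1, 0, 1.0), (-1, 0, 1.0)]
    if diagonal:
        steps += [(1, 1, np.sqrt(2)), (1, -1, np.sqrt(2)),
                  (-1, 1, np.sqrt(2)), (-1, -1, np.sqrt(2))]
    changed = True
    while changed:
        changed = False
        for r in range(rows):
            for c in range(cols):
                if not sea[r, c] or np.isinf(dist[r, c]):
                    continue
                for dr, dc, w in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and sea[rr, cc]:
                        nd = dist[r, c] + w * cell_km
                        if nd < dist[rr, cc] - 1e-12:
                            dist[rr, cc] = nd
                            changed = True
    return dist


def enumerate_paths_shortest(sea, cell_km, src, dst, diagonal=True):
    """Best simple-path cost by depth-first enumeration with pruning.

    Only suitable for grids with few sea cells.
    """
    rows, cols = sea.shape
    steps = [(0, 1, 1.0), (0, -1, 1.0), (1, 0, 1.0), (-1, 0, 1.0)]
    if diagonal:
        steps += [(1, 1, np.sqrt(2)), (1, -1, np.sqrt(2)),
                  (-1, 1, np.sqrt(2)), (-1, -1, np.sqrt(2))]
    best = [np.inf]
    visited = {src}

    def dfs(cell, cost):
        if cost >= best[0]:
            return
        if cell == dst:
            best[0] = cost
            return
        r, c = cell
        for dr, dc, w in steps:
            nxt = (r + dr, c + dc)
            if (0 <= nxt[0] < rows and 0 <= nxt[1] < cols
                    and sea[nxt] and nxt not in visited):
                visited.add(nxt)
                dfs(nxt, cost + w * cell_km)
                visited.remove(nxt)

    dfs(src, 0.0)
    return best[0]


def random_additive_tree(rng, n_leaves):
    """Random binary tree; returns (leaf names, distance matrix, splits).

    Distances are exact path sums, so the matrix is additive; splits are
    the non-trivial bipartitions (canonical smaller side by (size, order)).
    """
    names = [f"t{i}" for i in range(n_leaves)]
    # each active item: (leaf set, dict leaf -> distance to the item's root)
    items = [({n}, {n: 0.0}) for n in names]
    dist = {}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (sa, da), (sb, db) = items[i], items[j]
        la = float(rng.uniform(0.5, 3.0))
        lb = float(rng.uniform(0.5, 3.0))
        for x in sa:
            for y in sb:
                dist[frozenset((x, y))] = da[x] + la + db[y] + lb
        merged = ({*sa, *sb},
                  {**{x: d + la for x, d in da.items()},
                   **{y: d + lb for y, d in db.items()}})
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(merged)
    D = np.zeros((n_leaves, n_leaves))
    for a, b in itertools.combinations(range(n_leaves), 2):
        D[a, b] = D[b, a] = dist[frozenset((names[a], names[b]))]
    return names, D


def splits_from_distances(names, D):
    """Non-trivial splits of the additive tree behind D (four-point test)."""
    n = len(names)
    out = set()
    for size in range(2, n - 1):
        for side in itertools.combinations(range(n), size):
            side_set = set(side)
            rest = [k for k in range(n) if k not in side_set]
            ok = True
            for (a, b) in itertools.combinations(side, 2):
                for (c, d) in itertools.combinations(rest, 2):
                    s1 = D[a, b] + D[c, d]
                    s2 = D[a, c] + D[b, d]
                    s3 = D[a, d] + D[b, c]
                    if not (s1 <= min(s2, s3) + 1e-9 and
                            abs(s2 - s3) < 1e-9):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                split = frozenset(names[k] for k in side)
                comp = frozenset(names[k] for k in rest)
                out.add(min([split, comp], key=lambda s: (len(s), sorted(s))))
    return out
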