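"""The genetic stock identification engine.

Genotype likelihoods follow the conditional Dirichlet-multinomial
(posterior-predictive) model used by rubias-style GSI: with baseline allele
counts y and totals n at a locus with A alleles and per-allele prior
xi_a = 1/A (so the prior total xi = 1), the probability of drawing a
genotype from a collection is

    heterozygote (a, b):  2 (y_a + xi_a)(y_b + xi_b) / ((n + 1)(n + 2))
    homozygote  (a, a):   (y_a + xi_a)(y_a + xi_a + 1) / ((n + 1)(n + 2))

Log-likelihoods sum over non-missing loci; missing loci contribute nothing.
Self-assignment is leave-one-out: an individual's own two allele copies are
subtracted from its collection's counts before scoring it there.  The
mixed-stock model is the standard Gibbs sampler over latent origins z and
mixing proportions pi with a flat Dirichlet(1/C) prior on pi and baseline
counts held fixed.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .popgen import allele_counts
from .types import (MISSING, REFERENCE, AlleleCounts, AssignmentResult,
                    GenotypeTable, GroupMetrics, MixtureEstimate)

log = logging.getLogger(__name__)

__all__ = [
    "genotype_log_likelihood", "log_likelihood_matrix", "extend_registry",
    "self_assign_loo", "accuracy_efficiency", "fit_mixture",
]


# ---------------------------------------------------------------------------
# Registry helpers
# ---------------------------------------------------------------------------

def extend_registry(counts: AlleleCounts, table: GenotypeTable) -> AlleleCounts:
    """Widen the allele registry to include codes seen only in ``table``.

    New alleles get zero baseline counts (the query is scored on the prior
    alone for those codes).
    """
    new_alleles, new_counts = [], []
    loci_pos = {l: j for j, l in enumerate(table.locus_ids)}
    for l, locus in enumerate(counts.loci):
        al = counts.alleles[l]
        j = loci_pos.get(locus)
        if j is None:
            new_alleles.append(al)
            new_counts.append(counts.counts[l])
            continue
        g = table.genotypes[:, j, :]
        seen = np.unique(g[g != MISSING])
        extra = np.setdiff1d(seen, al)
        if len(extra) == 0:
            new_alleles.append(al)
            new_counts.append(counts.counts[l])
        else:
            merged = np.sort(np.concatenate([al, extra]))
            y = np.zeros((len(counts.groups), len(merged)))
            pos = np.searchsorted(merged, al)
            y[:, pos] = counts.counts[l]
            new_alleles.append(merged)
            new_counts.append(y)
    return AlleleCounts(counts.groups, counts.loci, new_alleles, new_counts,
                        counts.n.copy())


def _index_genotypes(counts: AlleleCounts, table: GenotypeTable) -> np.ndarray:
    """Map genotype allele codes to registry indices; (n, L, 2), -1 missing.

    Loci of ``counts`` absent from ``table`` are treated as missing.
    """
    n = table.n_individuals
    out = np.full((n, len(counts.loci), 2), -1, dtype=np.int64)
    loci_pos = {l: j for j, l in enumerate(table.locus_ids)}
    for l, locus in enumerate(counts.loci):
        j = loci_pos.get(locus)
        if j is None:
            continue
        g = table.genotypes[:, j, :]
        present = g[:, 0] != MISSING
        al = counts.alleles[l]
        idx = np.searchsorted(al, g[present])
        if (idx >= len(al)).any() or (al[np.minimum(idx, len(al) - 1)]
                                      != g[present]).any():
            raise KeyError(
                f"allele code at locus {locus!r} absent from registry; "
                "call extend_registry first")
        out[present, l, :] = idx
    return out


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def log_likelihood_matrix(counts: AlleleCounts, table: GenotypeTable) -> np.ndarray:
    """(n_individuals, n_groups) conditional-Dirichlet log-likelihoods."""
    idx = _index_genotypes(counts, table)
    n_ind, G = table.n_individuals, len(counts.groups)
    L = np.zeros((n_ind, G))
    for l in range(len(counts.loci)):
        a, b = idx[:, l, 0], idx[:, l, 1]
        present = a >= 0
        if not present.any():
            continue
        xi = 1.0 / len(counts.alleles[l])
        y = counts.counts[l]                       # (G, A)
        nl = counts.n[:, l]                        # (G,)
        denom = np.log(nl + 1.0) + np.log(nl + 2.0)
        w = np.log(y + xi)                         # (G, A)
        w1 = np.log(y + xi + 1.0)
        ai, bi = a[present], b[present]
        het = ai != bi
        contrib = np.empty((present.sum(), G))
        contrib[het] = (np.log(2.0) + w[:, ai[het]].T + w[:, bi[het]].T)
        contrib[~het] = (w[:, ai[~het]].T + w1[:, ai[~het]].T)
        contrib -= denom[None, :]
        L[present] += contrib
    return L


def genotype_log_likelihood(counts: AlleleCounts, collection: str,
                            genotype_vector) -> float:
    """Log-likelihood of one multilocus genotype under one collection.

    ``genotype_vector`` is a sequence of ``(a, b)`` allele-code pairs or
    None (missing), one per locus of ``counts``.  Unseen alleles are
    scored on the prior alone.
    """
    g = counts.group_index(collection)
    total = 0.0
    for l, pair in enumerate(genotype_vector):
        if pair is None:
            continue
        al = counts.alleles[l]
        if len(al) == 0:
            warnings.warn(f"empty registry at locus {counts.loci[l]}; skipped")
            continue
        a, b = sorted(pair)
        A = len(al) + len({a, b} - set(al.tolist()))
        xi = 1.0 / A
        lookup = {code: k for k, code in enumerate(al)}
        y = counts.counts[l][g]
        ya = y[lookup[a]] if a in lookup else 0.0
        yb = y[lookup[b]] if b in lookup else 0.0
        n = counts.n[g, l]
        if a == b:
            p = (ya + xi) * (ya + xi + 1.0) / ((n + 1.0) * (n + 2.0))
        else:
            p = 2.0 * (ya + xi) * (yb + xi) / ((n + 1.0) * (n + 2.0))
        total += np.log(p)
    return float(total)


def _scaled(L: np.ndarray) -> np.ndarray:
    """Row-wise scaled likelihoods (posterior with a uniform prior)."""
    z = L - L.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


def _unit_probs(probs: np.ndarray, collections: list[str],
                unit_of: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    units = list(dict.fromkeys(unit_of[c] for c in collections))
    out = np.zeros((probs.shape[0], len(units)))
    for j, c in enumerate(collections):
        out[:, units.index(unit_of[c])] += probs[:, j]
    return out, units


# ---------------------------------------------------------------------------
# Self-assignment
# ---------------------------------------------------------------------------

def self_assign_loo(baseline: GenotypeTable) -> AssignmentResult:
    """Leave-one-out self-assignment of every baseline individual.

    Each individual's own allele copies are removed from its collection's
    counts before that collection's likelihood is computed; all other
    collections are scored on the full baseline.
    """
    sizes = pd.Series(baseline.collection).value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"collections with fewer than 2 individuals: {small}")
    counts = allele_counts(baseline, "collection")
    idx = _index_genotypes(counts, baseline)
    collections = counts.groups
    cidx = np.array([collections.index(c) for c in baseline.collection])
    L = log_likelihood_matrix(counts, baseline)

    # replace the home-collection column entries with LOO values
    for l in range(len(counts.loci)):
        a, b = idx[:, l, 0], idx[:, l, 1]
        present = a >= 0
        if not present.any():
            continue
        xi = 1.0 / len(counts.alleles[l])
        y = counts.counts[l]
        nl = counts.n[:, l]
        ai, bi, ci = a[present], b[present], cidx[present]
        ya = y[ci, ai]
        yb = y[ci, bi]
        n_home = nl[ci]
        het = ai != bi
        # full-baseline contribution of the home column
        old = np.where(
            het,
            np.log(2.0) + np.log(ya + xi) + np.log(yb + xi),
            np.log(ya + xi) + np.log(ya + xi + 1.0),
        ) - (np.log(n_home + 1.0) + np.log(n_home + 2.0))
        ya_l = np.where(het, ya - 1.0, ya - 2.0)
        yb_l = yb - 1.0
        if (ya_l < 0).any() or (het & (yb_l < 0)).any():
            raise AssertionError("negative allele count after LOO subtraction")
        n_l = n_home - 2.0
        new = np.where(
            het,
            np.log(2.0) + np.log(ya_l + xi) + np.log(yb_l + xi),
            np.log(ya_l + xi) + np.log(ya_l + xi + 1.0),
        ) - (np.log(n_l + 1.0) + np.log(n_l + 2.0))
        rows = np.flatnonzero(present)
        L[rows, cidx[rows]] += new - old

    probs = _scaled(L)
    unit_of = baseline.unit_of()
    uprobs, units = _unit_probs(probs, collections, unit_of)
    map_c = np.array([collections[k] for k in probs.argmax(axis=1)], dtype=object)
    map_u = np.array([units[k] for k in uprobs.argmax(axis=1)], dtype=object)
    return AssignmentResult(
        baseline.individual_id, baseline.collection,
        baseline.collection, baseline.reporting_unit,
        collections, units, probs, uprobs, map_c, map_u,
    )


def assign(baseline_counts: AlleleCounts, table: GenotypeTable,
           unit_of: dict[str, str],
           true_collection=None, true_unit=None) -> AssignmentResult:
    """Non-LOO assignment of arbitrary individuals against fixed counts."""
    probs = _scaled(log_likelihood_matrix(baseline_counts, table))
    collections = baseline_counts.groups
    uprobs, units = _unit_probs(probs, collections, unit_of)
    map_c = np.array([collections[k] for k in probs.argmax(axis=1)], dtype=object)
    map_u = np.array([units[k] for k in uprobs.argmax(axis=1)], dtype=object)
    return AssignmentResult(
        table.individual_id, table.collection, true_collection, true_unit,
        collections, units, probs, uprobs, map_c, map_u,
    )


# ---------------------------------------------------------------------------
# Accuracy / efficiency
# ---------------------------------------------------------------------------

def accuracy_efficiency(result: AssignmentResult,
                        prob_threshold: float = 0.5) -> GroupMetrics:
    """Accuracy and efficiency per reporting unit.

    Accuracy A_u = correctly assigned / total assigned to u; efficiency
    E_u = correctly assigned / total truly from u.  Individuals whose MAP
    unit probability does not exceed ``prob_threshold`` are unassigned and
    drop out of both the numerator and n_assigned.  Panel means are
    unweighted over units; units with nobody assigned have undefined
    accuracy and are excluded from the mean.
    """
    if result.true_unit is None:
        raise ValueError("accuracy/efficiency need truth labels")
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValueError("prob_threshold must be in [0, 1]")
    map_p = result.unit_probs.max(axis=1)
    assigned = map_p > prob_threshold
    rows = []
    for u in result.units:
        to_u = assigned & (result.map_unit == u)
        correct = int((to_u & (result.true_unit == u)).sum())
        n_assigned = int(to_u.sum())
        n_true = int((result.true_unit == u).sum())
        rows.append({
            "unit": u,
            "accuracy": correct / n_assigned if n_assigned else np.nan,
            "efficiency": correct / n_true if n_true else np.nan,
            "n_correct": correct, "n_assigned": n_assigned, "n_true": n_true,
        })
    df = pd.DataFrame(rows).set_index("unit")
    return GroupMetrics(df, float(df["accuracy"].mean()),
                        float(df["efficiency"].mean()))


# ---------------------------------------------------------------------------
# Mixed-stock MCMC
# ---------------------------------------------------------------------------

def _ess(trace: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of a 1-D trace."""
    x = trace - trace.mean()
    n = len(x)
    if n < 10 or x.std() == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit_mixture(baseline: GenotypeTable, mixture: GenotypeTable,
                iterations: int = 20000, burn_in: int = 1000,
                seed: int = 0) -> MixtureEstimate:
    """Bayesian mixed-stock analysis by Gibbs sampling.

    One chain of ``iterations`` sweeps: z_i | pi categorical with
    probability proportional to pi_c * P(g_i | c), then
    pi | z ~ Dirichlet(1/C + counts).  Baseline counts stay fixed (no
    feedback from the mixture).  Reporting-unit proportions are member
    sums per sweep; the 95% interval is equal-tailed over the post-burn-in
    trace, and a unit is "included" when its lower bound clears
    1/(2 * mixture size) — a Dirichlet posterior never touches exactly 0.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    ref = baseline.subset(baseline.sample_type == REFERENCE)
    shared = [l for l in ref.locus_ids if l in mixture.locus_ids]
    if not shared:
        raise ValueError("baseline and mixture share no loci")
    counts = extend_registry(allele_counts(ref, "collection"), mixture)
    logL = log_likelihood_matrix(counts, mixture)
    n, C = logL.shape
    collections = counts.groups
    unit_of = ref.unit_of()
    units = list(dict.fromkeys(unit_of[c] for c in collections))
    u_index = np.array([units.index(unit_of[c]) for c in collections])
    U = len(units)

    rng = np.random.default_rng(seed)
    alpha = 1.0 / C
    # stabilised likelihood matrix (per-individual scaling cancels in z | pi)
    lik = np.exp(logL - logL.max(axis=1, keepdims=True))
    pi = np.full(C, 1.0 / C)
    kept = iterations - burn_in
    unit_trace = np.empty((kept, U))
    post_sum = np.zeros((n, C))
    pi_sum = np.zeros(C)
    for it in range(iterations):
        w = lik * pi
        p = w / w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        z = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        z = np.minimum(z, C - 1)
        counts_z = np.bincount(z, minlength=C)
        pi = rng.dirichlet(alpha + counts_z)
        if it >= burn_in:
            unit_trace[it - burn_in] = np.bincount(u_index, weights=pi,
                                                   minlength=U)
            post_sum += p
            pi_sum += pi
    mean_u = unit_trace.mean(axis=0)
    ci_low = np.percentile(unit_trace, 2.5, axis=0)
    ci_high = np.percentile(unit_trace, 97.5, axis=0)
    zero_line = 1.0 / (2.0 * n)
    included = [u for k, u in enumerate(units) if ci_low[k] > zero_line]
    post = post_sum / kept
    coll_trace_mean = pi_sum / kept
    for k, u in enumerate(units):
        ess = _ess(unit_trace[:, k])
        if ess < 200:
            warnings.warn(f"low effective sample size ({ess:.0f}) for unit {u}")
            break
    return MixtureEstimate(
        units, mean_u, ci_low, ci_high, included, collections,
        coll_trace_mean, mixture.individual_id, mixture.collection, post,
        unit_trace,
        {"iterations": iterations, "burn_in": burn_in, "seed": seed,
         "unit_of_collection": [unit_of[c] for c in collections],
         "mixture_size": n},
    )
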