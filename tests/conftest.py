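import numpy as np
import pytest
from hypothesis import settings

from charr_gsi import GenotypeTable, ScenarioConfig, generate_baseline
from charr_gsi.types import MISSING, REFERENCE

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


def make_table(genos, collections, units=None, sample_type=None, loci=None,
               ids=None):
    """Small helper: build a GenotypeTable from a nested genotype list."""
    genos = np.asarray(genos, dtype=np.int64)
    n, L = genos.shape[:2]
    collections = np.asarray(collections, dtype=object)
    units = np.asarray(units if units is not None else collections,
                       dtype=object)
    stype = np.asarray(sample_type if sample_type is not None
                       else [REFERENCE] * n, dtype=object)
    loci = loci or [f"L{j + 1}" for j in range(L)]
    ids = ids or [f"{collections[i]}_{i + 1:03d}" for i in range(n)]
    return GenotypeTable(np.asarray(ids, dtype=object), collections, units,
                         stype, loci, genos)


@pytest.fixture(scope="session")
def two_pop_fixed():
    """Two collections fixed for different alleles: complete separation."""
    genos = [[[1, 1], [1, 1]]] * 10 + [[[2, 2], [2, 2]]] * 10
    return make_table(genos, ["A"] * 10 + ["B"] * 10)


@pytest.fixture(scope="session")
def small_baseline():
    """A 4-collection, 2-region synthetic baseline (fixed seed)."""
    cfg = ScenarioConfig(n_regions=2, pops_per_region=(2, 2), n_loci_msat=40,
                         inds_per_collection=25, missing_rate=0.02, seed=11)
    return generate_baseline(cfg)


@pytest.fixture(scope="session")
def study_baseline():
    """A 28-collection study-scale baseline (desk-scale sample sizes)."""
    cfg = ScenarioConfig(n_loci_msat=60, inds_per_collection=15, seed=23)
    return generate_baseline(cfg)


def random_table(rng, n_collections=3, n_per=6, n_loci=5, max_alleles=4,
                 missing_rate=0.1):
    """Randomised genotype table for property tests."""
    names = [f"C{k + 1}" for k in range(n_collections)]
    colls, genos, ids = [], [], []
    for k, name in enumerate(names):
        for i in range(n_per):
            row = []
            for j in range(n_loci):
                if rng.random() < missing_rate:
                    row.append([MISSING, MISSING])
                else:
                    row.append(sorted(rng.integers(1, max_alleles + 1,
                                                   size=2).tolist()))
            genos.append(row)
            colls.append(name)
            ids.append(f"{name}_{i + 1:03d}")
    return make_table(genos, colls, ids=ids)
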