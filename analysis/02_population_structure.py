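"""Population structure of the baseline: F_ST, NJ trees, PCoA.

Reads results/data/, writes per-locus and pairwise theta tables, a
bootstrapped chord-distance NJ tree (Newick) and PCoA coordinates.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from charr_gsi import (allele_counts, bootstrap_tree, chord_distance,
                       nei_distance, pcoa, read_sample_table, wc_fst)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "structure"
OUT.mkdir(parents=True, exist_ok=True)

table = read_sample_table(ROOT / "data" / "baseline.csv")
counts = allele_counts(table)

per_locus = wc_fst(counts, "per_locus")
per_locus.rename_axis("locus").reset_index().to_csv(
    OUT / "fst_per_locus.csv", index=False)
pairwise = wc_fst(counts, "pairwise")
pairwise.to_csv(OUT / "fst_pairwise.csv")

tree = bootstrap_tree(table, distance="chord", replicates=1000, seed=7)
(OUT / "nj_chord.nwk").write_text(tree.to_newick() + "\n")
nei_tree = bootstrap_tree(table, distance="nei", replicates=1000, seed=7)
(OUT / "nj_nei.nwk").write_text(nei_tree.to_newick() + "\n")

ord_ = pcoa(chord_distance(counts))
coords = ord_.to_frame()
coords.insert(0, "collection", coords.index)
coords.to_csv(OUT / "pcoa_coordinates.csv", index=False)

upper = pairwise.to_numpy()[np.triu_indices(len(pairwise), 1)]
supports = [n.support for n in tree.walk() if not n.is_leaf and n is not tree]
print(f"{table.n_loci} loci; per-locus theta "
      f"{per_locus.min():.3f}-{per_locus.max():.3f} "
      f"(mean {per_locus.mean():.3f})")
print(f"pairwise theta: mean {np.nanmean(upper):.3f}, "
      f"range {np.nanmin(upper):.3f}-{np.nanmax(upper):.3f}")
print(f"NJ tree: {sum(s > 50 for s in supports)}/{len(supports)} internal "
      f"edges with >50% bootstrap support")
print(f"PCoA: first two axes explain "
      f"{100 * ord_.proportion_explained[:2].sum():.1f}% of variation")
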