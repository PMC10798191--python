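"""Assign elements to genes via active promoters and chromatin loops.

The simulator wires some loops so their distal anchor sits on an element
and their other anchor on a gene promoter; loop_genes should recover that
wiring exactly, and proximal_genes reports elements inside active
(H3K4me3-marked) promoters.
"""

import pandas as pd

from recescan.simulate import simulate_epigenome
from recescan.targets import (active_promoters, loop_genes, promoter_windows,
                              proximal_genes)

sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
rows = [dict(chrom="chr1" if i % 2 == 0 else "chr2",
             start=7_000 + (i // 2) * 30_000) for i in range(30)]
elements = pd.DataFrame(rows).assign(end=lambda d: d["start"] + 200,
                                     name=lambda d: "e" + d.index.astype(str))

epi = simulate_epigenome(sizes, elements, seed=21, n_genes=30, n_loops=25)
promoters = promoter_windows(epi["genes"], sizes)
active = active_promoters(promoters, epi["promoter_peaks"])

prox_genes, prox_pairs = proximal_genes(elements, active)
lp_genes, lp_triples = loop_genes(elements, epi["loops"], promoters)

print(f"{len(active)}/{len(promoters)} promoters are active (H3K4me3)")
print(f"proximal genes ({len(prox_genes)}): {prox_genes}")
print(f"loop genes ({len(lp_genes)}): {lp_genes}")
print(lp_triples.head(8).to_string(index=False))
print("# Each triple: an element in a distal loop anchor whose partner")
print("# anchor overlaps the gene's promoter (both orientations checked).")
print("planted wiring rows:", len(epi["loop_truth"]),
      "| recovered rows:", len(lp_triples))
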