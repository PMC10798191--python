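"""Call conserved elements from a simulated primate alignment.

A 200 bp element evolving at 30% of the neutral rate is planted between
400 bp neutral flanks; the two-state phylogenetic HMM should recover an
interval close to the planted [400, 600) window.
"""

import numpy as np

from recescan import ConservationHMM, call_elements
from recescan.phylo import SubstitutionModel
from recescan.simulate import default_tree, element_in_flanks_specs, simulate_alignment

tree = default_tree()
model = SubstitutionModel.hky85(np.array([0.3, 0.2, 0.2, 0.3]), kappa=3.0)

specs = element_in_flanks_specs("chr1", 0, element_len=200, flank=400,
                                regime="conserved", rho=0.3)
blocks, truth = simulate_alignment(tree, model, specs, seed=7)
print("planted element:", truth.iloc[0]["chrom"],
      int(truth.iloc[0]["start"]), "-", int(truth.iloc[0]["end"]))

elements = call_elements(blocks[0], ConservationHMM(), tree, model)
print(elements[["chrom", "start", "end", "score"]].to_string(index=False))
print("# Each row is a maximal Viterbi conserved run; 'score' is the summed")
print("# log-odds of conserved over neutral emission (larger = stronger).")
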