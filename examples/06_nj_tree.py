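"""Neighbour-joining phylogeny with bootstrap support.

Under concerted evolution, paralogues cluster within species instead of
with their orthologues — the classic topological fingerprint.
"""

from concerta import scenario_vtg, simulate_family, to_newick
from concerta.align import PROT_ALPHABET, PROT_MATRIX, progressive_msa
from concerta.njtree import bootstrap_support

truth = simulate_family(scenario_vtg(seed=7))
proteins = [r.protein() for r in truth.records]
rows = progressive_msa(proteins, alphabet=PROT_ALPHABET, submat=PROT_MATRIX)
tree = bootstrap_support([r.id for r in truth.records], rows, B=100, seed=7)
print(to_newick(tree))
# The two sp1 genes form a clade (with high support), as do the two sp2
# genes: each species' paralogues were homogenised after speciation.
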