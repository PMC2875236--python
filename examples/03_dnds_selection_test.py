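"""Nei-Gojobori dN/dS with the bootstrap Z-test for purifying selection.

Simulates one 1500-codon orthologue pair evolved at omega = 0.3 and tests
whether the synonymous distance significantly exceeds the nonsynonymous
one (the signature of purifying selection).
"""

from concerta import align_codons, scenario_pair, simulate_family
from concerta.dnds import dnds

truth = simulate_family(scenario_pair(n_codons=1500, omega=0.3,
                                      target_ds=0.2, seed=1))
aln = align_codons([r.cds() for r in truth.records],
                   [r.id for r in truth.records])
res = dnds(aln, 0, 1, B=1000, seed=1)

c = res.counts
print(f"Ps = {c.Ps:.4f} ({c.se_Ps:.4f})   Pn = {c.Pn:.4f} ({c.se_Pn:.4f})")
print(f"dS = {res.dS:.4f}   dN = {res.dN:.4f}   dN/dS = {res.omega:.4f}")
print(f"Z = {res.Z:.2f}   one-tailed p = {res.p_value:.2e}")
# dN/dS lands near the simulated 0.3 and the tiny p-value rejects
# neutrality in favour of purifying selection (dN < dS).
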