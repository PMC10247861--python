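"""Coalescence times, remeeting times and the weak-selection amplifier test.

Builds the 3-vertex path and the smallest amplifying barbell graph, solves the
coalescing-random-walk system and prints the quantities that certify (or rule
out) weak-selection amplification.
"""

import networkx as nx

from transamp import effective_population_size, is_weak_selection_amplifier
from transamp.bellgraphs import BellFamilySpec, make_bell

p3 = nx.path_graph(3)
n_eff, res = effective_population_size(p3)
print("P3 pairwise coalescence times (steps):")
print(res.tau_pair.round(4))
print("remeeting times tau_i:", res.tau_remeet.round(4))
print(f"identity sum pi_i^2 tau_i = {res.identity_value:.12f}  (always 1)")
print(f"N_eff = {n_eff:.4f} < N = 3  -> P3 is no amplifier of weak selection\n")

b45 = make_bell(BellFamilySpec("barbell", 4, 5))
n_eff, _ = effective_population_size(b45)
print(f"barbell B(4,5): N = {b45.number_of_nodes()}, N_eff = {n_eff:.6f}")
print("weak-selection amplifier:", is_weak_selection_amplifier(b45))
print("N_eff > N means selection is amplified relative to the complete graph",
      "in the weak-selection limit.")
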