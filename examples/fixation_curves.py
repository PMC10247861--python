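"""Exact fixation probabilities and transient-amplifier classification.

Solves the death-Birth absorbing chain exactly for the smallest amplifying
barbell B(4,5) (N = 12, 4096 mutant configurations) and compares its fixation
probability with the complete graph K12. Runtime is about one minute.
"""

from transamp.bellgraphs import BellFamilySpec, make_bell
from transamp.fixation import classify

g = make_bell(BellFamilySpec("barbell", 4, 5))
res = classify(g)

print("r        rho_B(4,5)     rho_K12        difference")
for r, rg, rn in zip(res.r_grid, res.rho_graph, res.rho_complete):
    if 0.9 <= r <= 1.3:
        print(f"{r:<8.4f} {rg:<14.10f} {rn:<14.10f} {rg - rn:+.2e}")

print(f"\nclassification: {res.classification}")
print(f"transient window (r_min, r_max): {res.transient_window}")
print("the graph out-fixes the complete graph only on a bounded fitness",
      "window just above r = 1 -- the signature of a transient amplifier.")
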