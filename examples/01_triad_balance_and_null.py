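"""Triad balance of a signed network versus the sign-shuffle null.

A signed drug-drug-interaction network encodes enhancive interactions as
+1 edges and degressive ones as -1.  Weak structural balance says a
well-organized network is dominated by PPP, NNP and NNN triangles, with
few unbalanced PPN triangles.  To show this structure is not an artifact
of the sign frequencies alone, we compare the observed triad census with
the expectation under uniformly shuffled signs (same topology, same
numbers of + and - edges).
"""

from ddibalance import (
    expected_shuffled_triad_fractions,
    toy_signed_network,
    shuffle_signs,
    triad_census,
)

net, true_partition = toy_signed_network()
census = triad_census(net)
print(f"toy network: {net.n_nodes} drugs, {net.n_edges} interactions")
print(f"observed triads: {census}")
print("observed fractions:",
      {k: round(v, 3) for k, v in census.fractions().items()})

ep, en = net.edge_sign_counts()
null = expected_shuffled_triad_fractions(ep, en)
print("\nsign-shuffle null (closed form, from "
      f"{ep} enhancive / {en} degressive edges):")
print({k: round(v, 3) for k, v in null.items()})

print("\none actual shuffle for comparison:")
print(triad_census(shuffle_signs(net, seed=0)))

frac = census.fractions()
print(f"\nbalanced observed: {1 - frac['ppn']:.3f} "
      f"vs balanced under null: {1 - null['ppn']:.3f}")
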