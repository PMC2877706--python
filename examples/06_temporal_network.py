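"""Temporal statistical-parsimony haplotype network.

Collapses each layer of a serially sampled alignment into haplotypes,
connects them up to the 95% parsimony limit, stacks the per-layer
networks, and links identical haplotypes across adjacent layers.
"""

from paleoabc import (network_from_alignment, parsimony_limit, scenario,
                      simulate_scenario)
from paleoabc.network import write_dot, write_graphml

aln = simulate_scenario(scenario("pymva_like_bottleneck"), seed=21)
print(f"95% parsimony connection limit for {aln.length} bp:",
      parsimony_limit(aln.length, 0.95), "steps")
net = network_from_alignment(aln, confidence=0.95)
print("haplotypes per layer (oldest first):", net.layer_haplotype_counts())
print("identity links between adjacent layers:", len(net.links))
write_graphml(net, "temporal_network.graphml")
write_dot(net, "temporal_network.dot")
print("wrote temporal_network.graphml / .dot — nodes are haplotypes sized "
      "by count, dashed edges link identical haplotypes through time.")
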