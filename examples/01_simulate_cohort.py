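"""Generate a synthetic matched-omics aging study.

Builds a two-group donor cohort (young 20-25 y, old 55-66 y), a toy
metabolite reaction-pair network with enzyme incidences and unique
monoisotopic masses, and matched expression / ion-intensity matrices in
which a subset of enzymes carries a planted age effect that propagates to
its distance-1 metabolites.
"""

import networkx as nx

from metlocal.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_matched_omics,
    generate_toy_network,
)

config = SimulationConfig(seed=1)
cohort = generate_cohort(config)
network, db = generate_toy_network(config)
expression, ion_mz, intensities, truth = generate_matched_omics(
    cohort, network, db, config
)

print(f"donors: {len(cohort)} "
      f"({(cohort.group == 'young').sum()} young, {(cohort.group == 'old').sum()} old), "
      f"ages {cohort.age.min()}-{cohort.age.max()} years")
print(f"network: {network.graph.number_of_nodes()} metabolites, "
      f"{network.graph.number_of_edges()} reaction-pair edges, "
      f"connected={nx.is_connected(network.graph)}")
print(f"enzymes: {len(network.enzyme_map)}, planted with age effect: "
      f"{len(truth.planted_enzymes)} -> {truth.planted_enzymes[:4]} ...")
print(f"expression matrix: {expression.shape[0]} genes x {expression.shape[1]} donors "
      f"(log2 scale)")
print(f"ion matrix: {intensities.shape[0]} ions x {intensities.shape[1]} donors; "
      f"m/z range {ion_mz.mz.min():.3f}-{ion_mz.mz.max():.3f}")
print()
print("Planted enzymes differ between age groups and their distance-1")
print("metabolites co-vary with the enzyme's expression; everything else is noise.")
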