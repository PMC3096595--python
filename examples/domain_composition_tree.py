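"""Domain-composition phylogeny from arcsine-transformed TF profiles.

Profiles are evolved on a known 5-taxon ultrametric tree by Brownian motion
of transformed domain proportions; UPGMA on Euclidean distances between the
transformed vectors recovers the generating topology.
"""

from netfootprint import build_domain_tree, species_distance_matrix
from netfootprint.domain_phylogeny import contingency_table, fisher_species_test
from netfootprint.synthetic import simulate_profiles_from_tree

profiles, true_newick = simulate_profiles_from_tree(seed=7)
print(f"generating tree: {true_newick}")
domains = sorted(profiles[0].counts)

dist = species_distance_matrix(profiles, domains)
print("\npairwise distances (arcsine-transformed proportions):")
print(dist.round(3).to_string())

for method in ("upgma", "nj"):
    print(f"\n{method}: {build_domain_tree(dist, method)}")

# Fisher test over the ten most variable domains: are the five repertoires
# drawn from one composition?  Small p = composition differs by species.
table = contingency_table(profiles, domains[:10])
res = fisher_species_test(table, n_draws=20000, seed=1)
print(f"\nFisher ({res.method}): p = {res.p_value:.4g}")
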