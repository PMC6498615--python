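"""Average nucleotide identity and the hybrid NJ tree.

Computes fragment-based (ANIb-style) and whole-sequence (ANIm-style) ANI
matrices for a small simulated population, combines them into the hybrid
distance matrix (ANIm within the species, ANIb against the outgroup
species), builds a neighbor-joining tree and roots it on the outgroup.
"""

import cladepan as cp

config = cp.SimulationConfig(
    n_clades=2, strains_per_clade=[3, 3], n_ancestral_families=80,
    outgroup=True, seed=7,
)
assemblies, annotations, truth = cp.simulate_dataset(config)

anib = cp.ani_matrix(assemblies, method="anib")
anim = cp.ani_matrix(assemblies, method="anim")
print("ANIb matrix (fraction identity, mean of the two directions):")
print(anib.df.round(3).to_string())

species = {g.genome_id: g.species_label for g in assemblies}
dist = cp.hybrid_distance_matrix(anim, anib, species)
tree = cp.root_tree(cp.nj_tree(dist), "OUT")
print("\nHybrid 1-ANI NJ tree, rooted on the outgroup:")
print(cp.to_newick(tree))

# Within-clade ANI is ~0.995 (intra-clade divergence 0.002 on both tips),
# between-clade ~0.96, and ~0.85 against the outgroup; the tree therefore
# groups each clade together with the outgroup as the basal branch.
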