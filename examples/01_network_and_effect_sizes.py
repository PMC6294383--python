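"""Build a co-occurrence network and the pairwise effect-size table.

A small planted community is generated, converted to an edge list and an
unweighted network, and each species pair is scored under the
hypergeometric co-occurrence model.
"""
import cooccurnet as cn

cfg = cn.SyntheticConfig(n_sites=60, species_per_group=8, p_in=0.4,
                         p_out=0.03, seed=2)
matrix, truth = cn.generate_occurrences(cfg)
edges = cn.build_edge_list(matrix)
net = cn.build_network(edges, all_species=list(matrix.species_ids))
print(f"{matrix.n_species} species, {net.n_edges} co-occurrence links, "
      f"{len(net.isolated)} isolated species")

table = cn.effect_size_table(matrix)
strongest = table.nlargest(3, "effect")
print(strongest[["species_a", "species_b", "observed", "expected", "effect", "p_ge"]]
      .to_string(index=False))
# effect = (observed - expected shared sites) / n_sites: positive values are
# pairs co-occurring more than independent placement predicts; p_ge is the
# exact upper-tail probability of the observed sharing.
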