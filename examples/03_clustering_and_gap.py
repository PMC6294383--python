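"""PAM clustering on Jaccard dissimilarity and gap-statistic k selection."""
import cooccurnet as cn

cfg = cn.SyntheticConfig(n_sites=100, species_per_group=10, p_in=0.9,
                         p_out=0.05, seed=5)
matrix, truth = cn.generate_occurrences(cfg)
diss = cn.jaccard_dissimilarity(matrix)

pam = cn.pam_cluster(diss, k=3)
match = cn.congruence_C(truth.partition, pam.partition)
print(f"k=3 medoids: {pam.medoids}")
print(f"total cost {pam.total_cost:.2f}, agreement with truth C = {match.c:.2f}")

gap = cn.gap_statistic(diss, k_max=6, b_refs=25, seed=1)
for k, g, s in zip(gap.k_values, gap.gap, gap.se):
    marker = " <- k_opt" if k == gap.k_opt else ""
    print(f"k={k}: gap={g:+.3f} (se {s:.3f}){marker}")
# the gap compares observed within-cluster dispersion with structure-free
# reference data; the 1-SE rule picks the smallest adequate k.
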