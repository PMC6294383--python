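# cooccurnet

Multi-scale analysis of species co-occurrence networks: build unweighted
co-occurrence networks from site × species presence-absence data, partition
species by simulated-annealing modularity and by medoid (PAM) clustering,
and compare the partitions three ways — a congruence statistic with a
permutation test, spatial-clustering tests on species' range centroids, and
probabilistic co-occurrence effect sizes for declared host/associate
("nest") complexes.

The package is aimed at community ecologists and biogeographers asking
whether network modules reflect shared habitat (environmental filtering:
species with overlapping ranges grouped together) or positive biotic
interactions (groups that are *not* spatially clustered), and how the
answer changes across nested spatial scales.

## The statistics at the core

- **Co-occurrence network**: species a and b are linked iff they share at
  least one site.  Modules maximize Newman–Girvan modularity
  Q = Σ_c [L_c/m − (D_c/2m)²] via spin-glass simulated annealing
  (100 spins, T: 1 → 0.01, cooling 0.99).
- **Medoid clusters**: PAM (BUILD + SWAP) on species-wise Jaccard
  dissimilarity d = 1 − |A∩B|/|A∪B|, with k set to the module count or
  chosen by the gap statistic.
- **Congruence** C = (maximum number of species co-assigned by the two
  partitions over all one-to-one label matchings) / (species compared);
  tested by permuting species across clusters with group sizes fixed,
  p = (#{C_perm ≥ C_obs}+1)/(n_perm+1).
- **Spatial clustering**: MD_within / MD_among — the ratio of mean pairwise
  Euclidean distances (km) between range centroids within vs among groups —
  with an MRPP-style permutation test (ratio < 1 and small p ⇒ spatially
  aggregated groups).
- **Co-occurrence model**: shared-site counts for a pair occupying N1, N2
  of N sites are hypergeometric; expected co-occurrence N1·N2/N, effect
  size (observed − expected)/N, exact tail probabilities.

Every stage is also runnable on synthetic data with planted ground truth
(habitat-structured occurrences, host-conditional associates, clustered or
common range centroids), so the whole pipeline is testable end to end
without any external data.

## Worked example

```python
import cooccurnet as cn

# a planted basin: 3 habitat groups x 20 species, 100 sites,
# moderate occupancy, spatially clustered ranges
cfg = cn.SyntheticConfig(n_sites=100, p_in=0.35, p_out=0.02, seed=7)
matrix, truth = cn.generate_occurrences(cfg)
units, occupancy = cn.generate_centroid_tables(cfg, truth)

pc = cn.PipelineConfig(seed=1, n_perm=999, b_refs=25, k_max=6, restarts=3)
rep = cn.run_basin_analysis(matrix, units, occupancy, pc, basin="demo")

print(f"modules={rep.n_modules}  Q={rep.q:.3f}")
print(f"C={rep.congruence.c:.3f}  p={rep.congruence.p:.3f}")
print(f"MD_within:among={rep.spatial_modules.ratio:.3f}  p={rep.spatial_modules.p:.3f}")
print(f"gap k_opt={rep.gap.k_opt}")
```

prints

```
modules=3  Q=0.192
C=1.000  p=0.001
MD_within:among=0.048  p=0.001
gap k_opt=3
```

Reading: the annealing found the three planted modules (modularity 0.192);
PAM clustering at k = 3 assigned every species to the same groups
(congruence C = 1.0, permutation p = 0.001 — the smallest attainable p at
999 permutations); within-module species' range centroids are ~20× closer
to each other than to other modules' species (ratio 0.048, p = 0.001); and
the gap statistic independently selects k = 3 clusters.

The `examples/` directory has one short script per capability (networks
and effect sizes, module detection, clustering and the gap statistic,
congruence, spatial tests, nest complexes, the full pipeline and CLI).

A thin command line mirrors the library:

```sh
cooccurnet simulate --out demo --seed 7 --p-in 0.35 --p-out 0.02
cooccurnet run --occurrence demo/occurrence.csv \
    --unit-centroids demo/unit_centroids.csv --occupancy demo/occupancy.csv \
    --seed 1 --out demo/report.tsv
```

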