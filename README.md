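# condiv

**Multi-breed SNP diversity partitioning and conservation prioritisation.**

`condiv` is for conservation geneticists who manage collections of closed
livestock populations — e.g. national gene banks of native chicken breeds —
and need to decide which breeds matter most for preserving genetic
diversity. Starting from diploid biallelic SNP genotypes of several
labelled breed populations (PLINK PED/MAP text or VCF), it computes
within- and between-breed diversity, partitions the total diversity of the
whole collection into within- and between-breed components, measures each
breed's leave-one-out contribution to every component, estimates LD decay
and LD-based effective population size, and combines the contribution
ranks into a single conservation-priority score. A synthetic-panel
generator with known ground truth makes the whole pipeline runnable and
testable without any external data.

## The statistics at the core

For breed *i* with allele frequency *p<sub>i</sub>* at a biallelic locus:

* **Gene-diversity partition** — H<sub>T</sub> = H<sub>S</sub> + D<sub>G</sub>,
  where H<sub>S</sub> = 1 − f̄ is the mean within-breed gene diversity
  (f̄ the mean within-breed expected identity), H<sub>T</sub> = 2p̄(1−p̄)
  is the gene diversity at the unweighted mean frequency, and the
  divergence D<sub>G</sub> equals the average of all n² pairwise Nei
  minimum distances D<sub>Nei</sub> = (J<sub>X</sub>+J<sub>Y</sub>)/2 −
  J<sub>XY</sub>.
* **Allelic-diversity partition** — A<sub>T</sub> = A<sub>S</sub> + D<sub>A</sub>,
  with A<sub>S</sub> = (1/n)Σ k<sub>i</sub> the mean allelic richness and
  D<sub>A</sub> = 1/(n(n−1)) Σ<sub>i≠j</sub>(k<sub>i</sub> − k<sub>ij</sub>)
  built from breed-private alleles; richness can be rarefied to equal
  gene-copy counts by hypergeometric expectation.
* **Leave-one-out contribution** — c<sub>k</sub>(X) = 100·(X<sub>all</sub> −
  X<sub>−k</sub>)/T<sub>all</sub>: the signed percentage change of a
  component when breed *k* is dropped. Rows are exactly additive:
  c(H<sub>T</sub>) = c(H<sub>S</sub>) + c(D<sub>G</sub>).
* **Differentiation** — Weir–Cockerham θ (multi-locus ratio of variance
  components) alongside the plain ratio σ²<sub>p</sub>/(p̄(1−p̄)).
* **LD / N<sub>e</sub>** — dosage r² against physical distance, inverted
  through E[r²] ≈ 1/(1 + 4N<sub>e</sub>c) to an effective-size trajectory.
* **Priority score** — rank breeds by contribution to H<sub>T</sub> and to
  A<sub>T</sub> (competition ranking); score = rank sum, lower = higher
  conservation priority.

## Worked example

Five breeds, one of them a small, highly drifted and inbred population
(`INB`), simulated with known truth and pushed through the pipeline:

```python
from condiv import *
from condiv.synthetic_data import SimulationConfig

cfg = SimulationConfig(n_breeds=5, samples_per_breed=20, n_snps=2000,
                       breed_fst=[0.4, 0.15, 0.15, 0.15, 0.15],
                       breed_inbreeding=[0.8, 0.1, 0.1, 0.1, 0.1],
                       missing_rate=0.02, seed=7,
                       breed_codes=["INB", "B2", "B3", "B4", "B5"])
panel, truth = simulate_panel(cfg)
filtered, qc = apply_qc(panel)          # autosomes, <10% missing, MAF>5%
print(diversity_summary(filtered))
```

```
breed_code  n_samples     Ho     He    MAF   FHOM    fii
       INB         20 0.0482 0.2251 0.1658 0.8709 0.0206
        B2         20 0.3027 0.3267 0.2460 0.1901 0.0019
        ...
```

`INB`'s collapsed heterozygosity (Ho = 0.05) and FHOM = 0.87 recover the
planted inbreeding of 0.8; its positive fii flags the homozygote excess.
Partitioning and ranking:

```python
g = gene_diversity_partition(filtered)   # HT 0.3717 = HS 0.3014 + DG 0.0703
a = allelic_partition(filtered)          # AT 1.9818 = AS 1.8898 + DA 0.0920
ranking = combined_priority(loo_contribution(filtered, which="gene"),
                            loo_contribution(filtered, which="allelic"))
```

```
breed_code  contrib_gene  contrib_allelic  rank_HT  rank_AT  score  final_rank
        B2        2.0326           0.1832        1        1      2           1
        B3        1.4723           0.0688        2        2      4           2
        B4        0.9880           0.0359        4        3      7           3
        B5        1.4183           0.0240        3        4      7           3
       INB        0.0024          -0.3414        5        5     10           5
```

Removing `B2` would cost the collection 2.03% of its total gene diversity,
so it ranks first for conservation; the eroded `INB` population adds
almost nothing to either diversity pool and ranks last. Multi-locus
Weir–Cockerham θ across the five breeds is 0.2011.

The same stages are available from the shell:

```bash
condiv simulate --config sim.yaml --out simdir
condiv qc --ped simdir/panel.ped --map simdir/panel.map --out qcdir
condiv diversity --ped qcdir/filtered.ped --map qcdir/filtered.map --out div.tsv
condiv partition --ped qcdir/filtered.ped --map qcdir/filtered.map --out partdir
condiv run --config condiv.yaml      # full pipeline from a YAML config
```

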