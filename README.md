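# iegdyn

Analysis toolkit for the **early phase of activity-dependent transcription**:
ranking immediate-early genes (IEGs) by replicate-consistent up-regulation,
clustering their high-temporal-resolution induction time courses with an
unsupervised choice of the cluster number, testing the resulting clusters for
enrichment of hand-curated, signed function annotations, and scanning
promoter sequences for CArG boxes — the serum response factor (SRF) binding
motif `CC[A/T]6GG`.

The intended user is a bench scientist or bioinformatician who has (a)
treated/control expression matrices over biological replicas, (b) qPCR
fold-change (or raw Ct) time courses sampled every few minutes over the first
~90 minutes after a stimulus, (c) a curated gene→function vocabulary, and (d)
promoter FASTA files from one or more species. A synthetic-data module
generates all of these with the statistical structure the analysis assumes,
so the full pipeline runs and is tested without any external data.

## Methods at a glance

**Up-regulation ranking.** With expression matrices G (treated) and C
(control) over m genes × n replicas, the per-replica log fold changes
log₂(G_ij/C_ij) are treated as a sample from an n-dimensional distribution.
The score of gene g is the upper-orthant survival fraction of the empirical
distribution,

    p(g) = #{g′ : x_{g′j} ≥ x_{gj} for all j} / m ,

self-inclusive, so p ∈ [1/m, 1]; it is invariant under any strictly
increasing per-replica transform. Genes are then selected by a geometric-mean
fold-change cut (strictly greater than, default 2) and/or a p cut.

**Time-course clustering.** Fold changes (from the ΔΔCt method if raw Ct
values are supplied: fold = 2^−ΔΔCt) are smoothed per replica with a cubic
smoothing spline on a 1-minute grid, min-max normalized to [0, 1] so that
*shape*, not magnitude, is compared, and the replica curves of each gene are
concatenated into one feature vector. Euclidean k-means (best of 100
restarts) clusters the vectors; the number of clusters minimizes

    Θ(N) = ⟨dist(c_i)⟩ + α·N ,

where dist(c_i) is the mean squared member-to-centroid distance in cluster i
scaled by the global mean squared distance to the grand mean (so the
size-weighted mean ⟨·⟩ is the within-cluster over total sum of squares,
dimensionless in [0, 1]) and α (default 0.10) penalizes fragmentation.
Clustering quality is a permutation Z-score, and the co-clustering of paired
control primers gets an exact or Monte-Carlo chance probability.

**Cluster enrichment.** For a universe of N clustered genes with k carriers
of a signed term (e.g. `GROWTH:-`), the probability that a cluster of size n
holds exactly x carriers is hypergeometric, C(k,x)·C(N−k,n−x)/C(N,n);
over/under-representation are the one-sided tails P(X ≥ x) / P(X ≤ x)
(equal to one-sided Fisher's exact tests), computed in exact integer
arithmetic.

**CArG-box scanning.** Promoters are scanned for the consensus `CC[A/T]6GG`
(a reverse-complement-closed class) and with a position weight matrix using
the min-max scaled log-odds "relative score" in [0, 1] at the standard 0.8
threshold (JASPAR-format matrices such as SRF MA0083.1 are read directly).
A hit is flagged *conserved* when every species shows the identical 10-mer
at a start offset within a tolerance (default 50 bp) — a simplified
intersection rule standing in for alignment-based conservation.

## Worked example

Generate the emulated study design — 33 genes in three planted dynamical
patterns (fast rise to a ~50-min plateau / near-linear rise / ~50-min peak
then pronounced decline) of sizes 13/14/6, 12 time points in [10, 95] min,
3 replicas, 15% multiplicative noise — and run the clustering stage:

```python
from iegdyn import simulate, timecourse
from iegdyn.enrichment import EnrichmentQuery, hypergeom_tail_ge

cfg = simulate.SimulationConfig(seed=1)
tcs, labels = simulate.generate_timecourses(cfg, [13, 14, 6])
bundle = timecourse.build_trajectories(tcs)
theta, k_opt, fits = timecourse.theta_criterion(bundle, range(1, 9), seed=1)
print("theta by k:", {k: round(v, 3) for k, v in theta.items()})
print("selected k:", k_opt)
```

prints

```
theta by k: {1: 1.1, 2: 0.519, 3: 0.451, 4: 0.516, 5: 0.603, 6: 0.691, 7: 0.78, 8: 0.872}
selected k: 3
```

Θ(N) dips at N = 3 — the planted number of dynamical patterns — and the
recovered cluster sizes are 13/14/6 (permutation Z-score 17.3, far tighter
than random). If the four genes carrying an anti-growth annotation all land
in the 13-gene fast-rise cluster, the enrichment tail is

```python
print(hypergeom_tail_ge(EnrichmentQuery(33, 4, 13, 4)))   # 0.01747...
```

i.e. p ≈ 0.017: the co-occurrence of all four negative growth regulators in
the fastest-responding cluster is unlikely by chance.

The same stages are available from the shell:

```
iegdyn simulate --seed 1 -o demo/
iegdyn cluster --input demo/sim_timecourses.tsv --k-range 1:8 --seed 1 -o demo_cluster/
iegdyn enrich --vocab demo/sim_vocabulary.tsv --clusters demo_cluster/clusters.tsv -o enrich.tsv
iegdyn scan-carg --fasta demo/sim_promoters.fa --threshold 0.8 -o scan/
iegdyn run --config pipeline.yaml
```

## Layout

```
src/iegdyn/simulate.py    synthetic time courses, ratio matrices, promoters
src/iegdyn/ranking.py     log2 ratios, orthant-ECDF p-values, selection
src/iegdyn/timecourse.py  ddCt, smoothing, normalization, k-means, Θ(N), Z, pairs
src/iegdyn/enrichment.py  exact hypergeometric tests over signed vocabularies
src/iegdyn/motifs.py      CArG consensus + PWM scanning, conservation flags
src/iegdyn/io.py          TSV/FASTA/vocabulary readers and writers
src/iegdyn/pipeline.py    end-to-end orchestration with run manifests
src/iegdyn/cli.py         `iegdyn` command-line interface
docs/methods.md           modeling choices, defaults, limitations
```
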