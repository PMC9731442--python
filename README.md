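# magpop

Metapopulation genomics of metagenome-assembled genomes (MAGs) from pooled
allele counts.

Marine protists such as diatoms are sampled by environmental shotgun
sequencing: reads from one station/depth recruited against a reference MAG
form a *population pool*, and per-position nucleotide counts (not
genotypes) are all that is observed.  `magpop` implements the analysis
chain that turns such pool-seq count tables into population-genetic
conclusions:

1. **Recruitment QC** — per-sample admission via an 80%/97% read-identity
   cascade, ≥4× mean vertical coverage, ≥80% coverage breadth, and a
   unimodality check of the depth distribution (Hartigan's dip with a
   bootstrap p-value) that flags non-specific recruitment from a mixture of
   genomes; relative abundance and cross-genome Spearman co-occurrence.
2. **SNV landscape** — bi-allelic variant calling with the pool-seq window
   (min-count 2, per-pool coverage in [4, 200], every pool covered), SNV
   density per covered position, transition:transversion ratio, and
   annotation-based context (coding/UTR/intron/intergenic) and effect
   (silent/missense/nonsense) classification.
3. **Differentiation** — per-site pairwise fixation index from pooled
   allele frequencies,

       p̄ = (p₁+p₂)/2,  H_T = 2p̄(1−p̄),  H_S = p₁(1−p₁) + p₂(1−p₂),
       F_ST = (H_T − H_S) / H_T ∈ [0, 1],

   with non-informative (monomorphic) sites suppressed, the median across
   loci as the pool-pair differentiation proxy, a unimodality check of the
   population-wide F_ST distribution (a multimodal profile betrays a
   species mixture), and aggregation of sample pairs into regional means
   (Pacific-Arctic, Kara-Laptev, Atlantic-Arctic, Arctic Archipelago,
   Davis-Baffin).
4. **Selection scans** — the Lewontin–Krakauer test,
   `LK_ℓ = (n−1)·F_ST,ℓ / mean(F_ST) ~ χ²(n−1)` under neutral drift in a
   single species, and a pool-seq PCA outlier scan on the B-allele
   frequency (BAF) matrix: binomial scaling, SVD, robust Mahalanobis
   distance of per-locus loading vectors (minimum covariance determinant),
   genomic-inflation correction, Benjamini–Hochberg FDR, candidates at
   q < 0.15.  Aberrant pools can be detected and excluded before scanning.
5. **Isolation by environment** — z-scored environmental tables (ammonium
   dropped, nitrate+nitrite merged), Euclidean distance matrices per
   variable and for station coordinates, REML variance partitioning of the
   vectorised pairwise-F_ST response across per-variable covariance
   kernels, and one-sided Mantel permutation tests as independent
   verification.

A first-class synthetic-data generator (`magpop.simulate`) produces pooled
counts under a Balding–Nichols island model with planted outlier loci,
environment-linked genetic distances, toy annotated genomes with controlled
Ts/Tv and effect composition, and unimodal/bimodal coverage profiles — so
every stage is testable end to end with known truth.

## Worked example

```python
from magpop import (SimulationConfig, simulate_metapopulation, pairwise_fst,
                    baf_from_counts, pca_outlier_scan)

cfg = SimulationConfig(n_pools=6, n_loci=10000, fst_target=0.05,
                       n_selected=50, fst_selected=0.8,
                       coverage_mean=100, seed=5)
ds = simulate_metapopulation(cfg)

fst = pairwise_fst(ds.counts)
print(fst.median_matrix.iloc[:3, :3].round(4))

scan = pca_outlier_scan(baf_from_counts(ds.counts), seed=5)
hits = set(scan.candidates.index) & ds.truth_selected
print(f"candidates at q<0.15: {len(scan.candidates)}")
print(f"planted loci recovered: {len(hits)}/{len(ds.truth_selected)}")
print(f"genomic inflation factor: {scan.genomic_inflation:.3f}")
```

prints

```
         pool_01  pool_02  pool_03
pool_01      NaN   0.0259   0.0259
pool_02   0.0259      NaN   0.0249
pool_03   0.0259   0.0249      NaN
candidates at q<0.15: 45
planted loci recovered: 42/50
genomic inflation factor: 1.005
```

The median pairwise F_ST (~0.026) sits below the mean per-locus value
(0.05, the generator's calibrated target) because the per-locus F_ST
distribution is strongly right-skewed.  Of the 50 loci planted at elevated
differentiation, 42 are recovered at q < 0.15 with 3 neutral loci among the
45 candidates, and a genomic inflation factor of 1.005 shows the
Mahalanobis null is well calibrated.

The same stages are exposed on the command line:

```bash
magpop simulate --n-pools 4 --n-loci 3000 --fst 0.1 --seed 7 --out demo
magpop fst demo/counts.sync --out demo/fst
magpop scan demo/counts.sync --method pca --seed 7 --out demo/scan.tsv
magpop run --sync demo/counts.sync --samples demo/samples.tsv --out demo/full
```

`magpop run` chains QC → variants → F_ST → scans → environmental
association and writes a provenance block (resolved configuration, seed,
input digests) next to the outputs; environmental association is skipped,
with the reason logged, when fewer than three admitted samples carry
metadata or the genetic variance is zero.

## Formats

Pooled counts are read and written in the PoPoolation2 sync dialect
(contig, 1-based position, reference base, `A:T:C:G:N:del` per pool);
variants as VCF v4.2 with per-pool DP/AD; annotation as GFF3 (+ FASTA);
sample metadata, F_ST matrices and scan tables as TSV; reports as JSON.
Alignment summaries can be extracted from SAM/BAM via a thin pysam adapter
or supplied as plain TSV fixtures.

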