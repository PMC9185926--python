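# epmap

Enhancer-promoter interaction maps for GWAS fine-mapping in livestock
genomics: link trait-associated leading signals to their target genes
through the 3D genome, and narrow candidate variants with chromatin,
population-genetic, and motif evidence.

Most trait-associated variants are noncoding and the gene they regulate is
often *not* the nearest one — enhancers skip their nearest gene for a
distal target in roughly three quarters of cases. `epmap` implements the
analysis layer of a two-breed skeletal-muscle multi-omics design:

- **Loop annotation** — chromatin loops (5-kb anchors, 5 kb–2 Mb span) are
  classified by anchor content (P-P, P-E, E-E, …), genes by regulation type
  (I–IV), and each promoter gets a cumulative interaction score
  `Σ −log10(FDR)` over its loops, quantile-normalized across samples, with
  differential loop-regulated genes called at |log2FC| > 1.5, p < 0.05
  (moderated t on log scores).
- **RNA-chromatin contacts** — raw bridge-linker reads (cDNA + linker +
  genomic DNA) are parsed via the linker's 12-bp seed and MmeI boundary
  motifs into 17–23 bp mate pairs, uniquely located, and classified local
  (±10 kb of the source gene) / cis / trans; chromatin-associated RNAs are
  called against a Poisson background.
- **Fine-mapping** — candidate SNPs are pooled per leading signal (the
  containing TAD for array GWAS; LD r² ≥ 0.5 within 2 Mb for sequencing
  GWAS) and passed through a 5-step filter: loop-mediated CRE → open
  chromatin → |ΔAF| ≥ 0.5 between lean and local breed groups → muscle-trait
  target gene with intra-chromosomal RNA contact → predicted strong TF-motif
  effect (PWM log-odds, relative-score shift).
- **Selective sweeps** — windowed Hudson FST and XP-nSL, selected regions as
  the intersection of both top-5% tails, and circular-permutation enrichment
  of loop anchors in those regions.
- **Interaction network** — the combined chromatin + RNA contact graph, its
  communities, and a spring layout minimizing
  `E = Σ ½ k (d(i,j) − s(i,j))²` over connected pairs.
- **Synthetic data** — a first-class generator that plants ground truth for
  every stage (causal variants that pass all five filter steps, decoys that
  each violate exactly one, Balding–Nichols breed divergence with known FST,
  sweep windows, contact-mode mixtures, raw reads), so the whole pipeline is
  testable end to end without any external download.

## Worked example

```python
from epmap.simulate import SimConfig, simulate
from epmap.pipeline import RunConfig, run_bundle

bundle = simulate(SimConfig(seed=1))          # 2 chroms x 10 Mb, planted truth
summary = run_bundle(bundle, RunConfig(seed=1))
print(summary["finemap"])
print(summary["loops"]["skipping_fraction"])
print(summary["sweep"])
```

prints

```
{'n_candidates': 10, 'n_target_genes': 10, 'planted_recall': 1.0,
 'decoy_pass_rate': 0.0, 'attrition': {1: 1316, 2: 95, 3: 10, 4: 10, 5: 10},
 'audit_conserved': True}
0.7571189279731994
{'global_fst': 0.21604400336772692, 'n_windows': 629, 'n_regions': 3,
 'sweep_recovery': 1.0}
```

Reading this: the 5-step filter examined 1,451 pool entries across 15 leading
signals and emitted exactly the 10 planted causal variants with their true
target genes (recall 1.0); all 50 planted decoys were dropped, each at its
designated step (10 apiece at steps 3, 4 and 5 — steps 1 and 2 also absorb
background SNPs); the per-step drop counts plus emissions equal the pool
sizes. 75.7% of planted enhancer loops skip the nearest gene, matching the
0.75 generative rate. Genome-wide Hudson FST is ≈0.2 (sweep windows pull it
slightly above the neutral divergence parameter F = 0.2), and all 3 planted
sweep windows fall in the intersection of the top-5% FST and XP-nSL tails.

The same run is available from a shell:

```sh
epmap simulate --seed 1 --out bundle/
epmap run --bundle bundle/ --out results/ --seed 1
```

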