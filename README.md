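# mirstage

Staged analysis of small-RNA-seq count data across a cellular reprogramming
time course — for computational biologists studying how miRNA expression is
re-set as somatic cells (e.g. mouse embryonic fibroblasts) pass through
marker-defined intermediates (Thy1−, SSEA1+, Oct4-GFP+) on the way to
pluripotency, alongside partial-iPSC, iPSC and mES reference lines.

The package chains five analyses behind one pipeline:

1. **Preprocessing** — TMM (trimmed mean of M-values) normalization,
   multi-copy miRNA collapsing, and an abundance filter that keeps a miRNA
   only if it reaches ≥ 4 cpm in at least one library of *every* replicate
   group.
2. **Differential expression** — a negative-binomial log-link GLM with
   variance μ + φμ², one mean per stage plus an additive replicate
   (library-kit batch) term; a single common dispersion φ is estimated by
   Cox–Reid adjusted profile likelihood and contrasts are tested by
   likelihood-ratio χ² with Benjamini–Hochberg correction per contrast.
   Per-transition summaries count up/down calls and the fraction of
   significant upregulations with log₂FC > 5, and a pattern classifier
   labels transient (down-then-up / up-then-down), monotone and stable
   trajectories. Genomic-cluster over-representation (e.g. the imprinted
   *Dlk1*–*Dio3* region) is tested by the hypergeometric tail.
3. **Profiles** — row-centered/scaled log₂-cpm matrices and PCA of the
   most-variant half of miRNAs.
4. **Networks** — a co-expression graph weighted by the positive part of
   the Pearson correlation; community detection maximizes modularity

   Q(γ) = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/2m] δ(cᵢ, cⱼ)

   with the structural resolution parameter γ, by seeded multi-level greedy
   optimization with restarts. An ensemble of runs is summarized by its
   *representative* partition (highest mean pairwise z-Rand similarity);
   submodules are found by re-analyzing each module's miRNAs independently,
   and γ sweeps report which modules split, persist or dissolve.
5. **isomiRs** — per-(miRNA, sample) 5′ start-offset distributions from
   alignments (SAM or tabular, strand-aware) and a switching rule that
   flags miRNAs with a > 1-nt 5′ shift in > 10 % of reads whose dominant
   start differs between sample groups, plus the seed (nt 2–8) implied by a
   shift.

A first-class synthetic-data generator (`mirstage.simulate`) plants the
archetypal expression programs this design is meant to detect — an abrupt
drop at the first transition with gradual recovery (imprinted-cluster
archetype), a MET spike, a monotone stem-cell ramp with a large late jump,
and a monotone decline — over negative-binomial noise with a replicate
batch effect, and returns the ground truth for recovery tests.

## Worked example

```sh
mirstage simulate --out demo --seed 7
mirstage run --counts demo/counts.tsv --samples demo/samples.tsv \
    --annotation demo/annotation.bed --offsets demo/isomir_offsets.tsv \
    --out demo_out --seed 7
```

prints (abridged):

```json
{
 "preprocess":   {"n_input": 300, "n_filtered": 300, "ref_sample": "piPSC_r2"},
 "differential": {"phi": 0.1012, "n_transitions": 6, "n_de_total": 183},
 "enrichment":   {"cluster": "Dlk1-Dio3", "n_down": 53,
                  "odds_ratio": 262.8, "p": 1.36e-40},
 "profile":      {"n_top": 150, "pc1_var": 0.273},
 "network":      {"n_nodes": 119, "gamma": 1.0, "Q": 0.371, "n_modules": 4},
 "isomir":       {"n_mirnas": 300, "n_switched": 1}
}
```

Reading this: the generator's dispersion (0.1) is recovered as φ ≈ 0.101;
53 miRNAs drop at the first transition and the planted imprinted-cluster
members dominate them (hypergeometric p ≈ 10⁻⁴⁰); the γ = 1 representative
partition finds the four planted co-expression programs; and exactly the
one planted isomiR (60 % of reads shifted +3 nt in MEF samples only) is
reported as switched. Full tables (DE per transition, partition with
submodule letters, PCA scores, z-Rand matrices, switch reports) and a
manifest with thresholds and artifact digests are written under
`demo_out/`.

The same stages are importable directly — `preprocess.tmm_factors`,
`differential.lrt_contrast`, `network.consensus_partition`,
`isomir.detect_switching`, … — and operate on pandas objects.

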