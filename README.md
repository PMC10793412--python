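# glycohub

Integrated transcriptome–glycoproteome analysis of case/control brain
cohorts: from multi-cohort differential expression of
glycosyltransferase genes ("glycogenes") to the downstream cell–cell
signaling they plausibly drive.

Aberrant protein glycosylation — particularly of the extracellular
matrix (ECM) — is an emerging layer of neurodegenerative disease
biology, but the glycoproteome cannot be measured at single-cell
resolution. `glycohub` implements the *glycogenomics* workaround: use
transcriptomes as a proxy to find the upstream glycosyltransferase
whose dysregulation best explains ECM changes, then trace its product
through single-cell data to a ligand–receptor interaction and a
downstream co-expression neighborhood. Because the cohort data this
kind of study uses are access-controlled, the package ships a
first-class synthetic-data generator that plants every structure the
pipeline is supposed to find, so each stage is testable against known
ground truth.

## Pipeline stages

1. **Meta-analysis** (`glycohub.meta`) — per gene and per cohort×region
   stratum, the bias-corrected standardized mean difference (Hedges'
   g): d = (x̄₁ − x̄₀)/s_pooled, g = J·d with
   J = 1 − 3/(4(n₁+n₀) − 9), combined across strata under a
   random-effects model with τ² by REML (DerSimonian–Laird as
   fallback/option), Benjamini–Hochberg FDR across genes.
2. **Enrichment** (`glycohub.enrich`) — hypergeometric
   over-representation against an all-gene background; preranked GSEA
   (weighted Kolmogorov–Smirnov running sum, gene-label permutation
   null, same-sign NES); a dual post-hoc test that asks which
   glycosylation pathways drive which enriched pathways
   (hypergeometric AND Wilcoxon on |effect|, both BH-corrected).
3. **Hub selection** (`glycohub.hub`) — bipartite graph between
   enriched pathways and differentially expressed glycogenes; the gene
   of maximal pathway degree is the functional hub.
4. **Pathway association** (`glycohub.pathway_assoc`) — ECM activity
   (member mean or eigengene) regressed on each candidate pathway's
   principal-component scores with a permutation F-test per stratum;
   Fisher's method (X² = −2Σln p, df = 2k) combines strata.
5. **Single cell** (`glycohub.sc`) — library-size log-normalization,
   VST-style feature selection, cell-type profiles, Wilcoxon marker
   tests, −log₁₀(FDR) ECM score matrices, and a saturating
   ligand–receptor score L̄R̄/(Kh + L̄R̄) with a label-permutation test.
6. **Network propagation** (`glycohub.propagate`) — |cor|^β soft
   adjacency on one cell type, topological overlap (TOM), percentile
   edge thresholding, random walk with restart from seed genes, top-k
   neighbor prioritization and ORA of the neighborhood.

`glycohub.synth` generates the synthetic study (bulk cohorts, pathway
collection, glycogene annotation, single-cell counts) with
machine-readable truth records; `glycohub.pipeline` wires the stages
end to end.

## Worked example

```python
from glycohub import synth, pipeline

res = pipeline.run_hub_pipeline(synth.default_bulk_spec(seed=0), gsea_seed=0)
print("enriched pathways (q<0.05):",
      int((res.gsea_table["q"] < 0.05).sum()))
glyco = res.meta_table[res.meta_table["gene"].str.startswith("GLYC")]
print("glycogene DEGs:", int(glyco["is_deg"].sum()))
print("hub:", res.selected.genes, "degree:", res.selected.degree)
```

prints

```
enriched pathways (q<0.05): 13
glycogene DEGs: 10
hub: ('GLYC0000',) degree: 10
```

The synthetic study plants ten differentially expressed glycogenes
(standardized effect 0.8 across 3 cohorts × 2 regions), seeds twelve
pathways with those effects, and places `GLYC0000` in ten of them
versus at most three for each decoy. The pipeline's effect-size GSEA
recovers the seeded pathways (13 enriched: the 12 seeded sets plus the
planted ECM-driver set, which carries a real negative signal), flags
the ten planted glycogenes as DEGs, and the bipartite degree ranking
returns the planted hub at degree 10. The combined effect for the hub
gene in this replicate is μ̂ = 0.89 (se 0.14, τ² = 0.05, q ≈ 2e-8),
consistent with the planted 0.8.

The same stages are exposed on the command line (`glycohub simulate`,
`glycohub meta`, `glycohub enrich ora|gsea|posthoc`, `glycohub hub`,
`glycohub assoc`, `glycohub sc profile|markers|lrscore`,
`glycohub propagate`); each reads and writes plain TSV/GMT/MTX files.

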