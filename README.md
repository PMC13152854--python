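# budtraj

Trajectory-centric analysis of chilling-requirement (CR) divergence in
stage-resolved dormancy transcriptomes.

Temperate fruit trees such as peach require a cultivar-specific amount of
winter chill before floral buds release endodormancy. Bulk RNA-seq series
that compare low-CR and high-CR cultivars across dormancy stages (S1
induction, S2 maintenance, S3 release) are dominated by genotype background:
a naive cross-cultivar contrast mostly recovers baseline differences, not
dormancy biology. `budtraj` implements the trajectory-centric alternative
for researchers working on bud dormancy and phenology: it standardizes each
gene's temporal profile *within* each cultivar, clusters the standardized
trajectories into temporal modules, quantifies where High-CR and Low-CR
groups diverge along the stage axis, and funnels the divergent programs into
co-expression networks and an evidence-ranked candidate list.

## The method

Given a genes × samples TPM matrix with a cultivar / stage / replicate /
CR-group design, matched hormone measurements (ABA, GA3, GA7) and functional
annotations, the pipeline runs:

1. **QC** — keep genes with TPM ≥ 1 in ≥ 3 libraries; work on
   log2(TPM+1); summarize replicate concordance and PCA structure
   (cultivar background on PC1, stage progression on PC2).
2. **Trajectory modules** — per cultivar *c* and stage *s*, compute the
   replicate-mean profile x̄\_{g,c,s} and standardize
   z\_{g,c,s} = (x̄\_{g,c,s} − μ\_{g,c}) / σ\_{g,c}; k-means (k = 8) on the
   concatenated cultivar blocks yields modules C1…C8.
3. **Divergence** — per gene and stage, d\_s = High\_s − Low\_s on
   log2(TPM+1) cultivar-stage replicate means (cultivars are the
   independent units); module divergence D(C,s) = mean |d\_s|; a gene is
   *directionally discordant* when sign(d\_s) flips across stages
   (|d\_s| ≥ ε = 0.05). Modules with a discordant majority are the
   CR-divergent programs. Candidates must additionally show an S1→S3 trend
   concordant in ≥ 3 of 4 cultivars, pass the abundance gate
   (mean TPM ≥ 0.5, max TPM ≥ 1), and carry a regulatory-plausible class
   (TF, kinase-related, hormone-associated, chromatin/RNA).
4. **Enrichment** — hypergeometric upper-tail tests per module term,
   Benjamini–Hochberg FDR within each annotation layer, significance at
   q < 0.05.
5. **Networks** — stage-residualized Pearson co-expression over
   candidates; WGCNA-style module layer (adjacency |r|^6, topological
   overlap, average-linkage tree cut) with eigengene–trait models
   (ME ~ Stage + Cultivar + CR\_group + ABA + GA3 + GA7; the CR term is
   aliased with cultivar in the reference design and flagged); a consensus
   network keeping only edges whose correlation sign agrees at |r| ≥ 0.5 in
   ≥ 3 of 4 per-cultivar networks; GraphML/SIF export for Cytoscape.
6. **Prioritization** — per-gene evidence components in [0,1]
   (peak divergence, hub degree, betweenness bridge score, cross-cultivar
   support, abundance) combined as a weighted sum
   (0.4/0.2/0.1/0.2/0.1) into a ranked candidate resource.

Because public stage-resolved CR datasets with ground truth do not exist,
the package ships a first-class synthetic-data generator
(`budtraj.synthetic`) that plants all of this structure — archetypes,
divergence windows, co-expression blocks, hormone coupling — so every stage
is testable against known truth.

## Worked example

```python
from budtraj import run_pipeline

res = run_pipeline({"simulate": {"enabled": True, "n_genes": 2000},
                    "seed": 1}, "runs/demo")
```

prints nothing by itself, but the result object (and the TSVs in
`runs/demo/`) contain, for this seed:

```
PC1 65.2%  PC2 18.2% of variance          # genotype axis, then stage axis
CR-divergent modules: C2, C5, C6           # discordant fraction >= 0.5
candidates: 145 genes
modules over candidates: turquoise 45, blue 33, grey 67
MEturquoise ~ ABA: r = 0.50, p = 0.0021    # ABA-coupled module
consensus network: 145 nodes, 1537 edges
```

The PC fractions say cultivar background dominates global variance with a
clean stage axis underneath; the flagged modules are the temporal programs
where High-CR and Low-CR group means diverge with stage-specific windows
(peak mean |High−Low| ≈ 0.49 log2 units); the turquoise candidate module
co-varies with ABA abundance across the 36 libraries; and the consensus
edges are reproducible across ≥ 3 of the 4 genotypes. `priority_top.tsv`
lists the top-ranked candidates with their module, peak-divergence stage
and functional class.

The `examples/` directory holds short narrative scripts, one per
capability (`simulate_dataset.py`, `qc_overview.py`,
`trajectory_divergence.py`, `network_and_ranking.py`). A thin CLI wraps
the same calls:

```bash
budtraj simulate --outdir sim/
budtraj run --simulate --outdir runs/demo
```

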