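# endoscope

Endotype discovery and mortality prognosis for bulk blood RNA-seq sepsis
cohorts.

Sepsis is a heterogeneous syndrome: patients with the same clinical
presentation can carry very different underlying immune states, which is a
leading explanation for the failure of one-size-fits-all therapeutics.
`endoscope` implements an analysis pipeline that stratifies a sepsis cohort
into molecular *endotypes* from peripheral-blood gene expression and builds
small transcript panels that predict 28-day mortality better than a bedside
severity score (qSOFA).

The pipeline, starting from a gene × patient count matrix:

1. **Preprocessing** — remove low-expression genes (mean CPM < 10),
   sex-linked genes (chromosomes X/Y) and unannotated features; estimate
   per-patient size factors s_j by median-of-ratios; fit a
   negative-binomial dispersion–mean trend α(μ) = a₀ + a₁/μ and apply the
   closed-form variance-stabilizing transformation (VST)
   u(x) = log₂[(1 + a₁ + 2a₀x + 2√(a₀x(1 + a₁ + a₀x))) / 4a₀].
2. **Mapper (TDA)** — correlation distance d = 1 − r between patient
   profiles, two spectral "neighborhood" lens coordinates from the mutual
   k-NN graph Laplacian, an overlapping 2-D cover (resolution R per axis,
   gain g), single-linkage clustering within each cover bin, and a graph
   whose nodes are bin-clusters and whose edges mark shared patients.
   Endotype groups are communities of this graph under greedy modularity,
   with at most 10% of patients allowed to be shared between groups;
   adjacent groups with too few deaths are merged into one low-mortality
   group, and groups are labeled t1..tK by descending mortality.
3. **Differential expression** — per-gene Welch t-tests (died vs survived,
   or between exclusive group members), Benjamini–Hochberg adjustment,
   log₂ fold changes as VST mean differences; one-way ANOVA plus pairwise
   Welch tests for clinical features.
4. **Prognostic panels** — mRMR feature selection (F-statistic relevance
   minus mean |Pearson r| redundancy) to a top-50 list, step-up panel
   sizing under 10×10 repeated stratified cross-validated AUROC of an L2
   logistic model, and a paired comparison against qSOFA on the same fold
   assignments; the same machinery runs within each endotype group.
5. **Enrichment** — preranked GSEA on L2FC-ranked genes with the weighted
   running-sum statistic, gene-permutation normalized enrichment scores
   (NES) and BH-adjusted p-values; GMT input/output.

A bundled synthetic-cohort generator (`endoscope.simulate_cohort`) emulates
the study conditions — ~500 patients across 3 sites, four latent endotypes
with mortalities 22/22/20/11%, endotype-specific 50-gene modules,
severity-linked prognostic genes, negative-binomial counts with a
dispersion trend, lognormal library sizes, and a clinical score calibrated
to AUROC 0.72 — so every stage is testable without restricted patient
data.

## Worked example

```python
import endoscope as es

# simulate a default cohort and run the full pipeline
cfg = es.PipelineConfig(simulation=es.SimulationConfig(seed=1), seed=1,
                        out_dir="endoscope_out")
bundle = es.run_pipeline(cfg)
print(bundle.manifest["n_genes_retained"], "genes retained")
print(bundle.manifest["n_groups"], "endotype groups,",
      f"shared fraction {bundle.manifest['shared_fraction']:.3f}")
rates = bundle.manifest["group_mortality"]
print("group mortality:", {g: round(rates[g], 2) for g in sorted(rates)})
print(f"panel AUROC {bundle.full_model.auroc_mean:.3f} ± "
      f"{bundle.full_model.auroc_sd:.3f} vs qSOFA "
      f"{bundle.full_model.comparator_auroc_mean:.3f}")
```

prints (seed 1):

```
2965 genes retained
6 endotype groups, shared fraction 0.022
group mortality: {'t1': 0.33, 't2': 0.22, 't3': 0.21, 't4': 0.16, 't5': 0.14, 't6': 0.1}
panel AUROC 0.903 ± 0.053 vs qSOFA 0.718
```

Here 2965 of 3400 simulated genes survive the expression/sex-linkage
filters; the mapper stage finds six soft patient groups (2.2% of assigned
patients sit in more than one, well under the 10% cap) whose mortalities
span the planted 11–22% range; and the selected transcript panel clearly
outperforms the simulated clinical score (0.90 vs 0.72 cross-validated
AUROC), as expected when the planted gene signal is stronger than the
clinical-score calibration target.

The same pipeline runs from the shell:

```bash
endoscope simulate --seed 1 --out cohort/          # counts + cohort + truth
endoscope run --config pipeline.yaml --seed 1      # full analysis
endoscope report --out endoscope_out/              # manifest summary
```

where `pipeline.yaml` either points at real inputs (`counts_tsv`,
`annotation_tsv`, `cohort_csv`) or contains a `simulation:` block.

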