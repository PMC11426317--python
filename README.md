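# ampliquant

Quantitative 16S rRNA amplicon analysis for multi-species insect
collections: blank-based contaminant screening, spike-in absolute
quantification, and treatment-effect statistics on both microbial abundance
and community composition.

## The problem

Non-destructive DNA extraction (alkaline lysis such as HotSHOT) lets the
same insect specimen be barcoded and then profiled for its microbiome — but
the hot alkaline incubation degrades DNA, so the question is *how much* of
the amplifiable bacterial template is lost and whether the reconstructed
community composition is biased. Answering it requires three things that
ordinary relative-abundance amplicon pipelines do not provide:

1. **Contaminant screening against negative controls.** Low-biomass insect
   samples are dominated by reagent contamination exactly when template is
   scarce. Every sequence genotype (zOTU/ASV or 97% OTU) is classified from
   the ratio of its maximal relative abundance in blank libraries
   (extraction, first-PCR, second-PCR negative controls) to its maximal
   relative abundance in experimental libraries: a genotype at least as
   prominent in a blank as in its best sample is called a contaminant.
   Chloroplast/mitochondrial/archaeal/chimeric genotypes are stripped by
   taxonomy flags first, and every call is recorded in an auditable ledger.

2. **Absolute quantification from a spike-in.** A linearized plasmid
   carrying an artificial 16S target (Ec5001) is added at a known copy
   number to a known fraction of each specimen homogenate. Assuming no
   amplification bias between template types,

   ```
   copies_per_insect = (bacterial_reads / spike_reads)
                       × spike_copies_added / homogenate_proportion
   ```

   where `bacterial_reads` counts symbiont-class genotypes only. Spike
   parameters are per-sample metadata; samples with missing parameters or
   zero spike reads are refused, not silently defaulted.

3. **Treatment-effect statistics.** Log₁₀ copy numbers are compared across
   treatment arms by a two-way ANOVA (treatment + host line, Type II sums
   of squares) or a mixed model with a random line intercept; per host line
   and per body-size class by Kruskal–Wallis; fold changes are summarized
   as per-line ratios of geometric means. Composition is compared per line
   on rarefied counts: Shannon entropy (Kruskal–Wallis), Bray–Curtis
   dissimilarity with PCoA, PERMANOVA and PERMDISP (permutation tests,
   with an exhaustive-enumeration mode for small designs).

Because the underlying study's raw reads are not deposited, the package
ships a first-class synthetic-experiment generator with known ground truth
(true copy numbers, true genotype classes, true fold change), so every
stage is testable end to end and estimator calibration can be demonstrated.

## Worked example

```python
from ampliquant import (SimulationConfig, simulate_experiment, decontaminate,
                        quantify_all, log_abundance_model, fold_change_summary,
                        per_group_kruskal)

cfg = SimulationConfig(n_lines=6, samples_per_arm=(8, 10), seed=11)
bundle, truth = simulate_experiment(cfg)          # 15-fold true effect
screen = decontaminate(bundle, threshold=1.0)
print("genotype classes:", screen.ledger.class_counts())

estimates, refused = quantify_all(bundle, screen.decontaminated,
                                  screen.spike_reads,
                                  sample_ids=screen.kept_samples)
fit = log_abundance_model(estimates, bundle.metadata, model="two_way_fixed")
per_line, summary = fold_change_summary(estimates, bundle.metadata,
                                        model_fit=fit)
kw, _ = per_group_kruskal(estimates, bundle.metadata, group_by="line")
```

prints (abridged):

```
genotype classes: {'symbiont': 78, 'contaminant': 15, 'nontarget': 3, 'spikein': 1}
quantified 106 specimens (0 refused)
treatment F = 310.31, p = 2.81e-32, coef = -1.181 log10 units
grand fold change = 15.1 (95% CI 10.5-21.6)
abundance significantly lower in 6/6 lines
```

All 15 reagent contaminants were recovered, the treatment coefficient
−1.181 log₁₀ units matches the simulated −log₁₀(15) = −1.176, and the
grand fold-change interval covers the simulated 15-fold loss.

The same analysis is available from the shell:

```bash
ampliquant simulate --seed 11 --out bundle/
ampliquant decontam --bundle bundle/ --threshold 1.0 --out screened/
ampliquant run-all --bundle bundle/ --seed 11 --out run/
```

`run-all` writes the decontamination ledger, abundance estimates, per-line
test tables (`abundance_tests.tsv`, `shannon_braycurtis.tsv`), fold
changes, figure-data tables (abundance box data; genus stacked bars at the
5% threshold; the between-arm genus shift table at 1%), a machine-readable
`report.json`, and a `run_log.yaml` with every seed and parameter needed to
reproduce the run.

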