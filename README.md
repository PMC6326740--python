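# netbgc

Between-network global connectivity (BGC) analysis of parcellated
resting-state fMRI, relating each functional network's mean out-of-network
connectivity to depression-symptom severity across subjects.

The package is aimed at network-neuroscience researchers who have
parcellated BOLD time series (region × frame matrices), motion and nuisance
regressor files, a region→network partition table, and per-subject CES-D
questionnaire responses — and who want the complete analysis surface for a
BGC–symptom study: motion scrubbing, nuisance regression, the BGC statistic
and its control analyses, symptom scoring and normalization, and calibrated
inference. A built-in synthetic cohort simulator with a planted, tunable
effect makes every stage testable without any imaging data.

## The statistic

Functional connectivity `W_ij` is the Pearson correlation between the
cleaned BOLD series of regions *i* and *j*. For region *i* in network *C*,

```
BGC_i = Σ_{j ∉ C} W_ij / (N_total − N_C)
```

— the mean connectivity from *i* to every region outside its own network,
a weighted out-of-network degree that is not inflated for regions in large
networks. A network's BGC is the unweighted mean over its regions, and the
primary analysis correlates network BGC with the Box–Cox-normalized CES-D
total across subjects (two-tailed t-based p, Benjamini–Hochberg FDR across
networks). Control analyses include Spearman robustness, age/gender
residualization, rank-based factor partial correlations, connection-
exclusion BGC, between-network mean FC, within-network FC with a Fisher-z
comparison, and a rerun under an alternate partition. See
`docs/methods.md` for the full model description.

## Worked example

Simulate a 96-subject cohort with the default planted effect (population
r ≈ −0.25 on the fronto-parietal analog network) and run the full analysis:

```python
import netbgc

cfg = netbgc.SimulationConfig.scaled_down(n_subjects=96, seed=1)
report = netbgc.run_pipeline(netbgc.PipelineConfig(simulation=cfg, seed=1))
netbgc.write_report(report, "demo_report")
```

or equivalently from the shell:

```
netbgc simulate --scaled-down --seed 1 --out cohort/        # write files
netbgc run --config pipeline.yaml --out demo_report/        # analyze
netbgc report --tables demo_report/                         # re-render
```

The rendered summary for seed 1 prints:

```
Network BGC-symptom associations (Pearson, BH-FDR):
  Fronto-parietal        r=-0.357 p=0.000 p_fdr=0.001
  Language               r=-0.027 p=0.794 p_fdr=0.966
  Somatomotor            r=+0.004 p=0.966 p_fdr=0.966
  Default mode           r=+0.201 p=0.050 p_fdr=0.099
n=96 subjects analyzed, 0 dropped; focus networks: Fronto-parietal, Language, Somatomotor
```

The planted effect network (the fronto-parietal analog) shows the most
negative correlation, here overshooting the planted population value of
−0.25 because a single n = 96 draw carries a sampling SE of about 0.1;
the other networks hover near zero. The report directory also contains the
region-level table (separate FDR family), all control-analysis tables, the
Box–Cox/KS diagnostics (for this seed λ = 0.48, KS p 0.107 before and
0.869 after transformation), per-subject scrubbing counts, and a
provenance block (config hash, seed, package versions).

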