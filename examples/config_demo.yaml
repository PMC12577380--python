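# Annotated demo configuration for `cprkit run-all --config examples/config_demo.yaml`
#
# Either give paths to real input tables under `inputs:` (counts, metadata,
# taxonomy, qpcr, reference_fasta, reference_taxonomy, annotations,
# reaction_classes, optionally differential_abundance) or, as here, a
# `simulate:` block that generates every input with planted ground truth.

output_dir: scratch/demo_bundle
seed: 42                     # one seed; sub-streams are derived per stage

simulate:
  seed: 42
  n_asv_cpr: 8               # CPR ASVs (classes cycle through the six CPR classes)
  n_asv_noncpr: 12           # background community
  n_experiments: 2           # alternating Auto (oxic) / Methylo (anoxic)
  time_points: [0, 7, 14, 21]  # days; t = 0 samples form the "Start" group
  n_replicates: 2
  depth: 15000               # reads per sample (multinomial sampling)
  noise_sd_log: 0.25         # sigma of multiplicative lognormal abundance noise
  qpcr_noise_sd_log: 0.2     # sigma of lognormal qPCR measurement error
  planted_pairs: 1           # CPR ASVs tracking a non-CPR partner (co-occurrence truth)

# analysis thresholds (defaults shown)
mismatch_budget: 2           # in-silico PCR mismatch budget
edge_min_weight: 0.1         # edges must exceed this weight (strictly)
network_method: rank         # or "sparcc"
alpha_spearman: 0.001        # stringent cutoff for the Spearman branch
alpha_enrichment: 0.05       # Bonferroni-corrected cutoff for function enrichment
min_completeness: 50
max_contamination: 10
cpr_classes: [Parcubacteria, ABY1, Gracilibacteria, Saccharimonadia, Berkelbacteria, Microgenomatia]
focal_classes: [Saccharimonadia, Berkelbacteria]
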