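# Demo study: four structured testcross populations at reduced scale,
# phenotyped in 3 environments x 2 replicates, full analysis chain.
schema_version: 1
seed: 1
stages: [simulate, qc, structure, trial, kinship, evaluate]

simulate:
  n_markers: 1000
  n_chromosomes: 10
  chrom_length_cm: 160
  n_qtl: 150
  mu: 700.0
  var_g: 1600.0
  var_ge: 700.0
  var_rep: 50.0
  var_error: 3300.0
  ge_structure: genetic
  env_names: [E1, E2, E3]
  env_means: [0.0, 60.0, -45.0]
  populations:
    - {name: pop1, type: bc1f3, n_lines: 100, parents: [P_donor, P_recurrent]}
    - {name: pop2, type: dh, n_lines: 40, parents: [P_donor, P_recurrent]}
    - {name: pop3, type: f45, n_lines: 40, parents: [P_donor, P_third]}
    - {name: pop4, type: unrelated, n_lines: 40}

qc:
  call_rate_min: 0.97
  missing_rate_max: 0.01
  maf_min: 0.05
  impute_method: major_allele

structure:
  n_components: 10

trial:
  convention: paper

kinship:
  center: false

evaluate:
  n_repeats: 5
  k_folds: 5
  schemes:
    - {scheme: within, model: A}
    - {scheme: within, model: AD}
    - {scheme: one_to_one, model: A}
    - {scheme: three_to_one, model: A}
    - {scheme: cv1, model: AE, target_env: E1}
    - {scheme: cv1, model: GxE, target_env: E1}
    - {scheme: cv2, model: GxE, target_env: E1}
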