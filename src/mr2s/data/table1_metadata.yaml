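# Provenance and handling policy for the bundled 52-instrument BMI -> T2DM fixture.
exposure_trait: "Body mass index (SD units per effect allele; GIANT meta-analysis)"
outcome_trait: "Type 2 diabetes mellitus (log-odds per effect allele; DIAGRAM-style meta-analysis)"
n_instruments: 52
# rs1167827's outcome beta is unreported in the source table (printed as a dash).
# Policy: impute |beta| = se * Phi^-1(1 - p/2) with the sign below, or exclude the SNP.
missing_outcome_beta:
  policy: impute        # impute | exclude
  sign: -1              # reconstructed; the negative sign best reproduces the published pooled OR
# Transcription notes: printed values are preserved verbatim, including two
# comma-formatted positions, one unreported beta, and apparent chromosome errata
# (rs1528435, rs16951275). Chromosome/position are metadata only and never enter
# estimation.
exposure_columns: {snp: snp, chr: chr, gene: gene, pos: bp, beta: beta_bmi, se: se_bmi, pval: p_bmi}
outcome_columns: {snp: snp, chr: chr, gene: gene, pos: bp, beta: beta_t2dm, se: se_t2dm, pval: p_t2dm}
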