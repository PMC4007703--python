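# Default 17-gene prostate expression panel.
#
# Panel structure (gene identities, pathway groups, reference set, gDNA
# contamination assay) is the published assay design.  The numeric scoring
# coefficients, intercept and scale below are ILLUSTRATIVE defaults chosen so
# that typical reference-normalized expression profiles map to mid-range
# scores: the proprietary coefficient values of the commercial score are not
# public, and every consumer of this file treats the coefficients as
# configuration, not as code.
#
# Normalized expression is Cp-oriented (gene Cp minus reference average plus
# 10), so a LARGER value means a LATER crossing, i.e. LESS transcript.  Signs
# of the coefficients below are entered for that orientation: pathways whose
# higher transcript abundance indicates worse outcome (stromal response,
# proliferation) carry negative coefficients here, and vice versa.

name: gps_prostate_17

groups:
  androgen: [AZGP1, KLK2, SRD5A2, FAM13C]
  cellular_organization: [FLNC, GSN, TPM2, GSTM2]
  proliferation: [TPX2]
  stromal: [BGN, COL1A1, SFRP4]

reference_genes: [ARF1, ATP5E, CLTC, GPS1, PGK1]

gdna_assay: ARF1_promoter

# Per-well weights for triplicate aggregation (renormalized over valid wells);
# equal weights give the arithmetic mean.
well_weights: [1.0, 1.0, 1.0]

group_coefficients:
  AZGP1: 0.25
  KLK2: 0.25
  SRD5A2: 0.25
  FAM13C: 0.25
  FLNC: 0.25
  GSN: 0.25
  TPM2: 0.25
  GSTM2: 0.25
  TPX2: 1.0
  BGN: 0.3333333333
  COL1A1: 0.3333333333
  SFRP4: 0.3333333333

gps_coefficients:
  androgen: 0.45
  cellular_organization: 0.35
  proliferation: -0.30
  stromal: -0.60

gps_intercept: 0.0

# Optional piecewise pre-transforms of group scores (identity when omitted).
group_transforms: {}

# gps = clamp(offset + slope * gps_unscaled, lower, upper)
scale_params:
  slope: 12.0
  offset: 35.0
  lower: 0.0
  upper: 100.0

qc_thresholds:
  gdna_cp: 35.0          # patient gDNA signal crossing earlier than this fails QC
  cp_ceiling: 45.0       # run length in cycles
  min_valid_wells: 2     # triplicates need at least 2 valid wells
  reference_mean_window: null

centering_constant: 10.0

# Dilution-series starting concentration (ng RNA per PCR well); the
# low-expressing genes run the higher series.
dilution_start_ng:
  default: 204.0
  TPX2: 1638.0
  SRD5A2: 1638.0

allow_partial: false
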