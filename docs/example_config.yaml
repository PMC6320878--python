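# Example full-pipeline configuration for `tlcval run --config`.
# Omitted keys fall back to the study defaults.
seed: 1
alpha: 0.05
cv_threshold: 5.0
noise_sd: 2.0
confidence: 95.0
use_printed_tables: true
label_claims:
  ASA: 500.0
  AA: 200.0
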