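# Baseline characteristics of the two MLH1 carrier surveillance series:
# the Finnish series (3-yearly recommended colonoscopy) and the pooled
# non-Finnish series (2-yearly or more frequent colonoscopy), 1997 onwards.
# Per-series observation years sum to the 7924 total of the final analysis.
series,recommended_interval_months,n_subjects,n_male,n_female,observation_years,age_inclusion_mean,age_inclusion_sd,followup_mean,followup_sd
finnish,36,505,246,259,4625,35.2,12.1,9.2,5.9
other,24,439,184,255,3299,36.1,11.0,7.5,5.2
all,,944,430,514,7924,35.5,11.7,8.4,5.7
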