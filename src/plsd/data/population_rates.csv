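# Age-standardized population CRC incidence (per 100,000, EUCAN 2015) and the
# carrier-cohort cumulative CRC incidence at age 70 (percent) per region.
region,asr_crc_per_100k,cohort_crc_cum_incidence_70_pct
finland,35.0,39.2
other,43.6,54.8
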