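scenario,price_usd2022,turnover_change,tax,subsidy
default_bio_160,160,350,675,0
agCO2_bio_80,80,210,390,125
agCO2_bio_160,160,330,690,375
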