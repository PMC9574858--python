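compound_id,ic50_cell_uM,ic50_bio_uM,p_passive_nm_s
protac1,0.924,0.244,30
protac2,16.9,1.41,11
protac3,18.0,0.667,6
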