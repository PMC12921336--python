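sample_id	group
tumor_1	cancer
tumor_2	cancer
norm_1	normal
norm_2	normal
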