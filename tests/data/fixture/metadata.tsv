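sample_id	group
cancer_01	cancer
cancer_02	cancer
cancer_03	cancer
cancer_04	cancer
cancer_05	cancer
cancer_06	cancer
cancer_07	cancer
cancer_08	cancer
cancer_09	cancer
cancer_10	cancer
cancer_11	cancer
cancer_12	cancer
cancer_13	cancer
cancer_14	cancer
normal_01	normal
normal_02	normal
normal_03	normal
normal_04	normal
normal_05	normal
normal_06	normal
normal_07	normal
normal_08	normal
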