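gene	r	G	dm_value	rank
gene03	0.8722617	2	0.3033931	1
gene04	0.8021128	2	0.205817	2
gene02	0.8571084	2	0.08712006	3
gene05	0.7959448	2	-0.006881084	4
gene01	0.9122612	2	-0.04132645	5
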