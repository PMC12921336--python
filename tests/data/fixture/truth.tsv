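gene	driven	G_true	pi_cancer	pi_normal	coupling
gene01	True	2	0.9	0.1	2
gene02	True	2	0.9	0.1	2
gene03	True	2	0.9	0.1	2
gene04	True	2	0.9	0.1	2
gene05	True	2	0.9	0.1	2
gene06	False	2	0.5	0.5	0
gene07	False	1	0	0	0
gene08	False	2	0.5	0.5	0
gene09	False	1	0	0	0
gene10	False	1	0	0	0
gene11	False	1	0	0	0
gene12	False	2	0.5	0.5	0
gene13	False	1	0	0	0
gene14	False	1	0	0	0
gene15	False	2	0.5	0.5	0
gene16	False	1	0	0	0
gene17	False	1	0	0	0
gene18	False	2	0.5	0.5	0
gene19	False	2	0.5	0.5	0
gene20	False	1	0	0	0
gene21	False	2	0.5	0.5	0
gene22	False	2	0.5	0.5	0
gene23	False	1	0	0	0
gene24	False	1	0	0	0
gene25	False	1	0	0	0
gene26	False	1	0	0	0
gene27	False	1	0	0	0
gene28	False	1	0	0	0
gene29	False	1	0	0	0
gene30	False	1	0	0	0
gene31	False	2	0.5	0.5	0
gene32	False	2	0.5	0.5	0
gene33	False	2	0.5	0.5	0
gene34	False	1	0	0	0
gene35	False	2	0.5	0.5	0
gene36	False	2	0.5	0.5	0
gene37	False	2	0.5	0.5	0
gene38	False	1	0	0	0
gene39	False	1	0	0	0
gene40	False	1	0	0	0
gene41	False	1	0	0	0
gene42	False	2	0.5	0.5	0
gene43	False	2	0.5	0.5	0
gene44	False	1	0	0	0
gene45	False	1	0	0	0
gene46	False	1	0	0	0
gene47	False	2	0.5	0.5	0
gene48	False	1	0	0	0
gene49	False	1	0	0	0
gene50	False	1	0	0	0
gene51	False	1	0	0	0
gene52	False	1	0	0	0
gene53	False	1	0	0	0
gene54	False	1	0	0	0
gene55	False	1	0	0	0
gene56	False	1	0	0	0
gene57	False	1	0	0	0
gene58	False	1	0	0	0
gene59	False	1	0	0	0
gene60	False	1	0	0	0
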