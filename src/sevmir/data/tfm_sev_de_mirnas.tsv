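mirna	fold_change	p
miR-148b-3p	2.79	8.33e-05
miR-22-3p	2.55	0.00258
miR-222-3p	2.51	0.000105
miR-16-5p	2.66	0.00282
miR-4711-3p	3.82	0.00012
miR-181d-5p	2.81	0.00304
let-7a-5p	2.44	0.000178
miR-142-5p	2.32	0.00336
miR-128-3p	3.24	0.000228
miR-484	2.24	0.00349
let-7d-5p	2.61	0.000277
miR-26a-5p	2.35	0.00351
let-7c-5p	2.01	0.000524
miR-92a-3p	2.53	0.00377
miR-328-3p	2.51	0.000554
miR-106b-5p	2.15	0.00379
let-7i-5p	2.61	0.000614
miR-326	2.02	0.00393
miR-191-5p	3.14	0.000651
miR-15b-5p	3.01	0.00473
miR-31-5p	2.92	0.000702
miR-93-5p	2.15	0.00485
miR-320a	2.01	0.000885
let-7f-5p	2.97	0.00491
miR-32-5p	4.76	0.00105
miR-29b-3p	2.44	0.00506
miR-130b-3p	2.42	0.00115
miR-107	2.95	0.00558
let-7e-5p	2.52	0.00133
miR-19b-3p	2.36	0.0056
miR-340-5p	3.12	0.00136
miR-548a-5p	6.18	0.00574
HK_RPL27	4.06	0.00143
miR-27a-3p	2.02	0.00638
miR-17-5p	2.13	0.00145
miR-185-5p	2.29	0.00663
miR-339-5p	2.43	0.0015
miR-4649-3p	2.33	0.00672
let-7g-5p	2.77	0.00156
miR-486-5p	2.01	0.00725
miR-744-5p	2.8	0.00177
miR-6754-3p	2.55	0.00728
miR-15a-5p	2.66	0.00181
miR-6754-5p	2.32	0.00776
miR-18a-5p	3.03	0.00193
miR-106a-5p	2.52	0.0078
miR-652-3p	2.26	0.00197
miR-6855-3p	4.54	0.00806
miR-5089-3p	4.58	0.00218
miR-181b-5p	2.66	0.00815
miR-130a-3p	2.7	0.00219
miR-221-3p	2.03	0.00844
miR-4420	4.6	0.00222
miR-19a-3p	2.22	0.00845
miR-25-3p	2.1	0.00239
miR-6778-5p	2.8	0.00953
miR-26b-5p	2.14	0.00255
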