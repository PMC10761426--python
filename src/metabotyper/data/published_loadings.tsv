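variable	published_factor	confidence	F1	F2	F3	F4	F5	F6
SM (d41:2)	1	2	0.83	-0.08	-0.06	0.03	0.19	-0.09
SM (d42:3)	1	2	0.85	0	-0.09	0.05	0.03	-0.08
SM (d40:1)	1	2	0.83	0.09	-0.07	0.11	0.1	0.07
SM (d39:1)	1	2	0.72	0	-0.04	0.13	0.24	-0.04
SM (d32:1)	1	2	0.77	0.07	-0.07	0.02	0.3	0.04
SM (d36:2)	1	2	0.82	0.22	-0.1	0.15	0	-0.04
SM (d34:2)	1	2	0.86	0.1	-0.06	-0.03	0.17	0.03
SM (d34:0)	1	2	0.9	0.09	-0.02	0.11	0.1	-0.03
SM (d40:2)	1	2	0.87	0.03	-0.08	-0.02	0.24	-0.01
SM (d38:1)	1	3	0.88	0.16	-0.12	0.1	0.16	-0.01
PC (16:0/16:0)	1	3	0.78	0.26	-0.03	0.04	0.44	-0.06
PC (O-34:1)	1	3	0.82	-0.08	0.01	0.03	0.2	-0.06
PC (O-40:4)	1	3	0.82	-0.03	-0.13	0.2	0.06	-0.06
PC (O-32:0)	1	3	0.8	0.04	-0.01	0.01	0.17	-0.03
PC (O-38:4)	1	3	0.81	-0.02	-0.04	0.04	0.17	0.01
PC (O-36:5)	1	3	0.75	-0.06	0.01	0.01	0.26	0.01
PC (16:0/18:2)	1	3	0.7	0.28	0.11	-0.14	0.28	0
CE (18:2)	1	2	0.86	0.11	0.05	-0.1	0.18	0.06
CE (20:4)	1	2	0.83	0.05	-0.12	0.06	0.15	0.03
CE (18:1)	1	2	0.83	0.23	-0.03	0.01	0.3	0.02
DG (36:4)	2	3	0.13	0.81	0.11	0.06	0.23	0.25
TG (16:0_18:0_18:1)	2	3	0.11	0.77	0.05	-0.1	0.44	0.09
TG (56:6)	2	3	0.36	0.85	-0.07	0.02	0.14	-0.08
TG (18:1_18:2_20:4)	2	3	-0.16	0.74	0.07	0.03	0	-0.07
TG (56:3)	2	3	-0.08	0.83	0.05	-0.04	0.28	0.06
TG (58:5)	2	3	0.05	0.83	0.02	-0.11	0.29	-0.06
TG (56:2)	2	3	0.11	0.76	0.02	-0.12	0.3	0.06
TG (54:3)	2	3	0.21	0.87	0.01	-0.07	0.08	0.05
TG (18:1_18:2_18:2)	2	3	0.05	0.8	-0.02	-0.15	0.01	-0.04
TG (57:2)	2	3	0.08	0.85	0.03	-0.09	0.31	-0.02
TG (53:3)	2	3	-0.06	0.84	0.08	-0.02	0.38	0
TG (54:4)	2	3	0.09	0.89	0.01	-0.11	-0.03	0
TG (16:0_18:1_18:2)	2	3	0.19	0.94	-0.02	-0.07	0.13	0
Phenylalanine	3	2	-0.08	0.02	0.84	0.03	0.05	0.33
Oxalic acid	3	2	-0.17	-0.08	0.64	-0.1	-0.05	-0.24
Myo-Inositol	3	2	0.03	0.02	0.65	0.25	0	0.19
Cholesterol	3	2	0.14	0.15	0.72	0.04	0.06	-0.19
Proline	3	2	-0.05	0.18	0.78	-0.12	0.14	0.17
Serine	3	2	-0.02	-0.09	0.93	-0.03	-0.13	0.16
Glycine	3	2	0	-0.14	0.77	0.05	-0.02	0.15
Alanine	3	2	-0.06	0.14	0.84	-0.13	0.13	0.11
Methionine	3	2	-0.09	0.01	0.84	-0.14	0.03	0.11
5-Oxoproline/Pyroglutamic acid	3	2	-0.12	-0.03	0.81	-0.06	-0.02	-0.08
Valine	3	2	0	0.15	0.81	-0.01	-0.02	0.05
Threonine	3	2	-0.03	-0.03	0.85	-0.21	-0.05	-0.01
FA (20:4)	4	2	0.09	-0.1	-0.03	0.73	-0.08	0.45
FA (20:3)	4	2	-0.04	0.01	-0.06	0.89	0.04	0.2
FA (17:0)	4	2	0.04	-0.14	0.05	0.86	-0.05	0.1
FA (22:4)	4	2	0.07	0	-0.15	0.86	-0.08	0.06
FA (18:3)	4	2	0.04	0.02	0	0.88	0.11	0.03
FA (18:0;O6)	4	4	0.04	-0.03	-0.04	0.92	-0.21	0.03
FA (14:0)	4	2	0.07	-0.03	0	0.87	0.07	0.02
FA (22:5)	4	2	0.16	-0.08	-0.08	0.91	0.01	-0.01
FA (22:6)	4	2	0.2	-0.09	0.04	0.64	-0.05	0
FA (14:1)	4	2	0.04	-0.11	-0.03	0.88	0.01	0
FAHFA (2:0_20:4)	4	4	-0.06	-0.04	0.02	0.88	-0.22	0.05
LPC (20:3/0:0)	5	2	0.21	0.18	0.04	-0.02	0.67	0.16
PC (18:0_20:3)	5	3	0.37	0.33	0.03	-0.06	0.73	0.1
PC (30:0)	5	3	0.32	0.21	0.05	-0.06	0.76	-0.09
PC (16:0_16:1)	5	3	0.36	0.3	0.01	0.02	0.78	-0.07
PC (34:3)	5	3	0.39	0.27	0.03	-0.15	0.79	-0.06
PC (40:5)	5	3	0.51	0.28	0.1	-0.02	0.69	-0.06
PC (33:1)	5	3	0.42	0.22	0.03	-0.04	0.68	-0.06
PC (18:0_18:1)	5	3	0.44	0.21	0.04	-0.07	0.71	0.06
PC (18:0_22:4)	5	3	0.3	0.28	-0.01	-0.02	0.72	0.03
PC (38:1)	5	3	0.52	0.18	-0.04	-0.11	0.65	0.01
Glutamic acid	6	2	-0.04	0.12	0.14	0.18	-0.09	0.85
Choline	6	2	0.01	0.13	0.17	0.03	0.07	0.74
Aspartic acid	6	2	0.02	-0.03	-0.01	0.19	0.04	0.72
Glutamine	6	2	-0.16	-0.1	0.18	0.07	-0.12	0.67
Arginine	6	2	0.01	0.02	0.12	0.02	0.14	0.66
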