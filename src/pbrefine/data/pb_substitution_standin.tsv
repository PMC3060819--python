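pb	a	b	c	d	e	f	g	h	i	j	k	l	m	n	o	p
a	2.20	-2.85	-1.77	-2.34	-3.47	-3.08	-2.57	-3.89	-3.41	-3.65	-3.99	-3.20	-3.52	-4.03	-3.45	-2.90
b	-2.85	2.20	-1.64	-1.04	-2.50	-2.52	-2.94	-2.83	-1.29	-2.82	-1.44	-2.50	-3.45	-4.03	-3.42	-2.51
c	-1.77	-1.64	2.20	-0.89	-2.37	-1.94	-1.82	-2.97	-2.93	-2.76	-3.13	-3.81	-3.46	-3.93	-3.18	-2.14
d	-2.34	-1.04	-0.89	2.20	-1.35	-1.17	-3.00	-2.30	-2.08	-2.01	-2.64	-3.59	-4.88	-5.25	-4.47	-3.69
e	-3.47	-2.50	-2.37	-1.35	2.20	-2.23	-1.64	-3.03	-3.30	-3.00	-3.10	-4.01	-5.13	-4.10	-5.14	-4.40
f	-3.08	-2.52	-1.94	-1.17	-2.23	2.20	-3.62	-0.84	-3.27	-1.69	-1.22	-2.50	-3.59	-4.34	-3.86	-4.02
g	-2.57	-2.94	-1.82	-3.00	-1.64	-3.62	2.20	-4.05	-3.96	-4.39	-3.87	-3.40	-3.06	-1.49	-3.09	-2.68
h	-3.89	-2.83	-2.97	-2.30	-3.03	-0.84	-4.05	2.20	-3.56	-2.46	-1.96	-3.11	-4.06	-4.88	-2.89	-4.34
i	-3.41	-1.29	-2.93	-2.08	-3.30	-3.27	-3.96	-3.56	2.20	-1.90	-2.21	-3.09	-4.28	-4.72	-4.63	-1.71
j	-3.65	-2.82	-2.76	-2.01	-3.00	-1.69	-4.39	-2.46	-1.90	2.20	-1.62	-2.88	-3.65	-4.37	-4.78	-3.20
k	-3.99	-1.44	-3.13	-2.64	-3.10	-1.22	-3.87	-1.96	-2.21	-1.62	2.20	-1.29	-2.49	-3.32	-3.41	-3.40
l	-3.20	-2.50	-3.81	-3.59	-4.01	-2.50	-3.40	-3.11	-3.09	-2.88	-1.29	2.20	-1.31	-2.30	-2.51	-3.07
m	-3.52	-3.45	-3.46	-4.88	-5.13	-3.59	-3.06	-4.06	-4.28	-3.65	-2.49	-1.31	2.20	-0.80	-1.09	-2.23
n	-4.03	-4.03	-3.93	-5.25	-4.10	-4.34	-1.49	-4.88	-4.72	-4.37	-3.32	-2.30	-0.80	2.20	-2.56	-2.88
o	-3.45	-3.42	-3.18	-4.47	-5.14	-3.86	-3.09	-2.89	-4.63	-4.78	-3.41	-2.51	-1.09	-2.56	2.20	-2.72
p	-2.90	-2.51	-2.14	-3.69	-4.40	-4.02	-2.68	-4.34	-1.71	-3.20	-3.40	-3.07	-2.23	-2.88	-2.72	2.20
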