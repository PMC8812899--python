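TARGET	SNP	EA	NEA	EAF	BETA	SE	P
ACE	rs4343	A	G	0.45	-0.63	0.02	1.53e-213
ACE	rs12452187	A	G	0.60	-0.23	0.02	2.53e-27
ACE	rs79480822	C	T	0.93	-0.55	0.05	6.37e-24
ACE	rs3730025	G	A	0.01	-0.80	0.09	4.32e-19
ACE	rs11655956	C	G	0.08	-0.35	0.04	1.06e-15
ACE	rs118121655	G	A	0.96	-0.54	0.07	3.10e-15
ACE	rs4365	G	A	0.97	-0.58	0.08	7.06e-12
ACE	rs4968771	G	A	0.08	-0.22	0.03	1.78e-11
ACE	rs12150648	G	A	0.96	-0.39	0.06	1.88e-10
ACE	rs80311894	T	G	0.97	-0.46	0.07	2.60e-10
ACE	rs118138685	C	G	0.04	-0.40	0.07	2.44e-9
ACE	rs13342595	C	T	0.23	-0.14	0.02	2.48e-9
ACE	rs28656895	T	C	0.23	-0.14	0.02	3.77e-9
ACE	rs4968780	C	A	0.05	-0.28	0.05	1.86e-8
ADRB1	rs1801253	G	C	0.23	-0.41	0.03	8.07e-43
ADRB1	rs11196549	G	A	0.96	-0.62	0.07	2.53e-19
ADRB1	rs4918889	G	C	0.17	-0.30	0.04	7.53e-18
ADRB1	rs460718	A	G	0.33	-0.24	0.03	2.21e-17
ADRB1	rs11196597	G	A	0.86	-0.27	0.04	3.07e-12
ADRB1	rs143854972	G	A	0.94	-0.39	0.06	4.35e-11
ADRB1	rs17875473	C	T	0.91	-0.28	0.05	9.04e-9
ADRB1	rs10787510	A	G	0.48	-0.15	0.03	2.01e-8
NCC	rs35797045	A	C	0.05	-0.35	0.06	4.85e-8
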