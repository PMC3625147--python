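# Published population-abundance-weighted relative abundances (%) of GH
# families among total GHs for six lignocellulose-degrading microbiomes:
# two higher-termite hindgut paunch metagenomes (A. wheeleri from cow dung,
# laboratory N. corniger on wood), a Costa Rican Nasutitermes sp. reference,
# a switchgrass-adapted compost, the tammar wallaby foregut and the cow rumen.
gh_family	a_wheeleri	n_corniger	nasutitermes_cr	compost	wallaby	rumen
GH5	10.4	17.2	13.9	3.2	3.7	1.0
GH6	0	0	0	2.1	0	0
GH7	0	0	0	0.1	0	0
GH9	4.2	7.0	4.3	4.3	0	0.9
GH44	0.3	0	0.8	0.4	0	0
GH45	0.8	3.6	0.6	0	0	0
GH48	0	0	0	0.5	0	0
GH8	1.5	4.0	2.7	0.5	0.4	0.5
GH10	9.0	10.5	9.9	8.9	4.1	1.0
GH11	4.4	4.7	1.9	1.4	0	0.1
GH12	0	0	0	0.6	0	0
GH26	1.4	2.9	2.0	1.5	1.9	0.8
GH28	1.1	0.2	1.4	0.9	0.7	0.6
GH53	0.7	3.2	2.2	0.2	3.3	2.7
GH16	0.7	0.5	0.6	2.0	1.5	0.1
GH17	0	0	0	0.1	0	0
GH74	0.8	1.4	0.7	1.6	0.4	0
GH81	0	0	0	0.3	0	0
GH51	4.1	0.8	2.0	7.8	4.5	9.9
GH54	0	0	0	0	0	0.2
GH62	0	0	0	1.7	0	0
GH67	2.5	2.0	3.3	3.6	1.9	0
GH78	1.9	0.4	0.8	8.1	9.3	5.1
GH1	2.8	3.1	2.5	9.2	22.7	1.8
GH2	15.7	7.1	13.6	8.6	8.9	28.5
GH3	17.4	15.1	15.5	12.2	26.8	26.6
GH29	3.3	1.8	1.2	2.1	0.7	4.2
GH35	0.1	0.1	0.6	0.6	1.1	1.9
GH38	2.1	1.7	4.2	2.6	1.1	2.6
GH39	1.6	1.4	1.5	1.0	0.4	0.3
GH42	2.8	5.0	6.9	2.5	3.0	1.9
GH43	10.1	5.2	6.6	11.3	3.7	9.3
GH52	0	1.1	0.3	0	0	0
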