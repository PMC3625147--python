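# Published per-category subtotals (%) matching gh_percentages_termite_studies.tsv.
category	a_wheeleri	n_corniger	nasutitermes_cr	compost	wallaby	rumen
cellulases	15.7	27.8	19.6	10.6	3.7	1.9
endohemicellulase	18.1	25.5	20.1	14.0	10.4	5.7
cell_wall_elongation	1.5	1.9	1.3	4.0	1.9	0.1
debranching	8.5	3.2	6.1	21.2	15.6	15.2
oligosaccharide_degrading	55.9	41.6	52.9	50.1	68.4	77.1
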