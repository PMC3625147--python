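# CAZy glycoside hydrolase families relevant to plant cell wall degradation,
# their pfam domains (empty = identified by sequence search, supplied as a
# per-gene GH_family annotation), broad functional category and known activity.
gh_family	pfam_ids	category	known_activity
GH5	PF00150	cellulases	cellulase
GH6	PF01341	cellulases	endoglucanase
GH7	PF00840	cellulases	endoglucanase
GH9	PF00759	cellulases	endoglucanase
GH44		cellulases	endoglucanase
GH45	PF02015	cellulases	endoglucanase
GH48	PF02011	cellulases	endo-processive cellulase
GH8	PF01270	endohemicellulase	endo-xylanase
GH10	PF00331	endohemicellulase	endo-1,4-beta-xylanase
GH11	PF00457	endohemicellulase	xylanase
GH12	PF01670	endohemicellulase	endoglucanase & xyloglucan hydrolysis
GH26	PF02156	endohemicellulase	beta-mannanase & xylanase
GH28	PF00295	endohemicellulase	galacturonases
GH53	PF07745	endohemicellulase	endo-1,4-beta-galactanase
GH16	PF00722	cell_wall_elongation	xyloglucanases & xyloglycosyltransferases
GH17	PF00332	cell_wall_elongation	1,3-beta-glucosidases
GH74		cell_wall_elongation	endoglucanases & xyloglucanases
GH81	PF03639	cell_wall_elongation	1,3-beta-glucanase
GH51		debranching	alpha-L-arabinofuranosidase
GH54	PF09206	debranching	alpha-L-arabinofuranosidase
GH62	PF03664	debranching	alpha-L-arabinofuranosidase
GH67	PF07477,PF07488,PF03648	debranching	alpha-glucuronidase
GH78	PF05592	debranching	alpha-L-rhamnosidase
GH1	PF00232	oligosaccharide_degrading	beta-glucosidase & other beta-linked dimers
GH2	PF00703,PF02836,PF02837	oligosaccharide_degrading	beta-galactosidases & other beta-linked dimers
GH3	PF00933,PF01915	oligosaccharide_degrading	mainly beta-glucosidases
GH29	PF01120	oligosaccharide_degrading	alpha-L-fucosidase
GH35	PF01301	oligosaccharide_degrading	beta-galactosidases & other beta-linked dimers
GH38	PF01074,PF07748	oligosaccharide_degrading	alpha-mannosidase
GH39	PF01229	oligosaccharide_degrading	beta-xylosidase
GH42	PF02449,PF08533,PF08532	oligosaccharide_degrading	beta-galactosidase
GH43	PF04616	oligosaccharide_degrading	arabinases & xylosidases
GH52	PF03512	oligosaccharide_degrading	beta-xylosidase
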