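accession	family	role	substrate	action
PF00150	GH5	catalytic_GH	cellulose	backbone_hydrolase
PF01341	GH6	catalytic_GH	cellulose	backbone_hydrolase
PF00840	GH7	catalytic_GH	cellulose	backbone_hydrolase
PF01270	GH8	catalytic_GH	cellulose	backbone_hydrolase
PF00759	GH9	catalytic_GH	cellulose	backbone_hydrolase
PF01670	GH12	catalytic_GH	cellulose	backbone_hydrolase
PF12891	GH44	catalytic_GH	cellulose	backbone_hydrolase
PF02015	GH45	catalytic_GH	cellulose	backbone_hydrolase
PF02011	GH48	catalytic_GH	cellulose	backbone_hydrolase
PF00232	GH1	catalytic_GH	cellulose	oligosaccharidase
PF00933	GH3	catalytic_GH	cellulose	oligosaccharidase
PF00331	GH10	catalytic_GH	xylan	backbone_hydrolase
PF00457	GH11	catalytic_GH	xylan	backbone_hydrolase
PF02055	GH30	catalytic_GH	xylan	backbone_hydrolase
PF14587	GH30c	accessory	none	other
PF04616	GH43	catalytic_GH	xylan	oligosaccharidase
PF00704	GH18	catalytic_GH	chitin	backbone_hydrolase
PF00182	GH19	catalytic_GH	chitin	backbone_hydrolase
PF03644	GH85	catalytic_GH	chitin	backbone_hydrolase
PF00728	GH20	catalytic_GH	chitin	oligosaccharidase
PF00128	GH13	catalytic_GH	other	backbone_hydrolase
PF00703	GH2	catalytic_GH	other	oligosaccharidase
PF01522	Polysacc_deac_1	catalytic_CE	xylan	debrancher
PF00756	Esterase	catalytic_CE	xylan	debrancher
PF13472	Lipase_GDSL_2	catalytic_CE	other	debrancher
PF00734	CBM1	accessory	none	binding
PF00553	CBM2	accessory	none	binding
PF00942	CBM3	accessory	none	binding
PF02018	CBM4_9	accessory	none	binding
PF02839	CBM5_12	accessory	none	binding
PF03422	CBM6	accessory	none	binding
PF02013	CBM10	accessory	none	binding
PF01607	CBM14	accessory	none	binding
PF00404	Dockerin	accessory	none	other
PF00041	Fn3	accessory	none	other
PF07554	FIVAR	accessory	none	binding
PF00754	F5_F8_type_C	accessory	none	binding
PF02368	BIG_2	accessory	none	other
PF02927	CelD_N	accessory	none	binding
PF01476	LysM	accessory	none	binding
PF12741	SusD	accessory	none	binding
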