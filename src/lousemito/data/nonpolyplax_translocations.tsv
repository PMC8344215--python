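gene	mrca_arrangement	derived_arrangement	species	genus
N	atp8-atp6-N	E-cob-S1-S2-N	Microthoracius_praelongiceps	Microthoracius
N	atp8-atp6-N	cob-S1-N-E-M	Pediculus_schaeffi	Pediculus
N	atp8-atp6-N	S1-N-E	Pediculus_capitis	Pediculus
N	atp8-atp6-N	S1-N-E	Pediculus_humanus	Pediculus
N	atp8-atp6-N	T-nad1-Q-N-C	Pedicinus_badii	Pedicinus
N	atp8-atp6-N	T-nad1-Q-N-G-nad3-W	Pedicinus_obtusus	Pedicinus
E	E-cob-S1-S2	cob-S1-N-E-M	Pediculus_schaeffi	Pediculus
E	E-cob-S1-S2	F-nad6-E-M	Pthirus_pubis	Pthirus
E	E-cob-S1-S2	S1-N-E	Pediculus_capitis	Pediculus
E	E-cob-S1-S2	S1-N-E	Pediculus_humanus	Pediculus
S1	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_apri	Haematopinus
S1	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_suis	Haematopinus
S1	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_asini	Haematopinus
S1	E-cob-S1-S2	S1-N-E	Pediculus_capitis	Pediculus
S1	E-cob-S1-S2	S1-N-E	Pediculus_humanus	Pediculus
S2	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_apri	Haematopinus
S2	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_suis	Haematopinus
S2	E-cob-S1-S2	D-Y-cox2-S1-S2-P-cox3-A	Haematopinus_asini	Haematopinus
S2	E-cob-S1-S2	G-nad3-V-W-S2	Pthirus_pubis	Pthirus
I	I-cox1-L2	P-nad2-I	Pediculus_schaeffi	Pediculus
I	I-cox1-L2	P-nad2-I	Pediculus_capitis	Pediculus
I	I-cox1-L2	P-nad2-I	Pediculus_humanus	Pediculus
I	I-cox1-L2	P-nad2-I	Pthirus_pubis	Pthirus
I	I-cox1-L2	R-nad4L-P-cox3-I	Pedicinus_obtusus	Pedicinus
L2	I-cox1-L2	L2-rrnS-C	Pediculus_schaeffi	Pediculus
L2	I-cox1-L2	L2-rrnS-C	Pediculus_capitis	Pediculus
L2	I-cox1-L2	L2-rrnS-C	Pediculus_humanus	Pediculus
D	D-Y-cox2-nad6	T-D-H-R-nad4L	Pthirus_pubis	Pthirus
D	D-Y-cox2-nad6	T-D-H	Pediculus_schaeffi	Pediculus
D	D-Y-cox2-nad6	T-D-H	Pediculus_capitis	Pediculus
D	D-Y-cox2-nad6	T-D-H	Pediculus_humanus	Pediculus
D	D-Y-cox2-nad6	G-nad3-W-D-A-V	Pedicinus_badii	Pedicinus
D	D-Y-cox2-nad6	D-A-M-F-nad6	Pedicinus_obtusus	Pedicinus
P	R-nad4L-P-cox3-A	P-nad2-I	Pthirus_pubis	Pthirus
P	R-nad4L-P-cox3-A	P-nad2-I	Pediculus_schaeffi	Pediculus
P	R-nad4L-P-cox3-A	P-nad2-I	Pediculus_capitis	Pediculus
P	R-nad4L-P-cox3-A	P-nad2-I	Pediculus_humanus	Pediculus
A	R-nad4L-P-cox3-A	G-nad3-W-D-A-V	Pedicinus_badii	Pedicinus
A	R-nad4L-P-cox3-A	D-A-M-F-nad6	Pedicinus_obtusus	Pedicinus
Q	Q-nad1-T-G-nad3-W	Q-N-E	Pediculus_humanus	Pediculus
Q	Q-nad1-T-G-nad3-W	T-nad1-Q-N-C	Pedicinus_badii	Pedicinus
Q	Q-nad1-T-G-nad3-W	T-nad1-Q-N-G-nad3-W	Pedicinus_obtusus	Pedicinus
T	Q-nad1-T-G-nad3-W	T-nad1-Q-N-C	Pedicinus_badii	Pedicinus
T	Q-nad1-T-G-nad3-W	T-nad1-Q-N-G-nad3-W	Pedicinus_obtusus	Pedicinus
T	Q-nad1-T-G-nad3-W	D-Y-cox2-T	Hoplopleura_kitti	Hoplopleura
T	Q-nad1-T-G-nad3-W	R-nad4L-P-cox3-A-T	Hoplopleura_akanezumi	Hoplopleura
T	Q-nad1-T-G-nad3-W	T-D-H-R-nad4L	Pthirus_pubis	Pthirus
T	Q-nad1-T-G-nad3-W	T-D-H	Pediculus_schaeffi	Pediculus
T	Q-nad1-T-G-nad3-W	T-D-H	Pediculus_capitis	Pediculus
T	Q-nad1-T-G-nad3-W	T-D-H	Pediculus_humanus	Pediculus
G	Q-nad1-T-G-nad3-W	G-nad4L-V	Pediculus_schaeffi	Pediculus
G	Q-nad1-T-G-nad3-W	G-nad4L-V	Pediculus_capitis	Pediculus
G	Q-nad1-T-G-nad3-W	G-nad4L-V	Pediculus_humanus	Pediculus
W	Q-nad1-T-G-nad3-W	C-nad6-W-L2	Hoplopleura_kitti	Hoplopleura
W	Q-nad1-T-G-nad3-W	C-nad6-W-L2	Hoplopleura_akanezumi	Hoplopleura
W	Q-nad1-T-G-nad3-W	G-nad3-V-W-S2	Pthirus_pubis	Pthirus
H	H-nad5-F	T-D-H-R-nad4L	Pthirus_pubis	Pthirus
H	H-nad5-F	T-D-H	Pediculus_schaeffi	Pediculus
H	H-nad5-F	T-D-H	Pediculus_capitis	Pediculus
H	H-nad5-F	T-D-H	Pediculus_humanus	Pediculus
F	H-nad5-F	F-nad6-E-M	Pthirus_pubis	Pthirus
F	H-nad5-F	M-F-nad6	Pedicinus_badii	Pedicinus
F	H-nad5-F	D-A-M-F-nad6	Pedicinus_obtusus	Pedicinus
C	rrnS-C	C-nad6-W-L2	Hoplopleura_kitti	Hoplopleura
C	rrnS-C	C-nad6-W-L2	Hoplopleura_akanezumi	Hoplopleura
C	rrnS-C	T-nad1-Q-N-C	Pedicinus_badii	Pedicinus
C	rrnS-C	atp8-atp6-C	Pedicinus_obtusus	Pedicinus
M	M-L1-rrnL-V	R-nad4L-nad6-M	Haematopinus_apri	Haematopinus
M	M-L1-rrnL-V	R-nad4L-nad6-M	Haematopinus_suis	Haematopinus
M	M-L1-rrnL-V	F-nad6-E-M	Pthirus_pubis	Pthirus
M	M-L1-rrnL-V	cob-S1-N-E-M	Pediculus_schaeffi	Pediculus
M	M-L1-rrnL-V	M-F-nad6	Pedicinus_badii	Pedicinus
M	M-L1-rrnL-V	D-A-M-F-nad6	Pedicinus_obtusus	Pedicinus
L1	M-L1-rrnL-V	L1-rrnS-C	Pediculus_schaeffi	Pediculus
L1	M-L1-rrnL-V	L1-rrnS-C	Pediculus_capitis	Pediculus
L1	M-L1-rrnL-V	L1-rrnS-C	Pediculus_humanus	Pediculus
V	M-L1-rrnL-V	G-nad3-V-W-S2	Pthirus_pubis	Pthirus
V	M-L1-rrnL-V	G-nad3-W-D-A-V	Pedicinus_badii	Pedicinus
V	M-L1-rrnL-V	nad2-Y-cox2-V	Pedicinus_obtusus	Pedicinus
V	M-L1-rrnL-V	G-nad4L-V	Pediculus_schaeffi	Pediculus
V	M-L1-rrnL-V	G-nad4L-V	Pediculus_capitis	Pediculus
V	M-L1-rrnL-V	G-nad4L-V	Pediculus_humanus	Pediculus
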