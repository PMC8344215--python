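# Inferred most recent common ancestor of Polyplax lice, variant with the
# S1-S2 tRNA cluster downstream of nad1 (i.e. positionally upstream of the
# reversed nad1 in the written order).  Equally parsimonious with the
# variant placing S1-S2 upstream of rrnS.
#taxon=Polyplax_MRCA_S1S2_nad1
#genus=Polyplax
atp8-atp6
E-cob-I
cox1-L2
D-Y-cox2-nad6
R-nad4L-P-cox3-A
S1-S2-~nad1-T-G-nad3-W
Q-nad2-N
K-nad4
H-nad5-F
rrnS-C
M-L1-rrnL-V
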