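# Mitochondrial karyotype of the spiny rat louse.
# Differs from P. reclinata only in the L1/L2 identity swap.
#taxon=Polyplax_spinulosa
#genus=Polyplax
atp8-atp6
E-cob-I
cox1-L1
~T-D-Y-cox2-nad6-A
R-nad4L-P-cox3
~nad1-G-nad3-W
Q-nad2-N
K-nad4
H-nad5-F
S1-S2-rrnS-C
M-L2-rrnL-V
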