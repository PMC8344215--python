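# Mitochondrial karyotype of the greater bandicoot rat louse.
# trnP sits a short distance inside the NCR of the nad2 minichromosome in
# the annotated genome; in the karyotype model it is written as the gene
# flanking the NCR (the adjacency class is the same).
#taxon=Polyplax_asiatica
#genus=Polyplax
atp8-atp6
E-cob-I
cox1-L2
D-Y-cox2-nad6
R-nad4L-cox3-A
S1-S2-~nad1-T-G-nad3-W
Q-nad2-N-P
K-nad4-F
H-nad5
rrnS-C
M-L1-rrnL-V
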