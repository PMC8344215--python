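# Ancestral mitochondrial karyotype of sucking lice (Anoplura), as used as
# the reference for the translocation analyses.  The nad2 minichromosome is
# written bare: no tRNA is attributed to it by the published arrangement
# strings, and the census for this karyotype uses the explicit base counts
# (22 NCR-adjacent, 24 intergenic, 46 total slots = 35 placed genes on 11
# minichromosomes); see lousemito.fixtures.SUCKING_LICE_MRCA_CENSUS_BASE.
#taxon=Anoplura_MRCA
#genus=Anoplura
atp8-atp6-N
E-cob-S1-S2
I-cox1-L2
D-Y-cox2-nad6
R-nad4L-P-cox3-A
Q-~nad1-T-G-nad3-W
nad2
K-nad4
H-nad5-F
rrnS-C
M-L1-rrnL-V
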