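# Prostate cancer seed genes (OMIM-derived training set)
AR
BRCA2
CD82
CHEK2
ELAC2
EPHB2
HIP1
KLF6
MAD1L1
MSR1
MXI1
PCAP
PTEN/PTENP1
RNASEL
HPC1
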