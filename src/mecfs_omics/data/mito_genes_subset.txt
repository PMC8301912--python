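# Small curated subset of mitochondrially localised gene symbols,
# packaged so gene-based subsetting is testable offline. For real
# analyses supply a full inventory (e.g. a MitoCarta export) instead.
PDPR
PANK2
ATP5F1E
SLC25A24
DGLUCY
SUCLG1
MCCC2
PCK2
ATP5F1A
ATP5F1B
ATP5F1C
ATP5F1D
ATP5MC1
NDUFA1
NDUFA2
NDUFB1
NDUFS1
NDUFS2
NDUFV1
SDHA
SDHB
SDHC
SDHD
UQCRC1
UQCRC2
UQCRFS1
CYC1
COX4I1
COX5A
COX6B1
COX7A2
CS
ACO2
IDH2
IDH3A
OGDH
FH
MDH2
PDHA1
PDHB
DLAT
DLD
CPT1A
CPT2
ACADVL
ACADM
HADHA
HADHB
ETFA
ETFB
TFAM
POLG
VDAC1
TOMM20
TIMM23
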