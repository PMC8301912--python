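# Ten CD surface-marker gene symbols used to check for shifts in the
# PBMC subtype distribution.
CD2
CD3E
CD4
CD5
CD7
CD8A
CD14
CD19
CD47
CD74
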