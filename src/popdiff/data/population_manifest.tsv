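population	n_individuals
IND	64
AFR	5203
AMR	5789
EAS	4327
EUR	33370
SAS	8256
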