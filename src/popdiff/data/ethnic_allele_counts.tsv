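group	n_individuals	rs11571769	rs11571707	rs144848
Asurini of the Xingu	5	2	4	4
Arara	7	0	8	8
Araweté	6	4	4	4
Asurini of the Tocantins	16	0	5	23
Awa-Guajá	8	1	4	6
Kayapó/Xikrin	2	1	1	1
Zo'é	5	4	6	6
Wajãpi	10	1	8	10
Karipuna	1	0	0	0
Phurere	1	0	1	1
Munduruku	1	1	1	1
Juruna	2	0	0	0
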