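reaction	metabolite	coefficient	reversible	pathways	organisms
2HIPD	2hipa	-1	false	decarboxylation	orgA
2HIPD	co2	1	false	decarboxylation	orgA
2HIPD	sal	1	false	decarboxylation	orgA
SLD	co2	1	false	decarboxylation	orgB
SLD	phnl	1	false	decarboxylation	orgB
SLD	sal	-1	false	decarboxylation	orgB
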