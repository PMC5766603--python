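OC(=O)c1cccc(C(O)=O)c1O	2hipa
O=C=O	co2
Oc1ccccc1	phnl
OC(=O)c1ccccc1O	sal
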