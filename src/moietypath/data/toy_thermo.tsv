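metabolite	dfG_prime_kcal
2hipa	-140.0
co2	-92.26
phnl	-60.0
sal	-100.0
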