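fly_gene	mouse_genes
toy	Pax6
ey	Pax6
so	Six1/Six2
eya	Eya1/Eya2/Eya3
dac	Dach1
Dpp	Bmp4
tsh	Sdccag33
hth	Meis2
hh	Shh
N	Notch1
wg	Wnt4
optix	Six3/Six6
ato	Atoh7
h	Hes1
eyg	Pax6(5a)
CI	Gli1
oc	Otx1
shf	Wif1
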