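gene_a	gene_b	sign	provenance
toy	ey	+	curated default
ey	so	+	curated default
ey	eya	+	curated default
so	eya	+	curated default
eya	dac	+	curated default
dac	ey	+	curated default
Dpp	ey	+	curated default
wg	ey	-	curated default
wg	Dpp	-	curated default
tsh	ey	+	curated default
tsh	hth	+	curated default
hth	ey	-	curated default
N	ey	+	curated default
N	eyg	+	curated default
eyg	wg	-	curated default
hh	ato	+	curated default
hh	CI	+	curated default
CI	Dpp	+	curated default
h	ato	-	curated default
so	ato	+	curated default
eya	ato	+	curated default
ey	optix	+	curated default
oc	ey	+	curated default
shf	hh	+	curated default
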