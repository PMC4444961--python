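genome_id	label
isca	solitary
acpi	solitary
tcas	solitary
bmor	solitary
dmel	solitary
aaeg	solitary
aros	solitary
mdem	solitary
nvit	solitary
nlon	solitary
ngir	solitary
amel	eusocial
ador	eusocial
aflo	eusocial
bimp	eusocial
bter	eusocial
lalb	facultative
mrot	solitary
hsal	eusocial
cflo	eusocial
acep	eusocial
sinv	eusocial
pbar	eusocial
pdom	eusocial
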