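genome_id	panel
isca	extended-only
acpi	extended-only
tcas	extended-only
bmor	extended-only
dmel	initial
aaeg	extended-only
aros	extended-only
mdem	initial
nvit	initial
nlon	extended-only
ngir	extended-only
amel	initial
ador	extended-only
aflo	extended-only
bimp	initial
bter	extended-only
lalb	extended-only
mrot	initial
hsal	extended-only
cflo	extended-only
acep	initial
sinv	extended-only
pbar	extended-only
pdom	extended-only
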