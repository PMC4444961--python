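mirna	isca	acpi	tcas	bmor	dmel	aaeg	aros	mdem	nvit	nlon	ngir	amel	ador	aflo	bimp	bter	lalb	mrot	hsal	cflo	acep	sinv	pbar	pdom
ame-miR-281	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1
ame-miR-306	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	0	0	1	1	1	1	1	0
ame-miR-279c	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1
ame-miR-279d	1	1	1	1	0	0	0	0	0	0	0	1	1	1	1	1	0	0	1	1	1	1	1	1
ame-miR-6065	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	0	1	1	1	1	1	0
ame-miR-927b	0	0	0	0	0	0	1	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-miR-3786	0	0	0	0	0	0	1	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-miR-980	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	0
ame-miR-2765	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	0
ame-miR-6048	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	0
ame-miR-6001	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-miR-1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-let-7	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-miR-279a	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
dme-bantam	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
dme-miR-iab-8	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
dme-miR-971	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ame-miR-252	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ame-miR-2796	0	0	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
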