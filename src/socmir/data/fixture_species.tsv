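genome_id	order	species	common_name	trait	initial_panel	bioproject
isca	Ixodida	Ixodes scapularis	Deer tick	solitary	False	34667
acpi	Hemiptera	Acyrthosiphon pisum	Pea aphid	solitary	False	29489
tcas	Coleoptera	Tribolium castaneum	Red flour beetle	solitary	False	15718
bmor	Lepidoptera	Bombyx mori	Silkworm	solitary	False	205630
dmel	Diptera	Drosophila melanogaster	Fruit fly	solitary	True	164
aaeg	Diptera	Aedes aegypti	Mosquito	solitary	False	19731
aros	Hymenoptera	Athalia rosae	Turnip sawfly	solitary	False	167403
mdem	Hymenoptera	Microplitis demolitor	Parasitoid wasp	solitary	True	251518
nvit	Hymenoptera	Nasonia vitripennis	Parasitoid wasp	solitary	True	20073
nlon	Hymenoptera	Nasonia longicornis	Parasitoid wasp	solitary	False	20225
ngir	Hymenoptera	Nasonia giraulti	Parasitoid wasp	solitary	False	20223
amel	Hymenoptera	Apis mellifera	Honey bee	eusocial	True	13343
ador	Hymenoptera	Apis dorsata	Honey bee	eusocial	False	174631
aflo	Hymenoptera	Apis florea	Honey bee	eusocial	False	86991
bimp	Hymenoptera	Bombus impatiens	Bumble bee	eusocial	True	70395
bter	Hymenoptera	Bombus terrestris	Bumble bee	eusocial	False	68545
lalb	Hymenoptera	Lasioglossum albipes	Sweat bee	facultative	False	174755
mrot	Hymenoptera	Megachile rotundata	Leafcutter bee	solitary	True	87021
hsal	Hymenoptera	Harpegnathos saltator	Jumping ant	eusocial	False	50203
cflo	Hymenoptera	Camponotus floridanus	Carpenter ant	eusocial	False	50201
acep	Hymenoptera	Atta cephalotes	Leafcutter ant	eusocial	True	48091
sinv	Hymenoptera	Solenopsis invicta	Fire ant	eusocial	False	49629
pbar	Hymenoptera	Pogonomyrmex barbatus	Harvester ant	eusocial	False	45797
pdom	Hymenoptera	Polistes dominula	Paper wasp	eusocial	False	Unpublished
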