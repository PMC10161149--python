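# Toy Italian lexicon: surface <TAB> lemma <TAB> pos (closed tagset)
tampone	tampone	noun
tamponi	tampone	noun
infermiere	infermiere	noun
infermieri	infermiere	noun
ostetrica	ostetrica	noun
ostetriche	ostetrica	noun
latte	latte	noun
allattamento	allattamento	noun
padre	padre	noun
padri	padre	noun
parto	parto	noun
stanza	stanza	noun
stanze	stanza	noun
personale	personale	noun
dolore	dolore	noun
durante	durante	other
migliorare	migliorare	verb
migliorato	migliorare	verb
allattare	allattare	verb
aiutare	aiutare	verb
aiutato	aiutare	verb
presente	presente	adjective
disponibile	disponibile	adjective
disponibili	disponibile	adjective
molto	molto	adverb
sempre	sempre	adverb
subito	subito	adverb
nessuno	nessuno	determiner
alcuni	alcuno	determiner
qualche	qualche	determiner
trieste	trieste	proper-noun
italia	italia	proper-noun
due	due	numeral
tre	tre	numeral
covid	covid	noun
mascherina	mascherina	noun
mascherine	mascherina	noun
visite	visita	noun
visita	visita	noun
orari	orario	noun
orario	orario	noun
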