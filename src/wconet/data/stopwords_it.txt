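# Italian function-word stoplist (lemmas, lowercase)
il
lo
la
le
gli
un
uno
una
di
del
della
che
chi
cui
non
piu
più
ed
se
ma
per
con
su
tra
fra
come
anche
quando
dove
mentre
essere
avere
fare
questo
quello
tutto
molto
poco
mi
ti
si
ci
vi
loro
mio
tuo
suo
nostro
vostro
al
dal
nel
sul
alla
dalla
nella
sulla
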