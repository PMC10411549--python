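# German stopword list, v1 (function words: articles, pronouns, prepositions,
# auxiliaries, common particles). One token per line, matched case-insensitively.
aber
alle
allem
allen
aller
alles
als
also
am
an
andere
anderen
anders
auch
auf
aus
bei
beim
bin
bis
bisschen
bist
da
dabei
dadurch
dafür
damit
danach
dann
daran
darauf
darum
das
dass
davon
dazu
dein
deine
dem
den
denen
denn
der
deren
des
deshalb
dessen
die
dies
diese
diesem
diesen
dieser
dieses
dir
doch
dort
du
durch
ein
eine
einem
einen
einer
eines
einfach
einige
er
es
etwas
euch
euer
eure
für
gegen
gewesen
hab
habe
haben
habt
hast
hat
hatte
hatten
hier
hin
hinter
ich
ihm
ihn
ihnen
ihr
ihre
ihrem
ihren
ihrer
im
immer
in
ins
ist
ja
jede
jedem
jeden
jeder
jedes
jetzt
kann
kannst
kein
keine
keinem
keinen
keiner
können
könnte
machen
man
manche
mehr
mein
meine
meinem
meinen
meiner
mich
mir
mit
muss
musste
müssen
nach
nein
nicht
nichts
noch
nun
nur
ob
oder
ohne
sehr
sein
seine
seinem
seinen
seiner
sich
sie
sind
so
sollte
sollten
sondern
sonst
über
um
und
uns
unser
unsere
unter
viel
viele
vom
von
vor
war
waren
warst
was
weil
weiter
welche
welchem
welchen
welcher
welches
wenn
werde
werden
wie
wieder
will
wir
wird
wirst
wo
wurde
wurden
zu
zum
zur
zwar
zwischen
schon
mal
eigentlich
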