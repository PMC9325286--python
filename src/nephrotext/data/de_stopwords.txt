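# General-purpose German stop words (one per line, lowercase).
# Negations ("kein", "keine", "nicht", "ohne", ...) ARE in this base list;
# the preprocessing config removes them programmatically so that negated
# findings stay distinguishable from positive ones.
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
ander
andere
anderem
anderen
anderer
anderes
auch
auf
aus
bei
beide
bin
bis
bist
da
damit
dann
der
den
des
dem
die
das
dass
daß
dazu
dein
denn
derselbe
dich
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
einig
einige
er
es
etwas
euer
eure
für
gegen
gewesen
hab
habe
haben
hat
hatte
hatten
hier
hin
hinter
ich
ihr
ihre
im
in
indem
ins
ist
jede
jedem
jeden
jeder
jedes
jene
jenem
jenen
jener
jenes
kann
kein
keine
keinem
keinen
keiner
keines
können
könnte
machen
man
manche
mein
mich
mir
mit
muss
musste
nach
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
seines
selbst
sich
sie
sind
so
solche
sondern
sonst
über
um
und
uns
unser
unter
viel
vom
von
vor
während
war
waren
warst
was
weg
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
wollen
wollte
würde
würden
zu
zum
zur
zwar
zwischen
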