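# Minimal valence lexicon bundled for hermetic scoring (synthetic,
# VADER-style format: token <tab> mean valence). Not the published
# lexicon; an adapter for the reference implementation is available.
love	3.2
loved	2.9
loving	2.8
like	1.5
liked	1.6
enjoy	2.2
enjoyed	2.3
great	3.1
good	1.9
best	3.2
better	1.9
awesome	3.1
amazing	2.8
excellent	2.7
fantastic	2.6
wonderful	2.7
perfect	2.7
nice	1.8
happy	2.7
glad	2.0
favorite	2.0
favourite	2.0
delicious	2.6
tasty	1.9
smooth	1.3
pleasant	2.3
relief	1.6
relieved	1.9
helps	1.7
helped	1.7
recommend	1.5
worth	0.9
fine	0.8
calm	1.3
clean	1.6
fresh	1.3
satisfying	2.2
satisfied	2.0
improved	1.9
improvement	1.7
win	2.8
thanks	1.9
thank	1.9
yes	1.7
bad	-2.5
worse	-2.1
worst	-3.1
awful	-2.0
terrible	-2.1
horrible	-2.5
hate	-2.7
hated	-3.2
disgusting	-2.4
gross	-1.9
nasty	-2.3
harsh	-1.6
annoying	-1.8
scary	-2.2
scared	-1.9
afraid	-2.0
worried	-1.8
worry	-1.5
fear	-2.2
sad	-2.1
angry	-2.3
upset	-1.9
sick	-2.0
sicker	-2.2
ill	-1.8
die	-3.0
died	-3.1
dying	-3.0
death	-2.9
kill	-3.2
kills	-3.0
dangerous	-2.2
damage	-2.0
damaged	-2.1
problem	-1.7
problems	-1.7
fail	-2.3
failed	-2.4
useless	-1.9
regret	-2.0
suffering	-2.4
suffer	-2.0
unhealthy	-1.8
toxic	-2.4
risk	-1.1
risky	-1.4
avoid	-1.2
quit	-0.6
no	-1.2
never	-1.3
cancer	-3.4
tumor	-2.6
headache	-1.7
headaches	-1.7
migraine	-2.1
pain	-2.5
painful	-2.5
ache	-1.9
cough	-1.1
coughing	-1.3
wheezing	-1.5
asthma	-1.6
nausea	-1.9
nauseous	-2.0
vomiting	-2.3
dizzy	-1.4
dizziness	-1.5
anxiety	-2.0
anxious	-1.8
depression	-2.6
depressed	-2.6
insomnia	-1.8
palpitations	-1.6
irritation	-1.6
irritated	-1.7
sore	-1.5
dry	-0.6
bleeding	-2.1
cramps	-1.7
heartburn	-1.6
stroke	-2.5
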