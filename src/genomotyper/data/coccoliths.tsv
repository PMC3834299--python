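strain	coccoliths	collection_site
92	N	English Channel
92A	N	English Channel
92D	Y	English Channel
92E	Y	English Channel
92F	Y	English Channel
CCMP379	N	English Channel
CCMP374	N	Gulf of Maine
CCMP373	N	Sargasso Sea
12-1	Y	Sargasso Sea
CCMP1516	Y	South Pacific
Van 556	N	North Pacific
CH 24/90	Y	North Atlantic
CH 25/90	Y	North Atlantic
L	N	Oslo Fjord
NZEH	Y	South Pacific
EH2	Y	South Pacific
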