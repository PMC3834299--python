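alias	canonical
12-1 ( = CCMP371) (Sargasso Sea)	12-1
12-1 (Sargasso Sea)	12-1
CCMP371	12-1
CCMP379 ( = 92A, according to CCMP)	CCMP379
CCMP379 (Unknown)	CCMP379
Van556	Van 556
CH24/90	CH 24/90
CH25/90	CH 25/90
92 (English Channel)	92
92A (English Channel)	92A
92D (English Channel)	92D
92E (English Channel)	92E
92F (English Channel)	92F
CCMP374 (Gulf of Maine)	CCMP374
CCMP373 (Sargasso Sea)	CCMP373
CCMP1516 (South Pacific)	CCMP1516
Van 556 (North Pacific)	Van 556
CH 24/90 (North Atlantic)	CH 24/90
CH 25/90 (North Atlantic)	CH 25/90
L (Oslo Fjord)	L
NZEH (South Pacific)	NZEH
EH2 (South Pacific)	EH2
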